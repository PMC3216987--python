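"""Published summary data of the source study, shipped as package fixtures.

Per-sample patient data live in sequence archives and are not redistributed;
what the study prints — per-haplogroup contingency counts for the three
case-control comparisons, with their reported p-values, odds ratios and
confidence intervals, plus a few headline count ratios — ships here so the
statistical engine can be validated against it.

Row ``note`` values:

* ``ok`` — OR and CI are derivable from the printed counts (Woolf formulas);
* ``rounding_ulp`` — one CI bound differs by a single unit in the third
  printed decimal (the authors' intermediate rounding);
* ``zero_cell`` — single-zero-cell row using the cohort-relative-risk
  fallback convention;
* ``known_inconsistent`` — the printed OR/CI (for some rows even the printed
  p) cannot be derived from the printed counts under any of the tests used;
  these rows document source inconsistencies and are excluded from strict
  reproduction sweeps.
"""

from __future__ import annotations

import pandas as pd

from .reference import _data_path
from .stats import ContingencyTable2x2, odds_ratio_ci

COMPARISONS = ("suspected_vs_han", "lhon304_vs_suspected", "lhon304_vs_han")

#: headline count ratios printed by the study:
#: share of M7b carriers resolvable to M7b1'2 among pooled patients; the lone
#: heteroplasmic primary-mutation carrier; haplogroup F in the general Han
#: pool; haplogroup D4 among pooled patients.
PUBLISHED_RATIOS = {
    "m7b12_within_m7b_pooled": (44, 57),
    "heteroplasmic_11778_pooled": (1, 479),
    "F_in_han": (274, 1689),
    "D4_in_pooled_lhon": (98, 479),
}

#: cohort sizes: newly sequenced patients, pooled patients (new + previously
#: reported 175), suspected patients, general Han Chinese controls
COHORT_SIZES = {"lhon304": 304, "lhon_pooled": 479, "suspected": 843,
                "han": 1689}


def percent(numerator: int, denominator: int, digits: int = 2) -> float:
    return round(100.0 * numerator / denominator, digits)


def load_published_tables() -> pd.DataFrame:
    return pd.read_csv(_data_path("published_tables.tsv"), sep="\t", comment="#")


def row_table(row) -> ContingencyTable2x2:
    return ContingencyTable2x2(int(row.a), int(row.n_case - row.a),
                               int(row.c), int(row.n_control - row.c))


def table_for(comparison: str, haplogroup: str) -> ContingencyTable2x2:
    df = load_published_tables()
    row = df[(df.comparison == comparison) & (df.haplogroup == haplogroup)]
    if row.empty:
        raise KeyError(f"{haplogroup} not in {comparison}")
    return row_table(row.iloc[0])


def counts_for(comparison: str):
    """(case counts, n_case, control counts, n_control) for one comparison."""
    df = load_published_tables()
    sub = df[df.comparison == comparison]
    case = dict(zip(sub.haplogroup, sub.a.astype(int)))
    control = dict(zip(sub.haplogroup, sub.c.astype(int)))
    return case, int(sub.n_case.iloc[0]), control, int(sub.n_control.iloc[0])


def sweep_or_ci(tolerance: float = 5e-4, ulp_tolerance: float = 1.5e-3):
    """Recompute OR and Woolf CI for every published row from its counts.

    Returns a DataFrame with the computed values, absolute deviations from
    the printed values, and a ``reproduced`` flag at the note-dependent
    tolerance (strict printed-precision for ``ok`` rows; one printed ulp for
    ``rounding_ulp``; ``known_inconsistent`` rows are never expected to
    reproduce and are reported with their deviations).
    """
    rows = []
    for r in load_published_tables().itertuples():
        t = row_table(r)
        or_, lo, hi, fb = odds_ratio_ci(t)
        devs = (abs(round(or_, 3) - r.or_printed),
                abs(round(lo, 3) - r.ci_low_printed),
                abs(round(hi, 3) - r.ci_high_printed))
        tol = ulp_tolerance if r.note == "rounding_ulp" else tolerance
        rows.append({
            "comparison": r.comparison, "haplogroup": r.haplogroup,
            "note": r.note, "fallback": fb,
            "or_computed": round(or_, 3), "or_printed": r.or_printed,
            "ci_low_computed": round(lo, 3), "ci_high_computed": round(hi, 3),
            "max_abs_dev": max(devs),
            "reproduced": max(devs) <= tol,
        })
    return pd.DataFrame(rows)
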