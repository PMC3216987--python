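"""Case-control 2x2 statistics for haplogroup classes.

For each haplogroup class the cohorts yield a 2x2 table

    ``a`` cases carrying the class, ``b`` cases not carrying it,
    ``c`` controls carrying it,   ``d`` controls not carrying it.

The nominal test is Pearson's chi-square with 1 df, replaced by the two-tailed
Fisher exact test (point-probability definition) whenever any observed cell is
below five.  Effect size is the odds ratio with a Woolf (log-scale) 95% CI.
Family-wise multiplicity over the class list is addressed with single-step
min-p (Westfall-Young) permutation of cohort labels, cohort sizes fixed.

A single zero cell makes the odds ratio degenerate; such rows fall back to a
cohort relative risk of membership in the control group (see
:func:`odds_ratio_ci`), always flagged ``fallback_used``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

Z95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int  # cases with class
    b: int  # cases without
    c: int  # controls with class
    d: int  # controls without

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self):
        return (self.a, self.b, self.c, self.d)

    def transposed(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)

    def swapped_cohorts(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


def _chi2_stat(a, b, c, d, continuity=False):
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    diff = np.abs(a * d - b * c)
    if continuity:
        diff = np.maximum(0.0, diff - n / 2.0)
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(den > 0, n * diff * diff / den, np.nan)
    return stat


def pearson_chi2(t: ContingencyTable2x2, continuity: bool = False):
    """Pearson chi-square (1 df) statistic and upper-tail p.

    Requires all four margins positive; degenerate tables belong to Fisher.
    """
    a, b, c, d = t.cells
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("zero margin: use fisher_two_tailed for this table")
    stat = float(_chi2_stat(a, b, c, d, continuity))
    return stat, float(sps.chi2.sf(stat, df=1))


def _fisher_support_p(n_case: int, n_control: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p for every achievable ``a`` at fixed margins.

    Margins: cohort sizes ``n_case``/``n_control`` and carrier total ``m``.
    Returns (support values of a, p for each).  Point-probability definition:
    p = sum of hypergeometric probabilities of tables no more probable than
    the observed one.
    """
    N = n_case + n_control
    if N == 0:
        return np.array([0]), np.array([1.0])
    lo, hi = max(0, m - n_control), min(m, n_case)
    xs = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(xs, N, m, n_case)
    # tolerance guards ties against floating-point noise
    ps = np.array([pmf[pmf <= p * (1 + 1e-7)].sum() for p in pmf])
    return xs, np.minimum(ps, 1.0)


def fisher_two_tailed(t: ContingencyTable2x2) -> float:
    a, b, c, d = t.cells
    xs, ps = _fisher_support_p(a + b, c + d, a + c)
    return float(ps[a - xs[0]])


def choose_test(t: ContingencyTable2x2) -> str:
    """``fisher`` iff any observed cell is below five, else ``chi2``."""
    return "fisher" if min(t.cells) < 5 else "chi2"


def nominal_p(t: ContingencyTable2x2, continuity: bool = False) -> tuple[str, float]:
    method = choose_test(t)
    if method == "chi2":
        return method, pearson_chi2(t, continuity)[1]
    return method, fisher_two_tailed(t)


def odds_ratio_ci(t: ContingencyTable2x2, z: float = Z95):
    """Odds ratio with Woolf 95% CI; documented fallback for a single zero cell.

    With one zero cell the OR is 0 or infinite, so the published convention is
    reproduced instead: the cohort relative risk of control-group membership,
    e.g. for ``a == 0``  RR = [d/(b+d)] / [c/c] = d/(b+d), with log-scale CI
    standard error sqrt(1/d - 1/(b+d)) (the zero-count terms cancel).  The row
    is flagged ``fallback_used``.  Two or more zero cells: (nan, nan, nan).
    """
    a, b, c, d = t.cells
    zeros = sum(1 for x in t.cells if x == 0)
    if zeros == 0:
        or_ = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        return (or_, or_ * math.exp(-z * se), or_ * math.exp(z * se), False)
    if zeros >= 2:
        return (math.nan, math.nan, math.nan, True)
    if a == 0:
        rr, se = d / (b + d), math.sqrt(1 / d - 1 / (b + d))
    elif c == 0:
        rr, se = b / (b + d), math.sqrt(1 / b - 1 / (b + d))
    elif b == 0:
        rr, se = c / (a + c), math.sqrt(1 / c - 1 / (a + c))
    else:  # d == 0
        rr, se = a / (a + c), math.sqrt(1 / a - 1 / (a + c))
    return (rr, rr * math.exp(-z * se), rr * math.exp(z * se), True)


# ---------------------------------------------------------------------------
# per-sample datasets


@dataclass
class CohortDataset:
    """Per-sample class memberships for one cohort.

    ``membership`` is an (n_samples x n_classes) boolean array; nested classes
    are simply multiple true columns for the same sample.
    """

    name: str
    sample_ids: list[str]
    classes: list[str]
    membership: np.ndarray

    def __post_init__(self):
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != (len(self.sample_ids), len(self.classes)):
            raise ValueError("membership shape mismatch")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def class_counts(self) -> dict[str, int]:
        sums = self.membership.sum(axis=0)
        return {c: int(k) for c, k in zip(self.classes, sums)}


def dataset_from_assignments(name, assignments, tree, classes) -> CohortDataset:
    """Build a dataset from classification results and the haplogroup tree."""
    ids = [r.sample_id for r in assignments]
    mem = np.zeros((len(ids), len(classes)), dtype=bool)
    for i, r in enumerate(assignments):
        for j, c in enumerate(classes):
            mem[i, j] = tree.is_descendant(r.best_haplogroup, c)
    return CohortDataset(name, ids, list(classes), mem)


def dataset_from_counts(name, counts: dict[str, int], n: int, tree,
                        classes) -> CohortDataset:
    """Reconstruct a per-sample membership matrix from published class counts.

    Nested classes are resolved through the tree: the count of a class is
    split into samples whose deepest listed class is that class versus its
    listed descendants.  The reconstruction is exact for count purposes
    (column sums equal the given counts), which is all that label permutation
    needs.
    """
    classes = list(classes)
    for c in classes:
        if c not in tree:
            raise KeyError(f"unknown class {c!r}")
    # direct count = count(c) minus counts of listed classes whose nearest
    # listed ancestor is c
    def nearest_listed_ancestor(c):
        node = tree[c].parent
        while node is not None:
            if node.name in classes:
                return node.name
            node = node.parent
        return None

    direct = dict(counts)
    for c in classes:
        anc = nearest_listed_ancestor(c)
        if anc is not None:
            direct[anc] -= counts[c]
    if any(v < 0 for v in direct.values()):
        raise ValueError("inconsistent nested counts")
    rows, ids = [], []
    k = 0
    for c in classes:
        ancset = {x for x in classes if tree.is_descendant(c, x)}
        row = np.array([x in ancset for x in classes], dtype=bool)
        for _ in range(direct[c]):
            rows.append(row)
            ids.append(f"{name}_{k:05d}")
            k += 1
    n_rest = n - len(rows)
    if n_rest < 0:
        raise ValueError(f"counts exceed cohort size {n}")
    empty = np.zeros(len(classes), dtype=bool)
    for _ in range(n_rest):
        rows.append(empty)
        ids.append(f"{name}_{k:05d}")
        k += 1
    return CohortDataset(name, ids, classes, np.array(rows))


def pool(ds1: CohortDataset, ds2: CohortDataset, name=None) -> CohortDataset:
    """Concatenate two disjoint cohorts over the same class universe."""
    if ds1.classes != ds2.classes:
        raise ValueError("class universes differ")
    if ds2.n == 0:
        return CohortDataset(name or ds1.name, list(ds1.sample_ids), ds1.classes,
                             ds1.membership.copy())
    clash = set(ds1.sample_ids) & set(ds2.sample_ids)
    if clash:
        raise ValueError(f"sample id collision: {sorted(clash)[:5]}")
    return CohortDataset(name or f"{ds1.name}+{ds2.name}",
                         ds1.sample_ids + ds2.sample_ids, ds1.classes,
                         np.vstack([ds1.membership, ds2.membership]))


# ---------------------------------------------------------------------------
# permutation adjustment


def _class_p_lookup(n_case: int, n_control: int, m: int,
                    continuity: bool = False) -> np.ndarray:
    """Nominal p for every possible case-carrier count ``a`` of one class.

    Entry ``a`` of the returned array is the p-value of the table
    (a, n_case-a, m-a, n_control-m+a) under the chi2/Fisher selection rule;
    unachievable ``a`` get p = 1.
    """
    lookup = np.ones(m + 1 if m <= n_case else n_case + 1)
    xs, fisher_ps = _fisher_support_p(n_case, n_control, m)
    a = xs
    b, c, d = n_case - a, m - a, n_control - (m - a)
    chi2_stat = _chi2_stat(a, b, c, d, continuity)
    chi2_ps = sps.chi2.sf(chi2_stat, df=1)
    use_fisher = np.minimum.reduce([a, b, c, d]) < 5
    ps = np.where(use_fisher | ~np.isfinite(chi2_ps), fisher_ps, chi2_ps)
    lookup = np.ones(int(xs[-1]) + 1)
    lookup[xs] = ps
    return lookup


def permutation_adjust(case: CohortDataset, control: CohortDataset,
                       B: int = 100_000, seed: int | None = 0,
                       continuity: bool = False, batch: int = 512):
    """Single-step min-p (Westfall-Young) adjusted p-values.

    Cohort labels are permuted with cohort sizes fixed; each permutation
    recomputes every class's nominal p with the same chi2/Fisher selection
    rule, and the family minimum is compared against each observed p:

        adjusted_p = (1 + #{b: min_j p_jb <= p_obs}) / (B + 1)

    Values are clipped from below at the observed nominal p so the invariant
    ``adjusted >= nominal`` holds exactly.  Returns (nominal, adjusted,
    at_floor) arrays; ``at_floor`` marks classes never reached by a permuted
    minimum, whose adjusted p is the estimator floor 1/(B+1) and is reported
    downstream as "< 1/B".
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if case.classes != control.classes or not case.classes:
        raise ValueError("cohorts must share a non-empty class list")
    rng = np.random.default_rng(seed)
    K = len(case.classes)
    n1, n2 = case.n, control.n
    M = np.vstack([case.membership, control.membership]).astype(np.int64)
    m_tot = M.sum(axis=0)

    lookups = [_class_p_lookup(n1, n2, int(m), continuity) for m in m_tot]
    a_obs = case.membership.sum(axis=0)
    p_obs = np.array([lookups[j][int(a_obs[j])] for j in range(K)])

    exceed = np.zeros(K, dtype=np.int64)
    done = 0
    n = n1 + n2
    while done < B:
        nb = min(batch, B - done)
        # nb random case/control label assignments with case size fixed
        keys = rng.random((nb, n))
        idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        A = M[idx].sum(axis=1)  # (nb, K) permuted case-carrier counts
        pmin = np.ones(nb)
        for j in range(K):
            pmin = np.minimum(pmin, lookups[j][A[:, j]])
        exceed += (pmin[:, None] <= p_obs[None, :] * (1 + 1e-12)).sum(axis=0)
        done += nb
    adjusted = (1 + exceed) / (B + 1)
    at_floor = exceed == 0
    adjusted = np.maximum(adjusted, p_obs)
    return p_obs, adjusted, at_floor


# ---------------------------------------------------------------------------
# the full association suite


@dataclass
class AssociationRow:
    haplogroup: str
    table: ContingencyTable2x2
    method: str
    nominal_p: float
    adjusted_p: float | None
    adjusted_floor: bool
    or_value: float
    ci_low: float
    ci_high: float
    fallback_used: bool
    significant: bool

    @property
    def adjusted_p_display(self) -> str:
        if self.adjusted_p is None:
            return ""
        if self.adjusted_floor:
            b_used = round(1 / self.adjusted_p) - 1  # adjusted is 1/(B+1) at the floor
            return f"<{1.0 / b_used:.0e}"
        return f"{self.adjusted_p:.3g}"


def run_association_suite(case: CohortDataset, control: CohortDataset,
                          B: int = 100_000, seed: int | None = 0,
                          continuity: bool = False,
                          permute: bool = True) -> list[AssociationRow]:
    """One AssociationRow per class, mirroring the published table columns."""
    classes = case.classes
    if control.classes != classes:
        raise ValueError("cohorts must share the class list")
    counts_case = case.class_counts()
    counts_control = control.class_counts()
    if permute:
        p_obs, adj, floor = permutation_adjust(case, control, B=B, seed=seed,
                                               continuity=continuity)
    rows = []
    for j, cname in enumerate(classes):
        a, c = counts_case[cname], counts_control[cname]
        t = ContingencyTable2x2(a, case.n - a, c, control.n - c)
        method, p = nominal_p(t, continuity)
        or_, lo, hi, fb = odds_ratio_ci(t)
        adj_p = float(adj[j]) if permute else None
        adj_floor = bool(floor[j]) if permute else False
        sig = permute and adj_p is not None and adj_p < 0.05
        rows.append(AssociationRow(cname, t, method, p, adj_p, adj_floor,
                                   or_, lo, hi, fb, sig))
    return rows


def association_frame(rows):
    import pandas as pd

    return pd.DataFrame([{
        "Haplogroup": r.haplogroup,
        "n_case": r.table.a, "n_control": r.table.c,
        "P": r.nominal_p,
        "adjusted_P": r.adjusted_p_display,
        "OR": round(r.or_value, 3) if np.isfinite(r.or_value) else "NA",
        "CI_low": round(r.ci_low, 3) if np.isfinite(r.ci_low) else "NA",
        "CI_high": round(r.ci_high, 3) if np.isfinite(r.ci_high) else "NA",
        "method": r.method,
        "fallback": r.fallback_used,
        "significant": r.significant,
    } for r in rows])


# ---------------------------------------------------------------------------
# power


def power_simulation(p_case: float, p_control: float, n_case: int,
                     n_control: int, alpha: float = 0.05, reps: int = 2000,
                     seed: int | None = 0) -> float:
    """Monte-Carlo power of the chi2/Fisher selection rule.

    Per-cohort carrier counts are drawn binomially at the stated class
    frequencies; power is the fraction of replicates with nominal p < alpha.
    """
    if not (0 <= p_case <= 1 and 0 <= p_control <= 1):
        raise ValueError("frequencies must be in [0, 1]")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    a = rng.binomial(n_case, p_case, size=reps)
    c = rng.binomial(n_control, p_control, size=reps)
    b, d = n_case - a, n_control - c
    chi2_ps = sps.chi2.sf(_chi2_stat(a, b, c, d), df=1)
    need_fisher = (np.minimum.reduce([a, b, c, d]) < 5) | ~np.isfinite(chi2_ps)
    ps = np.where(need_fisher, 1.0, chi2_ps)
    if need_fisher.any():
        cache: dict[tuple, float] = {}
        idx = np.flatnonzero(need_fisher)
        for i in idx:
            key = (int(a[i]), int(c[i]))
            if key not in cache:
                cache[key] = fisher_two_tailed(
                    ContingencyTable2x2(int(a[i]), int(b[i]), int(c[i]), int(d[i])))
            ps[i] = cache[key]
    return float((ps < alpha).mean())
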