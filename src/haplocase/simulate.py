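"""Synthetic cohorts with the statistical structure the pipeline assumes.

Raw per-sample patient data live in sequence archives, so every stage of the
pipeline is exercised against simulated cohorts instead: each sample draws a
haplogroup from a population frequency vector (cases from an odds-tilted
copy), its profile is the drawn clade's full defining path plus a Poisson
number of private substitutions at positions no motif uses, and sequences are
emitted by mutating the rCRS region accordingly (optionally with C-tract
length noise, which the caller is expected to mask again).

Default control frequencies follow the general Han Chinese haplogroup
distribution (n = 1,689) resolved to the terminal classes of the bundled
tree; the "N" entry absorbs the lineages outside the tabulated classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .reference import ReferenceGenome, VariantCall
from .calling import (
    DEFAULT_REGION,
    HaplotypeProfile,
    apply_profile,
    in_ctract_window,
    _region_positions,
)
from .haplotree import HaploTree

#: terminal-class frequencies of the general Han Chinese population (n=1689):
#: published class counts resolved to direct (deepest-listed-class) counts.
HAN_TERMINAL_COUNTS = {
    "A": 92, "B4": 196, "B5": 94, "C": 51, "D4": 252, "D5": 88,
    "R9": 31, "F": 10, "F1": 61, "F1a": 132, "F2": 26, "F2a": 22,
    "F3": 2, "F3a": 13, "F4": 8, "G": 71, "M10": 35, "M12": 4,
    "M7b": 119, "M7c": 54, "M8a": 63, "M9a": 29, "N9a": 62,
    "R11": 10, "Y": 16, "Z": 50,
}
#: lineages outside the tabulated classes (98/1689) fall through to the
#: remainder draw, which maps to the tree root ("other").
HAN_N = 1689


def han_terminal_frequencies() -> dict[str, float]:
    return {k: v / HAN_N for k, v in HAN_TERMINAL_COUNTS.items()}


@dataclass
class SimulationConfig:
    control_freqs: dict[str, float] = field(default_factory=han_terminal_frequencies)
    or_map: dict[str, float] = field(default_factory=dict)
    n_case: int = 500
    n_control: int = 1500
    private_rate: float = 1.0  # Poisson mean private substitutions per sample
    ctract_noise_p: float = 0.2  # probability of +1C length noise at 309
    region: tuple = DEFAULT_REGION
    seed: int = 0

    def __post_init__(self):
        total = sum(self.control_freqs.values())
        if total > 1 + 1e-9 or any(f < 0 for f in self.control_freqs.values()):
            raise ValueError("control frequencies must be non-negative, sum <= 1")
        if any(r <= 0 for r in self.or_map.values()):
            raise ValueError("odds multipliers must be positive")
        unknown = set(self.or_map) - set(self.control_freqs)
        if unknown:
            raise ValueError(f"or_map classes not in control_freqs: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "region" in raw:
            raw["region"] = tuple(tuple(iv) for iv in raw["region"])
        return cls(**raw)


def case_frequencies(cfg: SimulationConfig) -> dict[str, float]:
    """Case draw vector: odds of each or_map class multiplied by its factor
    (keeping the marginal odds ratio exact), remaining mass rescaled."""
    p = dict(cfg.control_freqs)
    tilted = {}
    for cls_, orr in cfg.or_map.items():
        odds = orr * p[cls_] / (1 - p[cls_])
        tilted[cls_] = odds / (1 + odds)
    rest = 1 - sum(tilted.values())
    if rest <= 0:
        raise ValueError("tilted frequencies exceed 1; lower the odds multipliers")
    base_rest = sum(v for k, v in p.items() if k not in tilted)
    scale = rest / (1 - sum(p[k] for k in tilted)) if base_rest else 0.0
    out = {}
    for k, v in p.items():
        out[k] = tilted.get(k, v * scale)
    return out


def _draw_classes(rng, freqs: dict[str, float], n: int) -> list[str]:
    names = sorted(freqs)
    probs = np.array([freqs[k] for k in names], dtype=float)
    slack = 1 - probs.sum()
    if slack > 1e-12:  # remainder of the frequency map -> tree root ("other")
        names.append("__other__")
        probs = np.append(probs, slack)
    probs = probs / probs.sum()
    return list(rng.choice(names, p=probs, size=n))


def _path_calls(tree: HaploTree, name: str) -> list[VariantCall]:
    if name == "__other__":
        return []
    calls, seen = [], set()
    for m in tree[name].path_motifs():
        if m.back_mutation:
            seen.discard(m.call.key)
            calls = [c for c in calls if c.key != m.call.key]
            continue
        if m.call.key not in seen:
            calls.append(m.call)
            seen.add(m.call.key)
    return calls


def simulate_assignments(cfg: SimulationConfig, rng=None):
    """Haplogroup draws only (no profiles): ``(labels, truth_by_sample)``.

    The cheap path for sampling-distribution studies where only the class
    counts matter; :func:`simulate_cohort` adds the per-sample profiles.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    control_f = dict(cfg.control_freqs)
    case_f = case_frequencies(cfg) if cfg.or_map else control_f
    draws = (_draw_classes(rng, case_f, cfg.n_case)
             + _draw_classes(rng, control_f, cfg.n_control))
    labels, truth = {}, {}
    for i, hap in enumerate(draws):
        cohort = "case" if i < cfg.n_case else "control"
        sid = f"{'LE' if cohort == 'case' else 'HN'}{i:05d}"
        labels[sid] = cohort
        truth[sid] = hap
    return labels, truth


def simulate_cohort(cfg: SimulationConfig, tree: HaploTree,
                    ref: ReferenceGenome, rng=None):
    """Draw the two cohorts.

    Returns ``(profiles, labels, truth)``: per-sample variant profiles,
    ``{sample_id: "case"|"control"}``, and ``{sample_id: true haplogroup}``.
    Fully reproducible from ``cfg.seed``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    missing = [c for c in cfg.control_freqs if c != "__other__" and c not in tree]
    if missing:
        raise ValueError(f"classes not in tree: {missing}")

    region_pos = _region_positions(cfg.region)
    motif_pos = tree.motif_positions()
    candidates = [p for p in region_pos
                  if p not in motif_pos and p != 3107
                  and not in_ctract_window(p)]

    labels, assignments = simulate_assignments(cfg, rng)
    profiles, truth = [], {}
    bases = "ACGT"
    for sid, hap in assignments.items():
        # only the sequenced region is observable on the emitted profile
        calls = [c for c in _path_calls(tree, hap)
                 if any(lo <= c.position <= hi for lo, hi in cfg.region)]
        taken = {c.position for c in calls}
        k = rng.poisson(cfg.private_rate)
        if k:
            free = [p for p in candidates if p not in taken]
            for pos in rng.choice(free, size=min(k, len(free)), replace=False):
                pos = int(pos)
                refbase = ref.base(pos)
                alt = bases[int(rng.integers(0, 4))]
                while alt == refbase:
                    alt = bases[int(rng.integers(0, 4))]
                calls.append(VariantCall(pos, refbase, alt, "substitution"))
        profiles.append(HaplotypeProfile(sid, tuple(calls), region=cfg.region,
                                         source="called", cohort=labels[sid]))
        truth[sid] = tree.root.name if hap == "__other__" else hap
    return profiles, labels, truth


def emit_fasta_records(profiles, ref: ReferenceGenome, cfg: SimulationConfig,
                       rng=None):
    """Sequences for the simulated profiles, with optional C-tract length noise
    (an extra C inside the 303-309 run) that variant calling is expected to mask."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    records = []
    positions = _region_positions(cfg.region)
    try:
        run_end = positions.index(309)
    except ValueError:
        run_end = None
    for p in profiles:
        seq = apply_profile(p, ref, cfg.region)
        if run_end is not None and rng.random() < cfg.ctract_noise_p:
            # sequence index of 309 shifts with upstream indels; recompute naively
            seq = seq.replace("CCCCCCCT", "CCCCCCCCT", 1)
        records.append((p.sample_id, seq))
    return records


def simulate_ortholog_alignment(ref: ReferenceGenome, start: int, length: int,
                                n_species: int = 43,
                                conservation: dict[int, float] | float = 0.8,
                                exact_counts: dict[int, int] | None = None,
                                seed: int | None = 0):
    """Synthetic ortholog alignment over an rCRS window.

    The human row is the rCRS slice; each species matches the human state at a
    position with the requested conservation probability, else shows a
    uniformly random different base.  ``exact_counts`` pins the number of
    matching species at chosen positions (deterministic rows 1..k match).
    """
    from .phylo import OrthologAlignment

    rng = np.random.default_rng(seed)
    human = ref.slice(start, start + length - 1)
    cons = conservation if isinstance(conservation, dict) else {}
    default_c = conservation if not isinstance(conservation, dict) else 0.8
    exact_counts = exact_counts or {}
    rows = []
    bases = "ACGT"
    for s in range(n_species):
        row = []
        for i, h in enumerate(human):
            pos = start + i
            if pos in exact_counts:
                match = s < exact_counts[pos]
            else:
                match = rng.random() < cons.get(pos, default_c)
            if match or h not in bases:
                row.append(h)
            else:
                alts = [b for b in bases if b != h]
                row.append(alts[int(rng.integers(0, 3))])
        rows.append("".join(row))
    names = ["human_rCRS"] + [f"species_{s + 1:02d}" for s in range(n_species)]
    return OrthologAlignment(names, [human] + rows, start=start)
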