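"""Derive per-sample variant profiles from raw sequence by alignment to the rCRS.

The sequencing design this mirrors reads an ~1.4 kb fragment spanning the
control region across the origin of the circular genome (rCRS 16033-16569
joined to 1-850).  Circularity is handled by linearising the declared region
(concatenating its intervals) before alignment.  Length variation of the
homopolymeric C-tracts (around 303-315 and 16184-16193) is conventionally
ignored in mtDNA haplotyping and is suppressed here; point substitutions
inside those windows are still reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .reference import (
    ReferenceGenome,
    VariantCall,
    TokenError,
    parse_variant_token,
    format_variant,
)

#: default sequencing window: control region + MT-TF + 5' part of MT-RNR1
DEFAULT_REGION = ((16033, 16569), (1, 850))

#: indel mask windows: C-tract length polymorphisms are not called
CTRACT_WINDOWS = ((302, 316), (16183, 16194))


def _region_positions(region) -> list[int]:
    pos = []
    for lo, hi in region:
        pos.extend(range(lo, hi + 1))
    return pos


def circular_sort_key(region):
    """Sort key ordering variants along the declared region intervals."""
    order = {}
    for i, p in enumerate(_region_positions(region)):
        order.setdefault(p, i)

    def key(v: VariantCall):
        return (order.get(v.position, v.position + 10 ** 6), v.insertion_index)

    return key


@dataclass
class HaplotypeProfile:
    """A sample's variant set over a stated region of the circular rCRS."""

    sample_id: str
    variants: tuple[VariantCall, ...]
    region: tuple = DEFAULT_REGION
    source: str = "called"
    cohort: str | None = None
    uncovered: tuple = ()  # intervals with no sequence coverage

    def __post_init__(self):
        for v in self.variants:
            if not any(lo <= v.position <= hi for lo, hi in self.region):
                raise ValueError(
                    f"variant {format_variant(v)} outside declared region {self.region}")
        self.variants = tuple(sorted(self.variants, key=circular_sort_key(self.region)))
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate variants in profile {self.sample_id}")

    @property
    def positions(self) -> set[int]:
        return {v.position for v in self.variants}

    def tokens(self, dialect: str = "auto") -> list[str]:
        return [format_variant(v, dialect) for v in self.variants]


def in_ctract_window(position: int) -> bool:
    return any(lo <= position <= hi for lo, hi in CTRACT_WINDOWS)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    # affine: opening a gap of length k costs 4 + k
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    # free end gaps: sequences may carry primer slack or fall short of the region
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older biopython naming
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def apply_profile(profile: HaplotypeProfile, ref: ReferenceGenome,
                  region=None) -> str:
    """Mutate the reference region by the profile's variants (simulator inverse
    of :func:`call_variants`)."""
    region = region or profile.region
    positions = _region_positions(region)
    by_pos: dict[int, list[VariantCall]] = {}
    for v in profile.variants:
        by_pos.setdefault(v.position, []).append(v)
    out = []
    for p in positions:
        base = ref.base(p)
        events = by_pos.get(p, [])
        subs = [v for v in events if v.vtype == "substitution"]
        dels = [v for v in events if v.vtype == "deletion"]
        ins = sorted((v for v in events if v.vtype == "insertion"),
                     key=lambda v: v.insertion_index)
        if dels:
            base = ""
        elif subs:
            base = subs[0].alt
        out.append(base + "".join(v.alt for v in ins))
    return "".join(out)


def call_variants(seq: str, ref: ReferenceGenome, region=DEFAULT_REGION,
                  sample_id: str = "sample", mask_ctracts: bool = True) -> HaplotypeProfile:
    """Call substitutions and indels in ``seq`` against the rCRS region.

    Global affine-gap alignment on the linearised region; indels are
    normalised to their 3'-most equivalent placement; C-tract length variants
    are suppressed unless ``mask_ctracts`` is false.  Uncovered flanks of the
    region are recorded on the profile rather than raising.
    """
    seq = seq.strip().upper()
    if not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    positions = _region_positions(region)
    ref_region = "".join(ref.base(p) for p in positions)
    if not 0.8 * len(ref_region) <= len(seq) <= 1.2 * len(ref_region):
        raise ValueError(
            f"sequence length {len(seq)} outside 0.8-1.2x of region length {len(ref_region)}")

    aligner = _make_aligner()
    aln = aligner.align(ref_region, seq)[0]
    tcoords, qcoords = aln.aligned  # aligned blocks (target, query)

    variants: list[VariantCall] = []
    covered_lo = tcoords[0][0] if len(tcoords) else 0
    covered_hi = tcoords[-1][1] if len(tcoords) else 0

    # substitutions within aligned blocks
    for (ts, te), (qs, qe) in zip(tcoords, qcoords):
        for i in range(te - ts):
            rb, qb = ref_region[ts + i], seq[qs + i]
            pos = positions[ts + i]
            if qb == rb or qb == "N" or rb == "N":
                continue
            variants.append(VariantCall(pos, rb, qb, "substitution"))

    # indels between consecutive blocks
    for k in range(len(tcoords) - 1):
        t_gap = (tcoords[k][1], tcoords[k + 1][0])
        q_gap = (qcoords[k][1], qcoords[k + 1][0])
        if t_gap[1] > t_gap[0] and q_gap[1] == q_gap[0]:
            # deletion of ref bases t_gap[0]..t_gap[1]-1 ; 3'-shift within homopolymer
            start, length = t_gap[0], t_gap[1] - t_gap[0]
            while (start + length < len(ref_region)
                   and ref_region[start] == ref_region[start + length]):
                start += 1
            for i in range(length):
                idx = start + i
                pos = positions[idx]
                if ref_region[idx] == "N":
                    continue
                if mask_ctracts and in_ctract_window(pos) and ref_region[idx] == "C":
                    continue
                variants.append(VariantCall(pos, ref_region[idx], "", "deletion"))
        elif q_gap[1] > q_gap[0] and t_gap[1] == t_gap[0]:
            # insertion of query bases after ref position index t_gap[0]-1; 3'-shift
            qstart, length = q_gap[0], q_gap[1] - q_gap[0]
            tpos = t_gap[0]
            ins = seq[qstart:qstart + length]
            while tpos < len(ref_region) and ref_region[tpos] == ins[0]:
                ins = ins[1:] + ins[0]
                tpos += 1
            anchor_idx = tpos - 1
            if anchor_idx < 0:
                continue  # insertion before the region start: unplaceable
            pos = positions[anchor_idx]
            if mask_ctracts and in_ctract_window(pos) and set(ins) == {"C"}:
                continue
            for j, b in enumerate(ins, start=1):
                variants.append(VariantCall(pos, "", b, "insertion", j))
        # (substitution-adjacent double gaps are rare under affine scoring; each
        # side is handled independently by the two branches above)

    uncovered = []
    if covered_lo > 0:
        uncovered.append((positions[0], positions[covered_lo - 1]))
    if covered_hi < len(positions):
        uncovered.append((positions[covered_hi], positions[-1]))

    return HaplotypeProfile(sample_id, tuple(variants), region=region,
                            source="called", uncovered=tuple(uncovered))


def import_profiles(table_path, ref: ReferenceGenome,
                    region=DEFAULT_REGION) -> list[HaplotypeProfile]:
    """Read a profile table: ``sample_id<TAB>variant tokens[<TAB>cohort]``.

    Tokens are whitespace-separated, validated against the reference; any
    invalid token raises, naming the sample and the offending token.
    """
    df = pd.read_csv(table_path, sep="\t", dtype=str, comment="#").fillna("")
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "variants" not in cols:
        raise ValueError("profile table needs columns: sample_id, variants[, cohort]")
    if df[cols["sample_id"]].duplicated().any():
        dupes = df[cols["sample_id"]][df[cols["sample_id"]].duplicated()].tolist()
        raise ValueError(f"duplicated sample_id(s): {dupes}")
    profiles = []
    for _, row in df.iterrows():
        sid = row[cols["sample_id"]]
        calls = []
        for tok in str(row[cols["variants"]]).split():
            try:
                calls.append(parse_variant_token(tok, ref))
            except TokenError as exc:
                raise TokenError(f"sample {sid}: invalid token {tok!r}: {exc}") from exc
        cohort = row[cols["cohort"]] if "cohort" in cols else None
        profiles.append(HaplotypeProfile(sid, tuple(calls), region=region,
                                         source="imported", cohort=cohort or None))
    return profiles


def export_profiles(profiles, path, dialect: str = "auto") -> None:
    rows = [{"sample_id": p.sample_id,
             "variants": " ".join(p.tokens(dialect)),
             "cohort": p.cohort or ""} for p in profiles]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
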