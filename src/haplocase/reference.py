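"""rCRS reference handling, variant nomenclature, gene map and functional annotation.

The human mitochondrial genome is numbered against the revised Cambridge
Reference Sequence (rCRS, 16,569 bp, circular).  Variants are recorded as
single-position events relative to that coordinate system, in the token
dialects customary in mtDNA population genetics:

* HGVS-like: ``m.11778G>A``, ``m.249delA``
* ref-position-alt: ``A14978G``
* control-region shorthand: ``16223T`` (position + derived base), ``249d``
  (deletion), ``309.1C`` (insertion, ``.1`` = first inserted base)

A trailing lowercase base or an IUPAC ambiguity code marks heteroplasmy; the
flag is carried on the call but never changes identity comparisons.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio import SeqIO

RCRS_LENGTH = 16569
#: rCRS position whose reference state is the placeholder 'N'; never a variant site.
PLACEHOLDER_POSITION = 3107

_IUPAC = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
}

_PURE = "ACGT"


class TokenError(ValueError):
    """Raised for a variant token that cannot be parsed or validated."""


@dataclass(frozen=True)
class VariantCall:
    """One nucleotide change relative to the rCRS.

    ``insertion_index`` is the 1-based index of an inserted base after
    ``position`` (the ``.1`` in ``309.1C``); it is 0 for non-insertions.
    """

    position: int
    ref: str
    alt: str
    vtype: str  # substitution | deletion | insertion
    insertion_index: int = 0
    heteroplasmic: bool = False

    def __post_init__(self):
        if not 1 <= self.position <= RCRS_LENGTH:
            raise TokenError(f"position {self.position} outside 1..{RCRS_LENGTH}")
        if self.vtype == "substitution":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise TokenError(f"bad substitution {self.ref}>{self.alt} at {self.position}")
        elif self.vtype == "deletion":
            if self.alt != "":
                raise TokenError("deletion must have empty alt")
        elif self.vtype == "insertion":
            if self.ref != "" or self.insertion_index < 1:
                raise TokenError("insertion must have empty ref and index >= 1")
        else:
            raise TokenError(f"unknown vtype {self.vtype!r}")

    @property
    def key(self):
        """Identity of the event, ignoring heteroplasmy."""
        return (self.position, self.insertion_index, self.ref, self.alt, self.vtype)

    def same_event(self, other: "VariantCall") -> bool:
        return self.key == other.key

    def __str__(self) -> str:
        return format_variant(self)


@dataclass(frozen=True)
class GeneFeature:
    gene: str
    start: int
    end: int
    kind: str  # protein | rRNA | tRNA | control
    strand: str  # H | L
    frame_offset: int = 0

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GeneMap:
    """Feature lookup over the 37 mitochondrial genes plus the control region."""

    def __init__(self, features: Sequence[GeneFeature]):
        self.features = list(features)
        names = {f.gene for f in self.features}
        required = {"MT-ND6", "MT-ATP6", "MT-CO1", "MT-RNR1", "MT-TF", "MT-CR"}
        missing = required - names
        if missing:
            raise ValueError(f"gene map incomplete, missing {sorted(missing)}")

    def overlapping(self, position: int) -> list[GeneFeature]:
        """Every feature covering ``position`` (features may overlap)."""
        return [f for f in self.features if position in f]

    def primary(self, position: int) -> GeneFeature | None:
        """The feature used for annotation: protein first, then RNA, then control."""
        rank = {"protein": 0, "rRNA": 1, "tRNA": 1, "control": 2}
        hits = sorted(self.overlapping(position), key=lambda f: (rank[f.kind], f.start))
        return hits[0] if hits else None

    @classmethod
    def from_tsv(cls, path) -> "GeneMap":
        feats = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("gene\t"):
                    continue
                gene, start, end, kind, strand, off = line.split("\t")
                feats.append(GeneFeature(gene, int(start), int(end), kind, strand, int(off)))
        return cls(feats)


@dataclass
class ReferenceGenome:
    name: str
    sequence: str
    accession: str
    gene_map: GeneMap | None = None

    def base(self, position: int) -> str:
        """Reference base at a 1-based rCRS position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside reference")
        return self.sequence[position - 1]

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive slice; ``start > end`` wraps around the origin."""
        if start <= end:
            return self.sequence[start - 1:end]
        return self.sequence[start - 1:] + self.sequence[:end]


def _data_path(name: str) -> Path:
    return Path(resources.files("haplocase.data") / name)


def load_reference() -> ReferenceGenome:
    """Load the bundled rCRS with its gene map attached.

    Raises ``ValueError`` if the bundled fixture is corrupted (wrong length or
    placeholder base), rather than returning a silently broken reference.
    """
    records = read_fasta(_data_path("rCRS.fasta"))
    (rid, seq), = records
    if len(seq) != RCRS_LENGTH:
        raise ValueError(
            f"corrupted rCRS fixture: length {len(seq)}, expected {RCRS_LENGTH}")
    if seq[PLACEHOLDER_POSITION - 1] != "N":
        raise ValueError("corrupted rCRS fixture: placeholder N missing at 3107")
    if not set(seq) <= set("ACGTN"):
        raise ValueError("corrupted rCRS fixture: non-nucleotide characters")
    gene_map = GeneMap.from_tsv(_data_path("rcrs_gene_map.tsv"))
    return ReferenceGenome("rCRS", seq, "NC_012920.1", gene_map)


# ---------------------------------------------------------------------------
# variant tokens


def _base_and_het(raw: str, position: int, reference: ReferenceGenome | None):
    """Resolve an alt-base character: lowercase or IUPAC code => heteroplasmic."""
    het = raw.islower() or raw.upper() in _IUPAC
    b = raw.upper()
    if b in _IUPAC:
        if reference is None:
            raise TokenError(f"IUPAC code {raw!r} needs a reference to resolve")
        ref = reference.base(position)
        alts = [x for x in _IUPAC[b] if x != ref]
        if len(alts) != 1:
            raise TokenError(f"ambiguity code {raw!r} at {position} does not include "
                             f"the reference base {ref}")
        return alts[0], True
    if b not in _PURE:
        raise TokenError(f"not a nucleotide: {raw!r}")
    return b, het


def parse_variant_token(token: str, reference: ReferenceGenome | None = None) -> VariantCall:
    """Parse a variant token in any accepted dialect into a canonical call.

    When a ``reference`` is given, shorthand refs are filled from it and
    explicit refs are validated against it.
    """
    t = token.strip()
    if not t:
        raise TokenError("empty variant token")
    body = t[2:] if t.startswith("m.") else t

    def need_ref() -> ReferenceGenome:
        if reference is None:
            raise TokenError(f"token {token!r} needs a reference sequence")
        return reference

    def check_pos(pos: int):
        if not 1 <= pos <= RCRS_LENGTH:
            raise TokenError(f"token {token!r}: position {pos} outside 1..{RCRS_LENGTH}")
        return pos

    def check_ref(pos: int, ref: str):
        if reference is not None and reference.base(pos) != ref:
            raise TokenError(
                f"token {token!r}: stated ref {ref} != rCRS base "
                f"{reference.base(pos)} at {pos}")

    # insertion: 309.1C
    if "." in body:
        posidx, _, basepart = body.partition(".")
        try:
            idxstr = "".join(ch for ch in basepart if ch.isdigit())
            idx = int(idxstr) if idxstr else 0
            alt_raw = basepart[len(idxstr):]
            pos = check_pos(int(posidx))
        except ValueError as exc:
            raise TokenError(f"cannot parse insertion token {token!r}") from exc
        if idx < 1 or len(alt_raw) != 1:
            raise TokenError(f"cannot parse insertion token {token!r}")
        alt, het = _base_and_het(alt_raw, pos, reference)
        return VariantCall(pos, "", alt, "insertion", idx, het)

    # deletion: 249delA / 249del / 249d
    low = body.lower()
    for marker in ("dela", "delc", "delg", "delt", "del", "d"):
        if low.endswith(marker) and low[:-len(marker)].isdigit():
            pos = check_pos(int(low[:-len(marker)]))
            stated = marker[3:].upper() if marker.startswith("del") and len(marker) == 4 else ""
            if stated:
                check_ref(pos, stated)
            ref = stated or (need_ref().base(pos) if reference is not None else "?")
            if reference is not None:
                ref = reference.base(pos)
            if ref == "?":
                raise TokenError(f"token {token!r} needs a reference sequence")
            return VariantCall(pos, ref, "", "deletion")

    # HGVS-like substitution: 11778G>A
    if ">" in body:
        left, _, alt_raw = body.partition(">")
        if len(left) < 2 or not left[:-1].isdigit() or len(alt_raw) != 1:
            raise TokenError(f"cannot parse token {token!r}")
        pos, ref = check_pos(int(left[:-1])), left[-1].upper()
        check_ref(pos, ref)
        alt, het = _base_and_het(alt_raw, pos, reference)
        if alt == ref:
            raise TokenError(f"token {token!r}: alt equals ref")
        return VariantCall(pos, ref, alt, "substitution", 0, het)

    # ref-position-alt: A14978G
    if body[0].upper() in _PURE and body[1:-1].isdigit() and len(body) >= 3:
        ref, pos = body[0].upper(), check_pos(int(body[1:-1]))
        check_ref(pos, ref)
        alt, het = _base_and_het(body[-1], pos, reference)
        if alt == ref:
            raise TokenError(f"token {token!r}: alt equals ref")
        return VariantCall(pos, ref, alt, "substitution", 0, het)

    # shorthand: 16223T
    if body[:-1].isdigit() and len(body) >= 2:
        pos = check_pos(int(body[:-1]))
        ref = need_ref().base(pos)
        alt, het = _base_and_het(body[-1], pos, reference)
        if alt == ref:
            raise TokenError(f"token {token!r}: alt equals rCRS base at {pos}")
        return VariantCall(pos, ref, alt, "substitution", 0, het)

    raise TokenError(f"unrecognised variant token syntax: {token!r}")


CONTROL_REGION = ((16024, 16569), (1, 576))


def in_control_region(position: int) -> bool:
    return any(lo <= position <= hi for lo, hi in CONTROL_REGION)


def format_variant(v: VariantCall, dialect: str = "auto") -> str:
    """Deterministic token for a call.

    ``hgvs``  -> ``m.11778G>A`` / ``m.249delA`` / ``m.309.1C``
    ``shorthand`` (tree-motif style) -> ``16223T`` / ``249d`` / ``309.1C``
    ``auto``  -> shorthand inside the control region, hgvs elsewhere.
    Heteroplasmy is rendered as a lowercase derived base in either dialect.
    """
    if dialect == "auto":
        dialect = "shorthand" if in_control_region(v.position) else "hgvs"
    if dialect not in ("hgvs", "shorthand"):
        raise ValueError(f"unknown dialect {dialect!r}")
    alt = v.alt.lower() if v.heteroplasmic else v.alt
    if v.vtype == "insertion":
        core = f"{v.position}.{v.insertion_index}{alt}"
        return core if dialect == "shorthand" else f"m.{core}"
    if v.vtype == "deletion":
        return f"{v.position}d" if dialect == "shorthand" else f"m.{v.position}del{v.ref}"
    if dialect == "shorthand":
        return f"{v.position}{alt}"
    return f"m.{v.position}{v.ref}>{alt}"


# ---------------------------------------------------------------------------
# functional annotation

_STOPISH = {"*"}


@dataclass(frozen=True)
class AminoAcidAnnotation:
    gene: str
    codon_number: int
    ref_aa: str
    alt_aa: str
    effect: str  # synonymous | nonsynonymous | rRNA | tRNA | noncoding | frameshift-unsupported

    @property
    def protein_change(self) -> str | None:
        if self.effect in ("synonymous", "nonsynonymous"):
            return f"p.{self.ref_aa}{self.codon_number}{self.alt_aa}"
        return None


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate(table=2))


def annotate_variant(v: VariantCall, ref: ReferenceGenome) -> AminoAcidAnnotation:
    """Classify a variant as NS/S/rRNA/tRNA/noncoding with the vertebrate mito code.

    MT-ND6 is encoded on the light strand: its codons are read on the reverse
    complement.  A 3'-terminal incomplete codon (completed by polyadenylation
    in vivo) is excluded from NS/S calling.
    """
    if ref.gene_map is None:
        raise ValueError("reference has no gene map attached")
    feat = ref.gene_map.primary(v.position)
    if feat is None:
        return AminoAcidAnnotation("intergenic", 0, "", "", "noncoding")
    if feat.kind == "control":
        return AminoAcidAnnotation(feat.gene, 0, "", "", "noncoding")
    if feat.kind in ("rRNA", "tRNA"):
        return AminoAcidAnnotation(feat.gene, 0, "", "", feat.kind)
    # protein gene
    if v.vtype != "substitution":
        return AminoAcidAnnotation(feat.gene, 0, "", "", "frameshift-unsupported")
    if feat.strand == "H":
        offset = v.position - feat.start
        codon_number = offset // 3 + 1
        cstart = feat.start + 3 * (codon_number - 1)
        codon = ref.slice(cstart, min(cstart + 2, feat.end))
        within = v.position - cstart
        alt_base = v.alt
    else:
        # light strand: gene read 3'->5' on the heavy strand
        offset = feat.end - v.position
        codon_number = offset // 3 + 1
        cend = feat.end - 3 * (codon_number - 1)
        codon_fwd = ref.slice(max(cend - 2, feat.start), cend)
        codon = str(Seq(codon_fwd).reverse_complement())
        within = cend - v.position
        alt_base = str(Seq(v.alt).reverse_complement())
    if len(codon) < 3:
        # incomplete terminal codon, treated as stop; no NS/S call possible
        return AminoAcidAnnotation(feat.gene, codon_number, "*", "*", "synonymous")
    ref_aa = _translate_codon(codon)
    mutated = codon[:within] + alt_base + codon[within + 1:]
    alt_aa = _translate_codon(mutated)
    effect = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    return AminoAcidAnnotation(feat.gene, codon_number, ref_aa, alt_aa, effect)


# ---------------------------------------------------------------------------
# FASTA IO


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA into ``[(id, uppercase sequence), ...]``."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA ids: {dupes}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
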