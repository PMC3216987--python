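"""Motif-tree model of the mtDNA haplogroup phylogeny and a match-fraction classifier.

A haplogroup tree node carries the variants that define its branch (its
"motif").  A sample is assigned by walking every node, scoring the fraction of
defining variants on the node's root path that the sample's profile carries.
This mirrors manual motif-based classification: deterministic, explainable,
and restricted to the sequenced region when only the control region is
available.  Back mutations (token suffix ``!``) expect the *reference* state:
a profile carrying the earlier variant at such a node scores a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .reference import ReferenceGenome, VariantCall, parse_variant_token, format_variant
from .calling import HaplotypeProfile


class TreeFormatError(ValueError):
    pass


@dataclass
class MotifVariant:
    call: VariantCall
    back_mutation: bool = False

    def token(self) -> str:
        return format_variant(self.call) + ("!" if self.back_mutation else "")


@dataclass
class HaploNode:
    name: str
    motif: list[MotifVariant]
    parent: "HaploNode | None" = None
    children: list["HaploNode"] = field(default_factory=list)

    @property
    def depth(self) -> int:
        d, n = 0, self
        while n.parent is not None:
            d, n = d + 1, n.parent
        return d

    def path(self) -> list["HaploNode"]:
        nodes, n = [], self
        while n is not None:
            nodes.append(n)
            n = n.parent
        return nodes[::-1]

    def path_motifs(self) -> list[MotifVariant]:
        return [m for node in self.path() for m in node.motif]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


class HaploTree:
    def __init__(self, root: HaploNode):
        self.root = root
        self.nodes: dict[str, HaploNode] = {}
        for n in root.walk():
            if n.name in self.nodes:
                raise TreeFormatError(f"duplicate haplogroup name {n.name!r}")
            self.nodes[n.name] = n

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __getitem__(self, name: str) -> HaploNode:
        return self.nodes[name]

    def is_descendant(self, name: str, ancestor: str) -> bool:
        """True if ``name`` equals ``ancestor`` or lies below it."""
        n = self.nodes[name]
        while n is not None:
            if n.name == ancestor:
                return True
            n = n.parent
        return False

    def motif_positions(self) -> set[int]:
        return {m.call.position for node in self.root.walk() for m in node.motif}


def load_tree(path, ref: ReferenceGenome | None = None) -> HaploTree:
    """Load the TSV tree dialect: ``depth<TAB>name[<TAB>comma-separated tokens]``.

    Depth must increase by at most one per line (pre-order serialisation).
    """
    stack: list[HaploNode] = []
    root = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise TreeFormatError(f"line {lineno}: need depth<TAB>name")
            try:
                depth = int(parts[0])
            except ValueError:
                raise TreeFormatError(f"line {lineno}: bad depth {parts[0]!r}")
            name = parts[1].strip()
            tokens = parts[2].split(",") if len(parts) > 2 and parts[2].strip() else []
            motif = []
            for tok in tokens:
                tok = tok.strip()
                back = tok.endswith("!")
                call = parse_variant_token(tok.rstrip("!"), ref)
                motif.append(MotifVariant(call, back))
            node = HaploNode(name, motif)
            if depth == 0:
                if root is not None:
                    raise TreeFormatError(f"line {lineno}: second root {name!r}")
                root = node
                stack = [node]
                continue
            if root is None:
                raise TreeFormatError(f"line {lineno}: first node must have depth 0")
            if depth > len(stack):
                raise TreeFormatError(
                    f"line {lineno}: depth jumps from {len(stack) - 1} to {depth}")
            stack = stack[:depth]
            node.parent = stack[-1]
            stack[-1].children.append(node)
            stack.append(node)
    if root is None:
        raise TreeFormatError("empty tree file")
    return HaploTree(root)


@dataclass
class ClassificationResult:
    sample_id: str
    best_haplogroup: str
    score: float
    matched: list[VariantCall]
    missing: list[VariantCall]
    extra: list[VariantCall]
    runner_up: tuple[str, float] | None = None


def _in_region(pos: int, region) -> bool:
    return any(lo <= pos <= hi for lo, hi in region)


def classify(profile: HaplotypeProfile, tree: HaploTree,
             region_filter: bool = True,
             score_insertions: bool = False) -> ClassificationResult:
    """Assign the best-matching haplogroup to a profile.

    Per node, score = matched / expected over the root-path motif, where a
    back-mutation motif is "matched" when the profile *lacks* the variant.
    When ``region_filter`` is true only motifs inside the profile's region are
    scored (control-region-only classification).  Insertion motifs are skipped
    by default because they overlap the masked C-tracts.  Ties break to the
    node with more matched variants, then to the deeper node, then
    lexicographically; if nothing scores above zero the root is returned.
    (Without the matched-count criterion a deep clade whose extra motifs all
    fall outside the sequenced region would swallow shallower classes that
    matched far more sites.)
    """
    if not tree.nodes:
        raise ValueError("empty tree")
    profile_keys = {v.key for v in profile.variants}

    scored: list[tuple[float, int, int, str]] = []
    per_node: dict[str, tuple[list, list]] = {}
    for node in tree.root.walk():
        # collapse the path per site: a back mutation ("X!") cancels the
        # ancestral expectation of X and expects the reference state instead
        expected: dict = {}
        for m in node.path_motifs():
            if region_filter and not _in_region(m.call.position, profile.region):
                continue
            if not score_insertions and m.call.vtype == "insertion":
                continue
            expected[m.call.key] = (m.call, not m.back_mutation)
        matched, missing = [], []
        for call, expect_present in expected.values():
            has = call.key in profile_keys
            (matched if has == expect_present else missing).append(call)
        expected = len(matched) + len(missing)
        score = len(matched) / expected if expected else 0.0
        scored.append((score, len(matched), node.depth, node.name))
        per_node[node.name] = (matched, missing)

    # order: score desc, matched desc, depth desc, name asc
    ranked = sorted(scored, key=lambda t: (-t[0], -t[1], -t[2], t[3]))
    best_score, _, _, best_name = ranked[0]
    if best_score <= 0.0:
        best_name, best_score = tree.root.name, 0.0
    matched, missing = per_node[best_name]
    path_keys = {m.call.key for m in tree[best_name].path_motifs()}
    extra = [v for v in profile.variants if v.key not in path_keys]
    runner = next(((n, s) for s, _, d, n in ranked if n != best_name), None)
    return ClassificationResult(profile.sample_id, best_name, best_score,
                                matched, missing, extra, runner)


@dataclass
class FrequencyTable:
    cohort: str
    classes: list[str]
    counts: dict[str, int]
    n: int
    disjoint: bool = True

    def count(self, name: str) -> int:
        return self.counts[name]


def aggregate_frequencies(assignments, tree: HaploTree, classes,
                          cohort: str = "cohort") -> FrequencyTable:
    """Count samples per class; a sample counts toward class C iff its best
    haplogroup is C or a descendant of C (nested classes double-count)."""
    assignments = list(assignments)
    for c in classes:
        if c not in tree:
            raise KeyError(f"unknown class {c!r}")
    counts = {c: 0 for c in classes}
    for res in assignments:
        for c in classes:
            if tree.is_descendant(res.best_haplogroup, c):
                counts[c] += 1
    disjoint = not any(a != b and tree.is_descendant(b, a)
                       for a in classes for b in classes)
    return FrequencyTable(cohort, list(classes), counts, len(assignments),
                          disjoint=disjoint)


def lump_rare(table: FrequencyTable, threshold: int = 5,
              label: str = "others") -> FrequencyTable:
    """Merge display classes with count < threshold into an "others" bin.

    Only defined for a disjoint display partition (nested classes would
    double-count the merged bin).
    """
    if not table.disjoint:
        raise ValueError("lump_rare needs disjoint (non-nested) display classes")
    kept = {c: k for c, k in table.counts.items() if k >= threshold}
    lumped = sum(k for k in table.counts.values() if k < threshold)
    counts = dict(kept)
    if lumped:
        counts[label] = counts.get(label, 0) + lumped
    return FrequencyTable(table.cohort, list(counts), counts, table.n, disjoint=True)


def classification_report(results, path=None):
    """Tabular report (sample, haplogroup, score, matched, missing, extra)."""
    import pandas as pd

    rows = [{
        "sample_id": r.sample_id,
        "haplogroup": r.best_haplogroup,
        "score": round(r.score, 4),
        "matched": " ".join(format_variant(v) for v in r.matched),
        "missing": " ".join(format_variant(v) for v in r.missing),
        "extra": " ".join(format_variant(v) for v in r.extra),
    } for r in results]
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
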