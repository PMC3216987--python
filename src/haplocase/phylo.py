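"""Within-haplogroup classification trees, terminal-branch private variants,
NS/S comparison and the ortholog conservation index.

Complete mtDNA genomes classified inside one haplogroup are arranged in a
classification tree: shared variants are pushed to the deepest branch whose
leaves all carry them, so each leaf's root-to-leaf path reconstructs its
profile exactly (C-tract length variants excluded).  Variants on a terminal
branch are that sample's *private* variants; protein-gene privates are
classified NS/S with the vertebrate mitochondrial code and scored for
cross-species conservation against an ortholog alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .reference import (
    ReferenceGenome,
    VariantCall,
    annotate_variant,
    format_variant,
    read_fasta,
)
from .calling import in_ctract_window
from .haplotree import HaploTree, classify
from .stats import ContingencyTable2x2, nominal_p


_SUFFIX = {"synonymous": "/s", "nonsynonymous": "/ns", "rRNA": "/r", "tRNA": "/t"}


@dataclass
class ClassificationTreeNode:
    label: str  # haplogroup name, or sample id at a leaf
    variants: list[VariantCall] = field(default_factory=list)
    children: list["ClassificationTreeNode"] = field(default_factory=list)
    recurrent: set = field(default_factory=set)  # keys of variants seen on >1 branch
    is_sample: bool = False

    @property
    def is_terminal(self) -> bool:
        return self.is_sample

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()

    def leaves(self):
        """Sample leaves (clade nodes without samples below are not leaves)."""
        return [n for n in self.walk() if n.is_sample]


def build_classification_tree(profiles, backbone: HaploTree, root_class: str,
                              ref: ReferenceGenome | None = None,
                              region_filter: bool = False) -> ClassificationTreeNode:
    """Arrange profiles classified within ``root_class`` into a shared-variant tree.

    The topology follows the backbone's named clades below ``root_class``;
    each variant is then attached to every maximal branch all of whose leaves
    carry it (leaf branches for singletons).  A variant attached to more than
    one branch is flagged recurrent.
    """
    if root_class not in backbone:
        raise KeyError(f"root class {root_class!r} not in backbone tree")
    results = [classify(p, backbone, region_filter=region_filter) for p in profiles]
    for p, r in zip(profiles, results):
        if not backbone.is_descendant(r.best_haplogroup, root_class):
            raise ValueError(
                f"sample {p.sample_id} classifies to {r.best_haplogroup}, "
                f"outside {root_class}")

    # clade skeleton: only clades on some sample's path are materialised
    nodes: dict[str, ClassificationTreeNode] = {
        root_class: ClassificationTreeNode(root_class)}

    def clade_node(name: str) -> ClassificationTreeNode:
        if name in nodes:
            return nodes[name]
        node = ClassificationTreeNode(name)
        parent = clade_node(backbone[name].parent.name)
        parent.children.append(node)
        nodes[name] = node
        return node

    leaves: dict[str, ClassificationTreeNode] = {}
    leaf_vars: dict[str, dict] = {}
    for p, r in zip(profiles, results):
        leaf = ClassificationTreeNode(p.sample_id, is_sample=True)
        clade_node(r.best_haplogroup).children.append(leaf)
        leaves[p.sample_id] = leaf
        leaf_vars[p.sample_id] = {
            v.key: v for v in p.variants
            if not (v.vtype != "substitution" and in_ctract_window(v.position))}

    root = nodes[root_class]

    def carriers_below(node) -> list[str]:
        return [n.label for n in node.leaves()]

    # deterministic child order: named clades first, then sample leaves
    for node in root.walk():
        node.children.sort(key=lambda n: (n.is_sample, n.label))

    # haplogroup-defining variants stay on their named clade's branch (the
    # root branch also carries the motifs of everything above root_class)
    motif_home: dict = {}
    for name, cnode in nodes.items():
        bb = backbone[name]
        motifs = bb.path_motifs() if name == root_class else list(bb.motif)
        for m in motifs:
            if not m.back_mutation:
                motif_home.setdefault(m.call.key, cnode)

    all_keys = {}
    for d in leaf_vars.values():
        all_keys.update(d)
    placements: dict = {k: [] for k in all_keys}

    # remaining variants: push to the deepest branch all of whose leaves carry
    # them; carriers split across branches yield multiple (recurrent) placements
    def place(node, key):
        below = carriers_below(node)
        if below and all(key in leaf_vars[s] for s in below):
            while len(node.children) == 1:  # unary chain: deepest equivalent branch
                node = node.children[0]
            placements[key].append(node)
            return
        for ch in node.children:
            place(ch, key)

    for key in all_keys:
        home = motif_home.get(key)
        if home is not None and all(key in leaf_vars[s] for s in carriers_below(home)):
            placements[key].append(home)
        else:
            place(root, key)
    recurrent_keys = {k for k, where in placements.items() if len(where) > 1}
    for key, where in placements.items():
        for node in where:
            node.variants.append(all_keys[key])
            if key in recurrent_keys:
                node.recurrent.add(key)
    for node in root.walk():  # deterministic, position-ascending branch lists
        node.variants.sort(key=lambda v: (v.position, v.insertion_index))
    return root


def branch_label(node: ClassificationTreeNode, ref: ReferenceGenome) -> str:
    """Branch variants with /s /ns /r /t suffixes; recurrent marked with '*'."""
    parts = []
    for v in node.variants:
        ann = annotate_variant(v, ref) if v.vtype == "substitution" else None
        suffix = _SUFFIX.get(ann.effect, "") if ann else ""
        star = "*" if v.key in node.recurrent else ""
        parts.append(format_variant(v, "shorthand") + suffix + star)
    return " ".join(parts)


def render_tree(root: ClassificationTreeNode, ref: ReferenceGenome,
                indent: str = "  ") -> str:
    lines = []

    def rec(node, level):
        tag = node.label if node.is_terminal else node.label + ":"
        lab = branch_label(node, ref)
        lines.append(f"{indent * level}{tag} {lab}".rstrip())
        for ch in node.children:
            rec(ch, level + 1)

    rec(root, 0)
    return "\n".join(lines)


def to_newick(root: ClassificationTreeNode, ref: ReferenceGenome) -> str:
    def rec(node):
        lab = branch_label(node, ref).replace(" ", "|")
        comment = f"[&&variants={lab}]" if lab else ""
        if node.is_terminal:
            return f"{node.label}{comment}"
        inner = ",".join(rec(c) for c in node.children)
        return f"({inner}){node.label}{comment}"

    return rec(root) + ";"


@dataclass
class PrivateVariantRecord:
    sample_id: str
    variant: VariantCall
    gene: str
    effect: str
    protein_change: str | None
    conservation_index: float | None = None
    haplogroup_specific: list[str] = field(default_factory=list)


def private_variants(tree: ClassificationTreeNode, sample_id: str,
                     ref: ReferenceGenome,
                     backbone: HaploTree | None = None,
                     alignment: "OrthologAlignment | None" = None):
    """Annotated terminal-branch variants of one sample.

    ``haplogroup_specific`` lists haplogroups in ``backbone`` whose motif
    contains the same variant (tree-lookup only; no external searches).
    """
    leaf = next((n for n in tree.walk() if n.is_terminal and n.label == sample_id), None)
    if leaf is None:
        raise KeyError(f"unknown sample {sample_id!r}")
    records = []
    for v in leaf.variants:
        ann = annotate_variant(v, ref)
        hgs = []
        if backbone is not None:
            hgs = [node.name for node in backbone.root.walk()
                   if any(m.call.key == v.key for m in node.motif)]
        ci = None
        if alignment is not None and v.vtype == "substitution" \
                and alignment.covers(v.position):
            ci = round(alignment.conservation_index(v.position)[0], 3)
        records.append(PrivateVariantRecord(
            sample_id, v, ann.gene, ann.effect, ann.protein_change, ci, hgs))
    return records


def count_ns_s_terminal(tree_a: ClassificationTreeNode,
                        tree_b: ClassificationTreeNode,
                        ref: ReferenceGenome):
    """Terminal-branch NS vs S counts (protein genes) for two groups + test.

    Returns (table, method, p) where the table rows are the two groups and
    the columns are NS and S.
    """
    def counts(tree):
        if not tree.leaves():
            raise ValueError("group has no samples")
        ns = s = 0
        for leaf in tree.leaves():
            for v in leaf.variants:
                if v.vtype != "substitution":
                    continue
                eff = annotate_variant(v, ref).effect
                if eff == "nonsynonymous":
                    ns += 1
                elif eff == "synonymous":
                    s += 1
        return ns, s

    ns_a, s_a = counts(tree_a)
    ns_b, s_b = counts(tree_b)
    t = ContingencyTable2x2(ns_a, s_a, ns_b, s_b)
    method, p = nominal_p(t)
    return t, method, p


# ---------------------------------------------------------------------------
# ortholog conservation


class OrthologAlignment:
    """Human-referenced ortholog alignment with an rCRS coordinate map.

    Row 0 is the human reference; the conservation index of a position is the
    fraction of non-human species matching the human state there, computed
    over species with a non-gap state at that column.
    """

    def __init__(self, names: list[str], rows: list[str], start: int = 1):
        if len({len(r) for r in rows}) != 1:
            raise ValueError("alignment rows differ in length")
        self.names = names
        self.rows = [r.upper() for r in rows]
        self.start = start  # rCRS coordinate of the first human (non-gap) column
        human = self.rows[0]
        self._col_of: dict[int, int] = {}
        pos = start
        for i, ch in enumerate(human):
            if ch != "-":
                self._col_of[pos] = i
                pos += 1

    @classmethod
    def from_fasta(cls, path, start: int = 1) -> "OrthologAlignment":
        records = read_fasta(path)
        return cls([r[0] for r in records], [r[1] for r in records], start)

    @property
    def n_species(self) -> int:
        return len(self.rows) - 1

    def covers(self, position: int) -> bool:
        return position in self._col_of

    def conservation_index(self, position: int) -> tuple[float, int]:
        """(index, number of species with a non-gap state at the column)."""
        if position not in self._col_of:
            raise KeyError(f"position {position} not covered (or gapped) in "
                           "the reference row")
        col = self._col_of[position]
        human = self.rows[0][col]
        states = [r[col] for r in self.rows[1:]]
        nongap = [s for s in states if s != "-"]
        if not nongap:
            return float("nan"), 0
        return sum(s == human for s in nongap) / len(nongap), len(nongap)
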