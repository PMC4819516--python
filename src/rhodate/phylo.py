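"""Phylogeny construction and mutation mapping for haploid genotype matrices.

Distances use pairwise deletion with a shared-callable denominator: the
difference rate between two samples is computed only over sites callable in
both, and the denominator includes the (weighted) count of mutually callable
invariant sites, so low-coverage samples are not biased toward short branches.
Trees are built by neighbor joining with deterministic tie-breaking, rooted by
an outgroup, and variant sites are assigned to branches by Fitch parsimony with
missing calls treated as unknown.  Clade support comes from a site bootstrap:
resample matrix columns (variant and invariant alike) with replacement and
rebuild the tree per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import treeio
from .errors import ConfigError, DataError
from .variants import ANCESTRAL, DERIVED, MISSING, GenotypeMatrix

__all__ = [
    "SiteWeights", "CladeSupport", "HaploTree", "MarkerTable",
    "pairwise_distance", "distance_matrix", "neighbor_joining",
    "root_by_outgroup", "map_mutations_parsimony", "bootstrap_support",
    "assign_haplogroup",
]


@dataclass
class SiteWeights:
    """Per-column weights for (bootstrap-)weighted statistics.

    ``variant`` has one weight per variant site; ``pattern`` one weight per
    invariant callable-pattern class (default: the class multiplicities, i.e.
    every invariant site counted once).
    """

    variant: np.ndarray
    pattern: np.ndarray

    @classmethod
    def unit(cls, matrix: GenotypeMatrix) -> "SiteWeights":
        return cls(np.ones(matrix.n_sites), matrix.pattern_counts.astype(float))

    @classmethod
    def bootstrap(cls, matrix: GenotypeMatrix, rng: np.random.Generator) -> "SiteWeights":
        """Multinomial resample of all ``universe_size`` site columns."""
        L = matrix.universe_size
        probs = np.concatenate([
            np.full(matrix.n_sites, 1.0 / L),
            matrix.pattern_counts / L,
        ])
        draw = rng.multinomial(L, probs).astype(float)
        return cls(draw[: matrix.n_sites], draw[matrix.n_sites:])


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def _pattern_bits(matrix: GenotypeMatrix) -> np.ndarray:
    """(n_samples, n_patterns) bool: sample callable in pattern class."""
    n = matrix.n_samples
    return np.stack([
        ((matrix.pattern_ids >> np.uint64(i)) & np.uint64(1)).astype(bool)
        for i in range(n)
    ])


def distance_matrix(
    matrix: GenotypeMatrix, weights: SiteWeights | None = None
) -> np.ndarray:
    """Pairwise-deletion difference-rate matrix over all samples."""
    w = weights or SiteWeights.unit(matrix)
    n = matrix.n_samples
    vc = matrix.variant_callable()
    calls = matrix.calls
    bits = _pattern_bits(matrix)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = vc[i] & vc[j]
            num = float(w.variant[both & (calls[i] != calls[j])].sum())
            den = float(w.variant[both].sum()) + float(w.pattern[bits[i] & bits[j]].sum())
            if den == 0:
                raise DataError(
                    f"samples {matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r} "
                    "share no callable sites"
                )
            D[i, j] = D[j, i] = num / den
    return D


def pairwise_distance(
    matrix: GenotypeMatrix, i: int | str, j: int | str,
    weights: SiteWeights | None = None,
) -> float:
    """Difference rate between two samples (pairwise deletion, see module doc)."""
    if isinstance(i, str):
        i = matrix.sample_index(i)
    if isinstance(j, str):
        j = matrix.sample_index(j)
    if i == j:
        return 0.0
    w = weights or SiteWeights.unit(matrix)
    vc = matrix.variant_callable()
    both = vc[i] & vc[j]
    num = float(w.variant[both & (matrix.calls[i] != matrix.calls[j])].sum())
    bits = _pattern_bits(matrix)
    den = float(w.variant[both].sum()) + float(w.pattern[bits[i] & bits[j]].sum())
    if den == 0:
        raise DataError(
            f"samples {matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r} "
            "share no callable sites"
        )
    return num / den


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(D: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """Saitou-Nei neighbor joining returning an unrooted dendropy tree.

    Ties in the Q criterion are broken by the lowest (row, column) index pair in
    the current agglomeration order (a merged cluster takes the lower index), and
    a negative branch length is clamped to zero with the deficit moved to its
    sibling, so the output is fully deterministic.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise ConfigError("distance matrix shape does not match labels")
    if n < 3:
        raise ConfigError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T):
        raise DataError("distance matrix is not symmetric")
    if not np.isfinite(D).all():
        raise DataError("distance matrix has non-finite entries")

    tns = dendropy.TaxonNamespace([str(l) for l in labels])
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(str(lab))
        nodes.append(nd)
    D = D.copy()

    def _join(i: int, j: int, li: float, lj: float) -> None:
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = max(li + lj, 0.0), 0.0
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # replace i by parent, drop j
        nodes[i] = parent
        nodes.pop(j)

    while D.shape[0] > 3:
        m = D.shape[0]
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        iu = np.triu_indices(m, k=1)
        k = int(np.argmin(Q[iu]))  # row-major over i<j: lowest (i, j) wins ties
        i, j = int(iu[0][k]), int(iu[1][k])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        _join(i, j, li, lj)
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)

    # final three clusters joined at an unrooted trifurcation
    center = dendropy.Node()
    l0 = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    l1 = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    l2 = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for nd, ln in zip(nodes, (l0, l1, l2)):
        center.add_child(nd)
        nd.edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------


def _leafsets_below(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= sets[ch]
            sets[node] = frozenset(acc)
    return sets


def unrooted_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Every non-trivial split of an unrooted tree, each as both leaf subsets."""
    sets = _leafsets_below(tree)
    all_leaves = frozenset(treeio.leaf_labels(tree))
    out: set[frozenset[str]] = set()
    for node, ls in sets.items():
        if node.parent_node is None:
            continue
        out.add(ls)
        out.add(all_leaves - ls)
    return out


def root_by_outgroup(tree: dendropy.Tree, outgroup: Iterable[str]) -> dendropy.Tree:
    """Root an unrooted tree on the branch separating the outgroup, at its
    midpoint.  The outgroup must be monophyletic (form one side of a split)."""
    og = frozenset(outgroup)
    all_leaves = frozenset(treeio.leaf_labels(tree))
    if not og or not og <= all_leaves:
        raise DataError(f"outgroup {sorted(og - all_leaves)} not in tree")
    sets = _leafsets_below(tree)
    target = None
    for node, ls in sets.items():
        if node.parent_node is None:
            continue
        if ls == og or ls == all_leaves - og:
            target = node
            break
    if target is None:
        raise DataError(
            f"outgroup is not monophyletic in the tree: {sorted(og)}"
        )
    length = target.edge.length or 0.0
    tree.reroot_at_edge(target.edge, length1=length / 2.0, length2=length / 2.0,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Parsimony mutation mapping
# ---------------------------------------------------------------------------


@dataclass
class HaploTree:
    """A rooted tree with per-branch mutation assignments.

    Mutation columns (indices into the matrix's variant sites) are attached to
    the head node of each branch as ``node.mutation_cols``; sites that would
    need more than one change from an ancestral root are homoplasic and
    excluded from dating.
    """

    tree: dendropy.Tree
    matrix: GenotypeMatrix
    homoplasic_cols: np.ndarray
    uninformative_cols: np.ndarray

    @property
    def n_homoplasic(self) -> int:
        return len(self.homoplasic_cols)

    def leaf_labels(self) -> list[str]:
        return treeio.leaf_labels(self.tree)

    def leaf_node(self, label: str) -> dendropy.Node:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == label:
                return lf
        raise DataError(f"leaf {label!r} not in tree")

    def mrca(self, labels: Iterable[str]) -> dendropy.Node:
        return treeio.mrca_node(self.tree, set(labels))

    def is_monophyletic(self, labels: Iterable[str]) -> bool:
        return treeio.clade_leafset(self.mrca(labels)) == frozenset(labels)

    def path_to_ancestor(self, leaf_label: str, ancestor: dendropy.Node) -> list[dendropy.Node]:
        """Nodes whose parent edge lies on the path leaf -> ancestor."""
        node = self.leaf_node(leaf_label)
        path = []
        while node is not ancestor:
            path.append(node)
            node = node.parent_node
            if node is None:
                raise DataError(
                    f"{ancestor} is not an ancestor of leaf {leaf_label!r}"
                )
        return path

    def branch_counts(self) -> dict[frozenset[str], int]:
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            out[treeio.clade_leafset(node)] = len(getattr(node, "mutation_cols", ()))
        return out

    def write_newick(self, path: str | Path, branch_lengths: str = "counts",
                     support: Mapping[frozenset, float] | None = None) -> None:
        """Write Newick with branch lengths as mutation counts or input lengths;
        optional support values become internal node labels."""
        clone = self.tree.clone(depth=1)
        for node in clone.preorder_node_iter():
            if node.parent_node is not None and branch_lengths == "counts":
                node.edge.length = len(getattr(node, "mutation_cols", ()))
            if support is not None and not node.is_leaf():
                ls = treeio.clade_leafset(node)
                if ls in support:
                    node.label = f"{support[ls]:g}"
        Path(path).write_text(
            clone.as_string(schema="newick", suppress_rooting=True)
        )


def map_mutations_parsimony(tree: dendropy.Tree, matrix: GenotypeMatrix) -> HaploTree:
    """Assign every variant site to a branch by Fitch parsimony.

    Missing calls are unknown (compatible with either state) and the root is
    constrained to the ancestral allele.  Sites whose minimum number of changes
    under that constraint exceeds one are flagged homoplasic and excluded from
    dating.  Among the equally parsimonious placements a single change can take
    when neighbouring calls are missing, the change is placed on the stem of
    the smallest clade containing every definitely derived leaf (the delayed,
    tipward resolution): unknown calls resolve to the ancestral state wherever
    possible, which keeps each mutation on the root paths of exactly the
    samples observed to carry it — the property the rho statistic's
    callability-restricted counts rely on.  Sites whose derived calls span
    both sides of the root (no branch below the root can host the change) are
    flagged uninformative and excluded.
    """
    leaves = set(treeio.leaf_labels(tree))
    if leaves != set(matrix.sample_ids):
        raise DataError("tree leaves do not match matrix samples")

    nodes = list(tree.postorder_node_iter())
    index = {id(nd): k for k, nd in enumerate(nodes)}
    V = matrix.n_sites
    row = {s: i for i, s in enumerate(matrix.sample_ids)}

    # state sets encoded bitwise: 1 = {ancestral}, 2 = {derived}, 3 = unknown
    sets = np.zeros((len(nodes), V), dtype=np.uint8)
    score = np.zeros(V, dtype=np.int32)
    for k, nd in enumerate(nodes):
        if nd.is_leaf():
            calls = matrix.calls[row[nd.taxon.label]]
            s = np.where(calls == MISSING, 3, np.where(calls == DERIVED, 2, 1))
            sets[k] = s.astype(np.uint8)
        else:
            children = [sets[index[id(ch)]] for ch in nd.child_nodes()]
            acc = children[0]
            for ch in children[1:]:
                inter = acc & ch
                union = acc | ch
                score += inter == 0
                acc = np.where(inter > 0, inter, union).astype(np.uint8)
            sets[k] = acc
    root_k = index[id(tree.seed_node)]
    score += (sets[root_k] & 1) == 0  # root constrained ancestral

    homoplasic = np.flatnonzero(score > 1)
    uninformative = list(np.flatnonzero(score == 0))

    # delayed (tipward) placement: stem of the minimal clade covering every
    # definitely derived leaf
    bitmask: dict[int, int] = {}
    leaf_of_row: dict[int, dendropy.Node] = {}
    for nd in nodes:
        if nd.is_leaf():
            bitmask[id(nd)] = 1 << row[nd.taxon.label]
            leaf_of_row[row[nd.taxon.label]] = nd
        else:
            bitmask[id(nd)] = 0
            for ch in nd.child_nodes():
                bitmask[id(nd)] |= bitmask[id(ch)]
        nd.mutation_cols = []
    for col in np.flatnonzero(score == 1):
        rows_derived = np.flatnonzero(matrix.calls[:, col] == DERIVED)
        if len(rows_derived) == 0:
            uninformative.append(int(col))
            continue
        target = 0
        for r in rows_derived:
            target |= 1 << int(r)
        nd = leaf_of_row[int(rows_derived[0])]
        while bitmask[id(nd)] & target != target:
            nd = nd.parent_node
        if nd.parent_node is None:
            uninformative.append(int(col))
        else:
            nd.mutation_cols.append(int(col))
    for nd in nodes:
        nd.mutation_cols = np.array(sorted(nd.mutation_cols), dtype=np.int64)
    return HaploTree(tree=tree, matrix=matrix, homoplasic_cols=homoplasic,
                     uninformative_cols=np.array(sorted(uninformative), dtype=np.int64))


# ---------------------------------------------------------------------------
# Bootstrap clade support
# ---------------------------------------------------------------------------


@dataclass
class CladeSupport:
    clade: frozenset[str]
    support: float          # percent of replicates containing the clade
    n_reps: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.support <= 100.0 or self.n_reps < 1:
            raise ConfigError("invalid clade support")


def bootstrap_support(
    matrix: GenotypeMatrix,
    clades: Sequence[Iterable[str]],
    n_reps: int = 100,
    seed: int = 0,
    tree_builder: Callable[[GenotypeMatrix, SiteWeights], dendropy.Tree] | None = None,
) -> list[CladeSupport]:
    """Site-bootstrap support for focal clades.

    Per replicate, all site columns (variant and invariant) are resampled with
    replacement, the tree is rebuilt from the reweighted distances, and a clade
    is counted as present if its leaf set forms one side of a split of the
    replicate tree.  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    if tree_builder is None:
        def tree_builder(mat: GenotypeMatrix, w: SiteWeights) -> dendropy.Tree:
            return neighbor_joining(distance_matrix(mat, w), mat.sample_ids)
    clade_sets = [frozenset(c) for c in clades]
    hits = np.zeros(len(clade_sets), dtype=int)
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        w = SiteWeights.bootstrap(matrix, rng)
        rep_tree = tree_builder(matrix, w)
        bips = unrooted_bipartitions(rep_tree)
        for c, cl in enumerate(clade_sets):
            if cl in bips:
                hits[c] += 1
    return [
        CladeSupport(clade=cl, support=100.0 * h / n_reps, n_reps=n_reps)
        for cl, h in zip(clade_sets, hits)
    ]


# ---------------------------------------------------------------------------
# Haplogroup assignment from marker tables
# ---------------------------------------------------------------------------


@dataclass
class MarkerTable:
    """Haplogroup-defining markers with their hierarchy.

    Columns: marker, position (1-based), ancestral, derived, haplogroup,
    parent (name of the next marker up the hierarchy, empty at the top).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"marker", "position", "haplogroup", "parent"}
        missing = req - set(self.table.columns)
        if missing:
            raise DataError(f"marker table missing columns: {sorted(missing)}")
        if self.table["position"].duplicated().any():
            raise DataError("marker positions must be unique")
        self.table = self.table.set_index("marker", drop=False)
        for m in self.table["marker"]:
            self.depth(m)  # raises on cycles / unknown parents

    @classmethod
    def read(cls, path: str | Path) -> "MarkerTable":
        t = pd.read_csv(path, sep="\t", dtype={"marker": str, "parent": str})
        t["parent"] = t["parent"].fillna("")
        return cls(t)

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def parent_of(self, marker: str) -> str:
        p = self.table.loc[marker, "parent"]
        return "" if pd.isna(p) else str(p)

    def depth(self, marker: str) -> int:
        d, seen = 0, {marker}
        while True:
            p = self.parent_of(marker)
            if p == "":
                return d
            if p not in self.table.index:
                raise DataError(f"marker {marker!r} has unknown parent {p!r}")
            if p in seen:
                raise DataError(f"marker hierarchy contains a cycle at {p!r}")
            seen.add(p)
            marker, d = p, d + 1

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff marker ``a`` lies on the parent chain of ``b`` (or a == b)."""
        while True:
            if a == b:
                return True
            b = self.parent_of(b)
            if b == "":
                return False

    def label_of(self, marker: str) -> str:
        return f"{self.table.loc[marker, 'haplogroup']}-{marker}"


def assign_haplogroup(
    sample_calls: Mapping[int, int], markers: MarkerTable
) -> str:
    """Assign a haplogroup from calls at marker positions.

    ``sample_calls`` maps 1-based position to 0 (ancestral), 1 (derived) or -1
    (missing); absent positions count as missing.  The deepest derived marker
    wins; missing intermediate markers are tolerated.  Derived calls at markers
    on incompatible branches of the hierarchy signal a data problem and raise.
    """
    derived = []
    for m in markers.table["marker"]:
        pos = int(markers.table.loc[m, "position"])
        if sample_calls.get(pos, MISSING) == DERIVED:
            derived.append(m)
    if not derived:
        return "unassigned"
    for a in derived:
        for b in derived:
            if not (markers.is_ancestor(a, b) or markers.is_ancestor(b, a)):
                raise DataError(
                    f"conflicting derived marker calls on incompatible branches: "
                    f"{a!r} vs {b!r}"
                )
    deepest = max(derived, key=lambda m: (markers.depth(m), m))
    return markers.label_of(deepest)


def assign_haplogroups(matrix: GenotypeMatrix, markers: MarkerTable) -> dict[str, str]:
    """Haplogroup label per sample of a genotype matrix."""
    pos_to_col = {int(p): k for k, p in enumerate(matrix.positions)}
    out = {}
    for i, s in enumerate(matrix.sample_ids):
        calls = {
            int(p): int(matrix.calls[i, pos_to_col[int(p)]])
            for p in markers.table["position"]
            if int(p) in pos_to_col
        }
        out[s] = assign_haplogroup(calls, markers)
    return out
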