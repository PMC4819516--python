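"""Small helpers around dendropy trees used across the package."""

from __future__ import annotations

import dendropy

from .errors import ConfigError, DataError


def parse_tree(newick: str, rooted: bool = True) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree (rooted by default)."""
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        rooting="force-rooted" if rooted else "force-unrooted",
    )
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def node_ages(tree: dendropy.Tree, tip_ages: dict[str, float] | None = None,
              rtol: float = 1e-6) -> dict[dendropy.Node, float]:
    """Node ages in years from branch lengths (years) and tip ages.

    Tips default to age 0; ancient tips may be given positive ages.  Ages must
    be consistent across the children of every internal node (the tree is
    ultrametric up to the stated tip ages).
    """
    tip_ages = tip_ages or {}
    ages: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = float(tip_ages.get(node.taxon.label, 0.0))
        else:
            cand = []
            for ch in node.child_nodes():
                if ch.edge.length is None:
                    raise ConfigError("tree_spec must give branch lengths in years")
                cand.append(ages[ch] + float(ch.edge.length))
            lo, hi = min(cand), max(cand)
            if hi - lo > rtol * max(hi, 1.0):
                raise ConfigError(
                    f"tree_spec is not ultrametric given tip ages: node age "
                    f"candidates span [{lo:g}, {hi:g}]"
                )
            ages[node] = sum(cand) / len(cand)
    for node, age in ages.items():
        if not node.is_leaf():
            for ch in node.child_nodes():
                if age < ages[ch]:
                    raise ConfigError("node ages must decrease from root to tips")
    return ages


def mrca_node(tree: dendropy.Tree, labels: set[str] | list[str]) -> dendropy.Node:
    labels = set(labels)
    node = tree.mrca(taxon_labels=labels)
    if node is None:
        raise DataError(f"no MRCA found for {sorted(labels)}")
    return node


def clade_leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())
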