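"""Presence/absence comparative analysis of miRNA families on a fixed species tree.

A miRNA family observed in a set of extant lineages is placed on the land-plant
cladogram under Dollo parsimony: the character is gained exactly once, at the most
recent common ancestor (MRCA) of the lineages that carry it, and may be lost any
number of times below that node.  The number of losses is the number of maximal
subtrees under the origin whose leaves all lack the family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd


class PhyloError(ValueError):
    pass


@dataclass
class PresenceMatrix:
    """Family x taxon boolean grid (rows = miRNA families, columns = taxon groups)."""

    families: list[str]
    taxa: list[str]
    cells: np.ndarray  # bool, shape (n_families, n_taxa)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        if len(set(self.families)) != len(self.families):
            raise PhyloError("duplicate family labels in presence matrix")
        if len(set(self.taxa)) != len(self.taxa):
            raise PhyloError("duplicate taxon labels in presence matrix")
        if self.cells.shape != (len(self.families), len(self.taxa)):
            raise PhyloError("presence matrix shape does not match labels")
        if not self.cells.any(axis=1).all():
            empty = [f for f, row in zip(self.families, self.cells) if not row.any()]
            raise PhyloError(f"families with no presence at all: {empty}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(
            families=[str(f) for f in df.index],
            taxa=[str(t) for t in df.columns],
            cells=df.to_numpy(dtype=bool),
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.cells.astype(int), index=self.families, columns=self.taxa
        )
        df.index.name = "family"
        df.to_csv(path, sep="\t")

    def row(self, family: str) -> dict[str, bool]:
        try:
            i = self.families.index(family)
        except ValueError:
            raise PhyloError(f"unknown family: {family}") from None
        return dict(zip(self.taxa, self.cells[i]))

    def presence_taxa(self, family: str) -> list[str]:
        return [t for t, p in self.row(family).items() if p]


def load_tree(source: str | Path) -> dendropy.Tree:
    """Load a rooted newick tree (from a path or a newick string).

    Internal node labels (e.g. ``euphyllophyta``) are kept as ``node.label``.
    """
    text = str(source)
    if not text.lstrip().startswith("("):
        text = Path(source).read_text()
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        rooting="force-rooted",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return tree


def _leaf_labels(node: dendropy.Node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}


def node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or "<unnamed>"


def mrca(tree: dendropy.Tree, leaf_set: set[str] | list[str]) -> dendropy.Node:
    """Least common ancestor of a non-empty set of leaf labels.

    A singleton set maps to the leaf itself.
    """
    wanted = set(leaf_set)
    if not wanted:
        raise PhyloError("mrca of an empty leaf set")
    all_leaves = _leaf_labels(tree.seed_node)
    unknown = wanted - all_leaves
    if unknown:
        raise PhyloError(f"leaves not in tree: {sorted(unknown)}")
    # Walk down from the root while one child subtree still spans the whole set.
    node = tree.seed_node
    while True:
        if node.is_leaf():
            return node
        for child in node.child_nodes():
            if wanted <= _leaf_labels(child):
                node = child
                break
        else:
            return node


@dataclass
class OriginAssignment:
    family: str
    origin: str  # node label
    n_losses: int
    origin_node: dendropy.Node = field(repr=False, compare=False, default=None)


def dollo_origin(
    family: str, presence_taxa: set[str] | list[str], tree: dendropy.Tree
) -> OriginAssignment:
    """Single-gain/multiple-loss placement of one presence row on the tree.

    The origin is the MRCA of the taxa carrying the family (under Dollo parsimony
    this is the unique loss-minimising single-gain node); losses are the maximal
    all-absent subtrees below it.
    """
    present = set(presence_taxa)
    if not present:
        raise PhyloError(f"family {family} has no presence — cannot place an origin")
    origin = mrca(tree, present)

    def all_absent(node: dendropy.Node) -> bool:
        return not (_leaf_labels(node) & present)

    n_losses = 0
    stack = list(origin.child_nodes()) if not origin.is_leaf() else []
    while stack:
        node = stack.pop()
        if all_absent(node):
            n_losses += 1  # maximal absent subtree; do not descend
        else:
            stack.extend(node.child_nodes())
    return OriginAssignment(family, node_label(origin), n_losses, origin)


def assign_origins(matrix: PresenceMatrix, tree: dendropy.Tree) -> list[OriginAssignment]:
    return [dollo_origin(f, matrix.presence_taxa(f), tree) for f in matrix.families]


def node_census(assignments: list[OriginAssignment]) -> dict[str, list[str]]:
    """Families grouped by origin node, in deterministic (input) family order."""
    census: dict[str, list[str]] = {}
    for a in assignments:
        census.setdefault(a.origin, []).append(a.family)
    return census


def taxon_census(
    matrix: PresenceMatrix, taxon: str, intersect_with: str | None = None
) -> int:
    """Number of families present in ``taxon`` (optionally also in ``intersect_with``)."""
    if taxon not in matrix.taxa:
        raise PhyloError(f"unknown taxon: {taxon}")
    col = matrix.cells[:, matrix.taxa.index(taxon)]
    if intersect_with is not None:
        if intersect_with not in matrix.taxa:
            raise PhyloError(f"unknown taxon: {intersect_with}")
        col = col & matrix.cells[:, matrix.taxa.index(intersect_with)]
    return int(col.sum())


def origins_table(assignments: list[OriginAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": [a.family for a in assignments],
            "origin_node": [a.origin for a in assignments],
            "n_losses": [a.n_losses for a in assignments],
        }
    )
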