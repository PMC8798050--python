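"""Bipartition machinery: Robinson-Foulds distances, replicate-run stability,
rogue-terminal ranking, and backbone-constraint handling.

All comparisons work on *nontrivial bipartitions* (splits) of the leaf set.
Trees are first restricted to the leaves being compared, so trees over
different (overlapping) taxon sets can be compared.  The normalized RF
distance divides the symmetric-difference count by 2(n-3), the maximum for
binary unrooted trees on n leaves; multifurcating inputs are allowed and
then simply cannot reach 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import MotuinvError
from .io import write_tree

Split = frozenset  # a split is the anchor-free side of a bipartition


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def restricted_splits(tree: dendropy.Tree, leaves: set[str]) -> set[Split]:
    """Nontrivial splits of the tree restricted to ``leaves``.

    Each split is canonicalized as the side *not* containing the
    lexicographically smallest leaf, so split sets from different trees are
    directly comparable.
    """
    if len(leaves) < 4:
        return set()
    anchor = min(leaves)
    n = len(leaves)
    splits: set[Split] = set()
    clades: dict[int, set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            clades[id(node)] = {label} if label in leaves else set()
        else:
            clade: set[str] = set()
            for child in node.child_nodes():
                clade |= clades[id(child)]
            clades[id(node)] = clade
            side = clade if anchor not in clade else leaves - clade
            if 2 <= len(side) <= n - 2:
                splits.add(frozenset(side))
    return splits


@dataclass(frozen=True)
class RFResult:
    """Robinson-Foulds distance on the shared leaf set of two trees."""

    rf: int
    n_shared: int

    @property
    def normalized(self) -> float:
        return self.rf / (2 * (self.n_shared - 3))


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> RFResult:
    """Symmetric difference of split sets after restriction to shared leaves."""
    shared = leaf_labels(t1) & leaf_labels(t2)
    if len(shared) < 4:
        raise MotuinvError(
            f"Robinson-Foulds needs >= 4 shared leaves, got {len(shared)}"
        )
    s1 = restricted_splits(t1, shared)
    s2 = restricted_splits(t2, shared)
    return RFResult(len(s1 ^ s2), len(shared))


def rf_matrix(trees: Sequence[dendropy.Tree]) -> tuple[np.ndarray, dict]:
    """Pairwise normalized RF among replicate trees plus summary stats."""
    k = len(trees)
    if k < 2:
        raise MotuinvError("need at least 2 trees")
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = robinson_foulds(trees[i], trees[j]).normalized
    off = mat[np.triu_indices(k, 1)]
    summary = {
        "min": float(off.min()),
        "max": float(off.max()),
        "mean": float(off.mean()),
        "n_trees": k,
    }
    return mat, summary


def _nrf_from_splits(
    splits: Sequence[set[Split]], n_leaves: int
) -> np.ndarray:
    k = len(splits)
    mat = np.zeros((k, k))
    denom = 2 * (n_leaves - 3)
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = len(splits[i] ^ splits[j]) / denom
    return mat


def leaf_instability(trees: Sequence[dendropy.Tree]) -> pd.Series:
    """Rank leaves by how much their removal reconciles replicate trees.

    The instability score of a leaf is the mean, over tree pairs, of
    nRF(pair) - nRF(pair with the leaf pruned): a leaf that wanders between
    runs scores high, a stably placed leaf near zero.  Works on the leaf set
    common to all trees.
    """
    common = set.intersection(*(leaf_labels(t) for t in trees))
    if len(common) < 5:
        raise MotuinvError("instability ranking needs >= 5 common leaves")
    k = len(trees)
    iu = np.triu_indices(k, 1)
    base_splits = [restricted_splits(t, common) for t in trees]
    base = _nrf_from_splits(base_splits, len(common))[iu]
    scores = {}
    for leaf in sorted(common):
        reduced_set = common - {leaf}
        reduced_splits = [restricted_splits(t, reduced_set) for t in trees]
        reduced = _nrf_from_splits(reduced_splits, len(reduced_set))[iu]
        scores[leaf] = float((base - reduced).mean())
    return pd.Series(scores, name="instability").sort_values(
        ascending=False, kind="stable"
    )


# ---------------------------------------------------------------------------
# Backbone constraints
# ---------------------------------------------------------------------------


@dataclass
class BackboneConstraint:
    """A tree over anchor taxa constraining a search over a superset.

    Taxa not on the backbone are free; the convention matches constrained
    searches where only the relative topology of the anchors is fixed.
    """

    backbone: dendropy.Tree
    full_taxa: list[str]

    def __post_init__(self) -> None:
        anchors = leaf_labels(self.backbone)
        extra = anchors - set(self.full_taxa)
        if extra:
            raise MotuinvError(
                f"anchor taxa missing from the full taxon list: {sorted(extra)[:5]}"
            )

    @property
    def anchors(self) -> set[str]:
        return leaf_labels(self.backbone)


def write_constraint(bc: BackboneConstraint, path: str | Path) -> None:
    """Write the backbone (anchors only, multifurcations allowed) as newick."""
    write_tree(bc.backbone, path)


@dataclass(frozen=True)
class ComplianceResult:
    compliant: bool
    violated: tuple[Split, ...]


def check_backbone_compliance(
    full: dendropy.Tree, bc: BackboneConstraint
) -> ComplianceResult:
    """Does the full tree, restricted to the anchors, display every
    nontrivial backbone split?"""
    anchors = bc.anchors
    missing = anchors - leaf_labels(full)
    if missing:
        raise MotuinvError(
            f"full tree lacks anchor taxa: {sorted(missing)[:5]}"
        )
    need = restricted_splits(bc.backbone, anchors)
    have = restricted_splits(full, anchors)
    violated = tuple(sorted(need - have, key=sorted))
    return ComplianceResult(not violated, violated)
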