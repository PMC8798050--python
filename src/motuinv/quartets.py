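"""Quartet-based support measures.

Two complementary views of how strongly data support an internal branch:

* :func:`branch_quartet_support` — for each internal branch of a reference
  (species) tree, the branch defines a quadripartition of the leaves into
  blocks (A, B | C, D).  Every quartet with one leaf per block has three
  possible resolutions; the function reports, over a set of gene trees, the
  frequencies (q1, q2, q3) of the species-tree resolution AB|CD and the two
  alternatives AC|BD and AD|BC — the quantities behind per-branch pie
  charts in coalescent species-tree summaries.
* :func:`fclm` — four-cluster likelihood mapping on an alignment: for
  quartets drawn one-per-group from four predefined taxon groups, the
  maximized Jukes-Cantor log-likelihoods of the three quartet topologies
  give per-quartet weights (p1, p2, p3); each quartet is assigned to the
  basin of its best topology (ties -> unresolved) and basin percentages are
  reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .distances import _encode
from .errors import MotuinvError
from .io import Alignment

TOPOLOGY_LABELS = ("T1", "T2", "T3")


# ---------------------------------------------------------------------------
# Gene-tree quartet support
# ---------------------------------------------------------------------------


def collapse_low_support(
    tree: dendropy.Tree, threshold: float
) -> dendropy.Tree:
    """Collapse internal branches whose support label is <= threshold.

    Support values are read from internal node labels (the usual newick
    convention for bootstrap support); unlabeled branches are kept.
    """
    tree = tree.clone(depth=1)
    for edge in list(tree.preorder_edge_iter()):
        head = edge.head_node
        if head.is_leaf() or edge.tail_node is None:
            continue
        label = head.label
        if label is None:
            continue
        try:
            support = float(label)
        except ValueError:
            continue
        if support <= threshold:
            edge.collapse()
    return tree


def _topological_distances(tree: dendropy.Tree) -> tuple[dict[str, int], np.ndarray]:
    """Leaf-to-leaf path lengths in edge counts (polytomies allowed)."""
    leaves = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    index = {label: i for i, label in enumerate(leaves)}
    n = len(leaves)
    dist = np.zeros((n, n), dtype=np.int64)
    # postorder accumulation of (leaf, depth-below-node) lists
    below: dict[int, list[tuple[int, int]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [(index[node.taxon.label], 0)]
            continue
        child_lists = []
        for child in node.child_nodes():
            lst = [(leaf, depth + 1) for leaf, depth in below.pop(id(child))]
            child_lists.append(lst)
        for la, lb in itertools.combinations(child_lists, 2):
            for leaf_a, da in la:
                for leaf_b, db in lb:
                    dist[leaf_a, leaf_b] = dist[leaf_b, leaf_a] = da + db
        below[id(node)] = [x for lst in child_lists for x in lst]
    return index, dist


def _quartet_topology(
    dist: np.ndarray, a: int, b: int, c: int, d: int
) -> int | None:
    """Resolution of quartet {a,b,c,d}: 0 for ab|cd, 1 for ac|bd, 2 for
    ad|bc, None if unresolved (polytomy)."""
    sums = (
        dist[a, b] + dist[c, d],
        dist[a, c] + dist[b, d],
        dist[a, d] + dist[b, c],
    )
    best = min(sums)
    winners = [k for k, s in enumerate(sums) if s == best]
    return winners[0] if len(winners) == 1 else None


def _quadripartitions(
    species_tree: dendropy.Tree,
) -> list[tuple[tuple[str, ...], ...]]:
    """Blocks (A, B, C, D) for every internal branch of the reference tree.

    The tree is treated as unrooted; branches incident to polytomies are
    skipped (their quadripartition is not defined).
    """
    tree = species_tree.clone(depth=1)
    tree.deroot()
    all_leaves = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    clades: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clades[id(node)] = frozenset({node.taxon.label})
        else:
            clades[id(node)] = frozenset().union(
                *(clades[id(c)] for c in node.child_nodes())
            )
    out = []
    seed = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is seed or node.is_leaf():
            continue
        parent = node.parent_node
        # head side: children of the branch's head node
        head_blocks = [clades[id(c)] for c in node.child_nodes()]
        # tail side: the other neighbors of the branch's tail node
        tail_blocks = [
            clades[id(c)] for c in parent.child_nodes() if c is not node
        ]
        if parent is not seed:
            tail_blocks.append(all_leaves - clades[id(parent)])
        if len(head_blocks) != 2 or len(tail_blocks) != 2:
            continue  # polytomy: no unique quadripartition
        a, b = sorted(head_blocks, key=min)
        c, d = sorted(tail_blocks, key=min)
        out.append((tuple(sorted(a)), tuple(sorted(b)),
                    tuple(sorted(c)), tuple(sorted(d))))
    return out


def _sample_block_quartets(
    blocks: tuple[tuple[str, ...], ...],
    cap: int,
    rng: np.random.Generator,
) -> list[tuple[str, str, str, str]]:
    sizes = [len(b) for b in blocks]
    total = int(np.prod(sizes))
    if total <= cap:
        return list(itertools.product(*blocks))
    picks = rng.choice(total, size=cap, replace=False)
    out = []
    for flat in picks:
        idx = []
        for s in reversed(sizes):
            idx.append(int(flat % s))
            flat //= s
        idx.reverse()
        out.append(tuple(block[i] for block, i in zip(blocks, idx)))
    return out


def branch_quartet_support(
    species_tree: dendropy.Tree,
    gene_trees: list[dendropy.Tree],
    collapse_threshold: float | None = None,
    max_quartets_per_branch: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Quartet frequencies (q1, q2, q3) per internal branch of a reference
    tree, over a collection of gene trees.

    q1 is the frequency of the reference resolution AB|CD among resolved
    induced quartets; q2 and q3 are AC|BD and AD|BC.  Gene-tree branches
    with support <= ``collapse_threshold`` are collapsed first.  Branches
    for which no gene tree contains a usable quartet get NaN frequencies.
    """
    if collapse_threshold is not None:
        gene_trees = [collapse_low_support(t, collapse_threshold) for t in gene_trees]
    ref_leaves = {leaf.taxon.label for leaf in species_tree.leaf_node_iter()}
    gt_data = []
    for gt in gene_trees:
        labels = {leaf.taxon.label for leaf in gt.leaf_node_iter()}
        if not labels <= ref_leaves:
            raise MotuinvError(
                "gene-tree leaves must be a subset of the species-tree leaves"
            )
        gt_data.append(_topological_distances(gt))
    rng = np.random.default_rng(seed)
    rows = []
    for blocks in _quadripartitions(species_tree):
        quartets = _sample_block_quartets(blocks, max_quartets_per_branch, rng)
        counts = np.zeros(3, dtype=np.int64)
        unresolved = 0
        for taxa in quartets:
            for index, dist in gt_data:
                if any(t not in index for t in taxa):
                    continue
                topo = _quartet_topology(dist, *(index[t] for t in taxa))
                if topo is None:
                    unresolved += 1
                else:
                    counts[topo] += 1
        total = int(counts.sum())
        freqs = counts / total if total else np.full(3, np.nan)
        rows.append(
            {
                "branch": "|".join(min(b) for b in blocks),
                "block_a": ",".join(blocks[0]),
                "block_b": ",".join(blocks[1]),
                "block_c": ",".join(blocks[2]),
                "block_d": ",".join(blocks[3]),
                "q1": freqs[0],
                "q2": freqs[1],
                "q3": freqs[2],
                "n_resolved": total,
                "n_unresolved": unresolved,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Four-cluster likelihood mapping (JC69)
# ---------------------------------------------------------------------------


def _jc_p(t: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """JC69 probabilities of (same, different) state after branch length t."""
    e = np.exp(-4.0 * np.asarray(t) / 3.0)
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e


def _tip_conditionals(b: np.ndarray, t: float) -> np.ndarray:
    """(4, npat) array of P(tip state | ancestral state x) under JC."""
    same, diff = _jc_p(t)
    return np.where(np.arange(4)[:, None] == b[None, :], same, diff)


def _quartet_loglik(
    bases: tuple[np.ndarray, ...], counts: np.ndarray, branch_lengths: np.ndarray,
    pairing: tuple[int, int, int, int],
) -> float:
    """JC log-likelihood of the quartet topology pairing (i,j)|(k,l)."""
    i, j, k, l = pairing
    ti, tj, tk, tl, tm = branch_lengths
    u = _tip_conditionals(bases[i], ti) * _tip_conditionals(bases[j], tj)
    v = _tip_conditionals(bases[k], tk) * _tip_conditionals(bases[l], tl)
    same, diff = _jc_p(tm)
    p5 = np.full((4, 4), diff)
    np.fill_diagonal(p5, same)
    site = 0.25 * (u * (p5 @ v)).sum(axis=0)
    return float((counts * np.log(np.maximum(site, 1e-300))).sum())


_PAIRINGS = ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2))


def _max_loglik(bases, counts, pairing) -> float:
    def neg(x):
        return -_quartet_loglik(bases, counts, x, pairing)

    best = -np.inf
    for x0 in (0.1, 0.5):
        res = minimize(
            neg, np.full(5, x0), method="L-BFGS-B",
            bounds=[(1e-8, 20.0)] * 5, options={"maxiter": 200},
        )
        best = max(best, -float(res.fun))
    return best


@dataclass
class FcLMReport:
    """Outcome of a four-cluster likelihood mapping analysis."""

    groups: dict[str, tuple[str, ...]]
    n_total: int
    n_sampled: int
    n_skipped: int
    quartets: pd.DataFrame = field(repr=False)

    @property
    def basin_percent(self) -> dict[str, float]:
        """Percentage of evaluated quartets in each topology's basin
        (plus 'unresolved'); sums to 100."""
        evaluated = len(self.quartets)
        out = {label: 0.0 for label in TOPOLOGY_LABELS + ("unresolved",)}
        if evaluated:
            shares = self.quartets["basin"].value_counts()
            for label, count in shares.items():
                out[label] = 100.0 * count / evaluated
        return out


def fclm(
    aln: Alignment,
    groups: dict[str, list[str]] | list[list[str]],
    n_quartets: int = 1000,
    seed: int = 0,
    min_overlap: int = 100,
    tie_tol: float = 1e-6,
) -> FcLMReport:
    """Four-cluster likelihood mapping under JC69.

    ``groups`` names four disjoint taxon sets.  T1 is the topology grouping
    (group1, group2 | group3, group4), T2 is (1,3|2,4), T3 is (1,4|2,3).
    Per quartet, weights p_i are the softmax of the three maximized
    log-likelihoods; the basin is the argmax topology, with ties (weight
    difference below ``tie_tol``) reported as unresolved.  Quartets whose
    four sequences share fewer than ``min_overlap`` jointly resolved sites
    are skipped.
    """
    if not isinstance(groups, dict):
        groups = {f"G{i+1}": g for i, g in enumerate(groups)}
    names = list(groups)
    if len(names) != 4:
        raise MotuinvError("FcLM requires exactly four taxon groups")
    sets = [list(groups[n]) for n in names]
    flat = [t for g in sets for t in g]
    if len(set(flat)) != len(flat):
        raise MotuinvError("FcLM groups must be disjoint")
    for name, g in zip(names, sets):
        if not g:
            raise MotuinvError(f"FcLM group {name!r} is empty")
        for t in g:
            if t not in aln:
                raise MotuinvError(f"taxon {t!r} not in alignment")
    rng = np.random.default_rng(seed)
    combos = _sample_block_quartets(tuple(tuple(g) for g in sets), n_quartets, rng)
    n_total = int(np.prod([len(g) for g in sets]))
    codes = {rec.id: _encode([rec.seq])[0] for rec in aln}
    rows = []
    n_skipped = 0
    for taxa in combos:
        quartet_codes = [codes[t] for t in taxa]
        ok = np.all([c != 255 for c in quartet_codes], axis=0)
        if int(ok.sum()) < min_overlap:
            n_skipped += 1
            continue
        bases = tuple(c[ok].astype(np.int64) for c in quartet_codes)
        patterns = ((bases[0] * 4 + bases[1]) * 4 + bases[2]) * 4 + bases[3]
        counts = np.bincount(patterns, minlength=256).astype(float)
        keep = counts > 0
        counts = counts[keep]
        pat = np.flatnonzero(keep)
        pat_bases = (pat // 64 % 4, pat // 16 % 4, pat // 4 % 4, pat % 4)
        lls = np.array(
            [_max_loglik(pat_bases, counts, p) for p in _PAIRINGS]
        )
        w = np.exp(lls - lls.max())
        w /= w.sum()
        order = np.argsort(w)[::-1]
        if w[order[0]] - w[order[1]] < tie_tol:
            basin = "unresolved"
        else:
            basin = TOPOLOGY_LABELS[order[0]]
        rows.append(
            {
                "taxa": "|".join(taxa),
                "ll1": lls[0], "ll2": lls[1], "ll3": lls[2],
                "p1": w[0], "p2": w[1], "p3": w[2],
                "basin": basin,
            }
        )
    quartets = pd.DataFrame(
        rows, columns=["taxa", "ll1", "ll2", "ll3", "p1", "p2", "p3", "basin"]
    )
    return FcLMReport(
        groups={n: tuple(g) for n, g in zip(names, sets)},
        n_total=n_total,
        n_sampled=len(combos),
        n_skipped=n_skipped,
        quartets=quartets,
    )
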