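"""Uncorrected pairwise distances and desk-scale distance-tree builders.

Distances are p-distances with pairwise deletion: per sequence pair, only
sites where both symbols are unambiguous nucleotides (A/C/G/T) are compared;
gaps, '?', 'N' and partial IUPAC ambiguities count as missing.  A pair whose
overlap falls below ``min_overlap`` jointly resolved sites has an *undefined*
distance (NaN), which downstream clustering treats as "never linked".

The NJ and UPGMA builders exist so the pipeline can produce trees at desk
scale without external software; both break ties by the lowest row index, so
output is deterministic for a fixed input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .errors import MotuinvError
from .io import DNA_STATES, Alignment

#: Default minimum number of jointly resolved sites for a defined distance.
DEFAULT_MIN_OVERLAP = 100


@dataclass
class DistanceMatrix:
    """Symmetric uncorrected distances with per-pair overlap counts.

    ``d[i, j]`` is NaN where the pair's overlap is below the ``min_overlap``
    used at construction.
    """

    ids: list[str]
    d: np.ndarray
    overlap: np.ndarray
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.overlap.shape != (n, n):
            raise MotuinvError("distance/overlap matrix shape mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, terminal_id: str) -> int:
        return self.ids.index(terminal_id)

    def get(self, a: str, b: str) -> float:
        """Distance between two ids (NaN if undefined)."""
        return float(self.d[self.index(a), self.index(b)])

    @property
    def n_undefined(self) -> int:
        """Number of undefined (below-overlap) off-diagonal pairs."""
        return int(np.isnan(self.d).sum() - np.isnan(np.diag(self.d)).sum()) // 2

    def defined(self) -> np.ndarray:
        """Boolean mask of defined entries."""
        return ~np.isnan(self.d)

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(i) for i in ids]
        return DistanceMatrix(
            list(ids), self.d[np.ix_(idx, idx)].copy(),
            self.overlap[np.ix_(idx, idx)].copy(), self.min_overlap,
        )


def _encode(seqs: Sequence[str]) -> np.ndarray:
    """Map sequences to uint8 codes 0..3 for A,C,G,T and 255 for missing."""
    lut = np.full(256, 255, dtype=np.uint8)
    for i, base in enumerate(DNA_STATES):
        lut[ord(base)] = i
        lut[ord(base.lower())] = i
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return lut[arr].reshape(len(seqs), -1)


def p_distance(a: str, b: str, min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """Uncorrected distance between two aligned sequences.

    Returns NaN (undefined) if fewer than ``min_overlap`` sites are jointly
    resolved.  Raises on unequal lengths.
    """
    if len(a) != len(b):
        raise MotuinvError(
            f"unequal sequence lengths: {len(a)} vs {len(b)}"
        )
    codes = _encode([a, b])
    both = (codes[0] != 255) & (codes[1] != 255)
    n = int(both.sum())
    if n < min_overlap:
        return float("nan")
    mismatches = int((codes[0][both] != codes[1][both]).sum())
    return mismatches / n


def distance_matrix(
    aln: Alignment, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceMatrix:
    """All-pairs p-distance matrix with pairwise deletion.

    Vectorized via per-state indicator products: overlap = R·Rᵀ and
    matches = Σ_s X_s·X_sᵀ, where R marks resolved sites and X_s state s.
    """
    codes = _encode([rec.seq for rec in aln])
    resolved = (codes != 255)
    overlap = resolved.astype(np.int64) @ resolved.T.astype(np.int64)
    matches = np.zeros_like(overlap)
    for s in range(4):
        x = (codes == s).astype(np.int64)
        matches += x @ x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (overlap - matches) / overlap
    d[overlap < min_overlap] = np.nan
    np.fill_diagonal(d, np.where(np.diag(overlap) >= min_overlap, 0.0, np.nan))
    # single-sequence / self comparisons: diagonal is zero by definition
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(aln.ids, d, overlap, min_overlap)


# ---------------------------------------------------------------------------
# Tree building
# ---------------------------------------------------------------------------


def _require_defined(dm: DistanceMatrix) -> np.ndarray:
    if np.isnan(dm.d).any():
        raise MotuinvError(
            "distance matrix has undefined entries (overlap below "
            f"{dm.min_overlap}); impute or remove those terminals before "
            "building a tree"
        )
    return dm.d.astype(float).copy()


def _newick_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; ties broken by lowest (i, j) index pair.

    Additive distance matrices are recovered exactly.  Requires n >= 3 and a
    fully defined matrix.
    """
    n = len(dm)
    if n < 3:
        raise MotuinvError("neighbor joining needs at least 3 terminals")
    d = _require_defined(dm)
    # nodes are newick subtree strings; indices track the active rows
    nodes = [f"{_escape(t)}" for t in dm.ids]
    active = list(range(n))
    D = d
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie rule: argmin on flattened array takes the first
        i_, j_ = divmod(int(np.argmin(q)), m)
        if i_ > j_:
            i_, j_ = j_, i_
        i, j = active[i_], active[j_]
        dij = D[i, j]
        bi = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        bj = dij - bi
        # guard tiny negatives from numerics
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        new = f"({nodes[i]}:{bi:.10g},{nodes[j]}:{bj:.10g})"
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, dnew])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    a, b, c = active
    ba = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    bb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    bc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    ba, bb, bc = (max(x, 0.0) for x in (ba, bb, bc))
    newick = (
        f"({nodes[a]}:{ba:.10g},{nodes[b]}:{bb:.10g},{nodes[c]}:{bc:.10g});"
    )
    return _newick_tree(newick)


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """UPGMA (average linkage, ultrametric heights); lowest-index merge ties."""
    n = len(dm)
    if n < 2:
        raise MotuinvError("UPGMA needs at least 2 terminals")
    D = _require_defined(dm)
    nodes = [_escape(t) for t in dm.ids]
    heights = [0.0] * n
    sizes = [1] * n
    active = list(range(n))
    while len(active) > 1:
        m = len(active)
        sub = D[np.ix_(active, active)].copy()
        np.fill_diagonal(sub, np.inf)
        i_, j_ = divmod(int(np.argmin(sub)), m)
        if i_ > j_:
            i_, j_ = j_, i_
        i, j = active[i_], active[j_]
        h = D[i, j] / 2.0
        bi, bj = h - heights[i], h - heights[j]
        new = f"({nodes[i]}:{bi:.10g},{nodes[j]}:{bj:.10g})"
        si, sj = sizes[i], sizes[j]
        dnew = (si * D[i, :] + sj * D[j, :]) / (si + sj)
        D = np.vstack([D, dnew])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        nodes.append(new)
        heights.append(h)
        sizes.append(si + sj)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    return _newick_tree(nodes[active[0]] + ";")


def _escape(label: str) -> str:
    """Quote a leaf label if it contains newick-special characters."""
    if any(c in label for c in "(),:;[] '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label
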