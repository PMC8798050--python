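"""Distance-threshold mOTU delimitation.

A molecular operational taxonomic unit (mOTU) is a cluster of terminals
within a stated uncorrected-distance threshold, treated as a putative
species.  Two clustering rules are provided:

* ``single_linkage`` — clusters are connected components of the graph
  linking pairs with a *defined* distance <= t.  This is the reference
  method for headline counts.
* ``greedy`` — a CD-HIT-style incremental rule: terminals are processed in
  descending ungapped length (ties: lexicographic id); each joins the first
  existing cluster whose *representative* is within t, else founds a new
  cluster.  Provided for comparability with similarity-based delimitation
  tools; a CD-HIT similarity s corresponds to the distance threshold
  t = 1 - s.

Undefined distances (pairwise overlap below ``min_overlap``) never link.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix
from .errors import MotuinvError
from .io import Alignment, VoucherMetadata

METHODS = ("single_linkage", "greedy")


@dataclass
class MotuPartition:
    """Terminal-to-cluster assignment at one distance threshold."""

    threshold: float
    method: str
    assignment: dict[str, int]
    representatives: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, rep in self.representatives.items():
            if self.assignment.get(rep) != cid:
                raise MotuinvError(
                    f"representative {rep!r} is not a member of cluster {cid}"
                )

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[int, list[str]]:
        """Cluster id -> member ids, members in assignment order."""
        out: dict[int, list[str]] = {}
        for term, cid in self.assignment.items():
            out.setdefault(cid, []).append(term)
        return out


@dataclass
class SweepCurve:
    """mOTU counts across a grid of distance thresholds."""

    thresholds: list[float]
    counts: list[int]

    def __post_init__(self) -> None:
        pairs = sorted(zip(self.thresholds, self.counts))
        for (t1, c1), (t2, c2) in zip(pairs, pairs[1:]):
            if t1 < t2 and c2 > c1:
                raise MotuinvError(
                    f"mOTU count increased with threshold ({t1}->{t2}: "
                    f"{c1}->{c2}); sweep is not monotone"
                )

    def as_dict(self) -> dict[float, int]:
        return dict(zip(self.thresholds, self.counts))


def _check_threshold(t: float) -> None:
    if not (0.0 <= t <= 1.0):
        raise MotuinvError(f"threshold must be in [0, 1], got {t}")


def _canonical_ids(ids: Sequence[str], labels: np.ndarray) -> dict[str, int]:
    """Renumber raw component labels by order of first appearance."""
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for term, lab in zip(ids, labels):
        lab = int(lab)
        if lab not in remap:
            remap[lab] = len(remap)
        assignment[term] = remap[lab]
    return assignment


def cluster_single_linkage(dm: DistanceMatrix, t: float) -> MotuPartition:
    """Connected components of the <=t threshold graph on defined distances."""
    _check_threshold(t)
    with np.errstate(invalid="ignore"):
        link = (dm.d <= t) & ~np.isnan(dm.d)
    adj = csr_matrix(link.astype(np.int8))
    _, labels = connected_components(adj, directed=False)
    assignment = _canonical_ids(dm.ids, labels)
    reps = {}
    for term, cid in assignment.items():
        reps.setdefault(cid, term)  # provisional: first member
    return MotuPartition(t, "single_linkage", assignment, reps)


def _greedy_order(aln: Alignment) -> list[str]:
    return [
        rec.id
        for rec in sorted(aln, key=lambda r: (-r.ungapped_length, r.id))
    ]


def cluster_greedy(aln: Alignment, dm: DistanceMatrix, t: float) -> MotuPartition:
    """CD-HIT-style greedy clustering against cluster representatives.

    The result is invariant to input file order because processing order is
    by (descending ungapped length, id).
    """
    _check_threshold(t)
    if set(aln.ids) != set(dm.ids):
        raise MotuinvError("alignment and distance matrix cover different ids")
    order = _greedy_order(aln)
    idx = {term: i for i, term in enumerate(dm.ids)}
    assignment: dict[str, int] = {}
    reps: list[str] = []  # representative of cluster k at position k
    for term in order:
        joined = False
        for cid, rep in enumerate(reps):
            d = dm.d[idx[term], idx[rep]]
            if not np.isnan(d) and d <= t:
                assignment[term] = cid
                joined = True
                break
        if not joined:
            assignment[term] = len(reps)
            reps.append(term)
    return MotuPartition(t, "greedy", assignment, dict(enumerate(reps)))


def cluster(
    dm: DistanceMatrix,
    t: float,
    method: str = "single_linkage",
    aln: Alignment | None = None,
) -> MotuPartition:
    """Dispatch to a clustering method by name."""
    if method == "single_linkage":
        return cluster_single_linkage(dm, t)
    if method == "greedy":
        if aln is None:
            raise MotuinvError("greedy clustering requires the alignment")
        return cluster_greedy(aln, dm, t)
    raise MotuinvError(f"unknown clustering method {method!r}")


#: Default sweep grid: 1%..10% distance in 1% steps.
DEFAULT_SWEEP_GRID = [round(0.01 * k, 2) for k in range(1, 11)]


def threshold_sweep(
    dm: DistanceMatrix,
    thresholds: Iterable[float] | None = None,
    method: str = "single_linkage",
    aln: Alignment | None = None,
) -> SweepCurve:
    """Cluster at each threshold and record the mOTU count."""
    ts = sorted(thresholds) if thresholds is not None else list(DEFAULT_SWEEP_GRID)
    counts = [cluster(dm, t, method=method, aln=aln).n_clusters for t in ts]
    return SweepCurve(ts, counts)


def select_representatives(
    partition: MotuPartition, aln: Alignment
) -> list[str]:
    """One terminal per mOTU: longest ungapped sequence, ties by smallest id.

    Updates ``partition.representatives`` in place and returns the pruned id
    list in cluster-id order.
    """
    lengths = {rec.id: rec.ungapped_length for rec in aln}
    chosen: dict[int, str] = {}
    for cid, members in sorted(partition.clusters().items()):
        chosen[cid] = min(members, key=lambda m: (-lengths[m], m))
    partition.representatives = chosen
    return [chosen[cid] for cid in sorted(chosen)]


def count_motus(
    partition: MotuPartition,
    metadata: Iterable[VoucherMetadata],
    require_fragment: str = "cox1",
) -> int:
    """mOTU count after dropping terminals lacking a required fragment.

    A cluster is counted if at least one member carries the fragment;
    terminals without a metadata row are treated as lacking it.
    """
    has = {
        m.terminal_id
        for m in metadata
        if require_fragment in m.fragments_present
    }
    counted = {
        cid
        for term, cid in partition.assignment.items()
        if term in has
    }
    return len(counted)
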