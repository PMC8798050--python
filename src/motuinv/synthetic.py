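"""Synthetic datasets with the statistical structure the inventory assumes.

The generator emulates a multi-species barcoding sample: a Yule species tree
rescaled so the closest species pair is at least ``inter_min`` expected
substitutions/site apart, several terminals per species hanging off each
species tip within ``intra_max`` of each other (the "barcode gap" is the
separation between those two scales), Jukes-Cantor sequence evolution for
each mtDNA fragment, island geography with tunable endemism, and per-
terminal fragment missingness.  Every emitted terminal carries a truth row
(true species, occupied landmasses), so parameter-recovery tests can compare
pipeline output with known truth.

Distances are stated in expected substitutions/site; the realized
p-distance concentrates on the JC expectation P(d) = 3/4 (1 - e^(-4d/3)),
so the barcode-gap guarantee is probabilistic, not absolute.

All randomness flows from one mandatory seed through a documented
stream-splitting scheme (one :class:`numpy.random.SeedSequence` child per
stage), so stages are individually reproducible and emitted files are
byte-identical across runs with the same seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import yaml

from .errors import MotuinvError
from .io import (
    Alignment,
    BarrierMap,
    SequenceRecord,
    VoucherMetadata,
    write_alignment,
    write_metadata,
    write_tree,
)

SUBTRIBES = ("Metriorrhynchina", "Cautirina", "Metanoeina")
SUBTRIBE_WEIGHTS = (0.75, 0.20, 0.05)

#: Default island geography: landmass -> region.
DEFAULT_GEOGRAPHY: dict[str, str] = {
    "New Guinea": "New Guinea",
    "Australia": "Australia",
    "Sulawesi": "Wallacea",
    "Borneo": "Sundaland",
    "Sumatra": "Sundaland",
    "Luzon": "Philippines",
}

#: Default sea barriers: the New Guinea/Australia and Borneo/Sumatra pairs
#: sit on inundated shelf (< 100 m); all other pairs are deep sea (> 200 m).
DEFAULT_BARRIERS: dict[str, str] = {
    "Australia|New Guinea": "shelf",
    "Borneo|Sumatra": "shelf",
}


def default_barrier_map(landmasses: Sequence[str] | None = None) -> BarrierMap:
    landmasses = list(landmasses or DEFAULT_GEOGRAPHY)
    bm = BarrierMap()
    for a, b in itertools.combinations(sorted(landmasses), 2):
        bm.set(a, b, DEFAULT_BARRIERS.get(f"{a}|{b}", "deep_sea"))
    return bm


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults give a clean barcode gap.

    ``intra_max``/``inter_min`` are expected substitutions/site (maximum
    within-species pairwise divergence and minimum between-species tip
    distance).  Fragment lengths and missingness follow typical voucher
    panels of three mtDNA fragments where the barcode fragment is nearly
    always present and the others are often absent.
    """

    seed: int
    n_species: int = 50
    terminals_per_species: tuple[int, int] = (5, 5)  # uniform inclusive bounds
    intra_max: float = 0.005
    inter_min: float = 0.08
    tree_depth: float = 0.5
    gamma_shape: float | None = None
    fragments: Mapping[str, int] = field(
        default_factory=lambda: {"cox1": 1100, "rrnL": 800, "nad5": 1210}
    )
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {"cox1": 0.077, "rrnL": 0.630, "nad5": 0.502}
    )
    geography: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GEOGRAPHY)
    )
    endemism_p: float = 0.95
    dispersal_p: float = 0.5
    allow_gap_overlap: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise MotuinvError("a seed is mandatory")
        if not self.allow_gap_overlap and self.intra_max >= self.inter_min:
            raise MotuinvError(
                "intra_max must be below inter_min (no barcode gap); "
                "set allow_gap_overlap=True to override"
            )
        lo, hi = self.terminals_per_species
        if lo < 1 or hi < lo:
            raise MotuinvError("terminals_per_species bounds must be 1 <= lo <= hi")
        for name, p in self.missingness.items():
            if name not in self.fragments:
                raise MotuinvError(f"missingness for unknown fragment {name!r}")
            if not 0.0 <= p <= 1.0:
                raise MotuinvError("missingness must be a probability")


@dataclass
class SyntheticTruth:
    """Ground truth for one emitted dataset."""

    terminal_species: dict[str, str]
    species_occupancy: dict[str, tuple[str, ...]]
    species_subtribe: dict[str, str]
    species_tree: dendropy.Tree

    @property
    def n_species(self) -> int:
        return len(self.species_occupancy)


@dataclass
class SyntheticDataset:
    fragments: list[tuple[str, Alignment]]
    metadata: list[VoucherMetadata]
    truth: SyntheticTruth
    barriers: BarrierMap
    config: SimulationConfig


def _min_tip_distance(tree: dendropy.Tree) -> float:
    """Minimum patristic distance between any two tips."""
    best = np.inf
    below: dict[int, list[float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [0.0]
            continue
        lists = []
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            lists.append([d + bl for d in below.pop(id(child))])
        for la, lb in itertools.combinations(lists, 2):
            cand = min(la) + min(lb)
            best = min(best, cand)
        below[id(node)] = [d for lst in lists for d in lst]
    return float(best)


class _YuleNode:
    __slots__ = ("birth", "end", "children", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.end: float | None = None
        self.children: list["_YuleNode"] = []
        self.label: str | None = None

    def newick(self) -> str:
        length = (self.end or 0.0) - self.birth
        if self.children:
            inner = ",".join(c.newick() for c in self.children)
            return f"({inner}):{length:.12g}"
        return f"{self.label}:{length:.12g}"


def simulate_species_tree(
    n_species: int,
    depth: float,
    seed: int,
    inter_min: float = 0.0,
) -> dendropy.Tree:
    """Yule topology with ``n_species`` tips, scaled to the given root
    height, then rescaled up if needed so the minimum inter-tip path is at
    least ``inter_min``.

    The pure-birth process is simulated directly: exponential waiting times
    at total rate k for k extant lineages, a uniformly chosen lineage splits
    at each event, and the tips are extended past the last split by one more
    exponential draw so every pendant branch is positive.
    """
    if n_species < 2:
        raise MotuinvError("need at least 2 species")
    rng = np.random.default_rng(int(seed))
    t = 0.0
    root = _YuleNode(0.0)
    root.end = 0.0
    active = [_YuleNode(0.0), _YuleNode(0.0)]
    root.children = list(active)
    while len(active) < n_species:
        t += float(rng.exponential(1.0 / len(active)))
        idx = int(rng.integers(len(active)))
        node = active[idx]
        node.end = t
        node.children = [_YuleNode(t), _YuleNode(t)]
        active[idx: idx + 1] = node.children
    t += float(rng.exponential(1.0 / n_species))
    for i, node in enumerate(active):
        node.end = t
        node.label = f"sp{i + 1:04d}"
    tree = dendropy.Tree.get(
        data=root.newick() + ";", schema="newick", preserve_underscores=True
    )
    height = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    scale = depth / height if height > 0 else 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    if inter_min > 0:
        mind = _min_tip_distance(tree)
        if mind < inter_min:
            boost = inter_min / mind
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= boost
    return tree


def simulate_populations(
    species_tree: dendropy.Tree,
    terminals_per_species: Mapping[str, int] | int,
    intra_max: float,
    seed: int,
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Hang terminals off each species tip.

    Terminal pendant branches are U(0, intra_max/2), so the pairwise
    within-species distance is at most ``intra_max`` (and half that in
    expectation).  A species sampled once keeps its tip (relabeled).
    Returns the terminal tree and the terminal -> species truth map.
    """
    tree = species_tree.clone(depth=1)
    rng = np.random.default_rng(seed)
    terminal_species: dict[str, str] = {}
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    for leaf in leaves:
        sp = leaf.taxon.label
        k = (
            terminals_per_species
            if isinstance(terminals_per_species, int)
            else terminals_per_species[sp]
        )
        if k == 1:
            name = f"{sp}_t01"
            leaf.taxon.label = name
            terminal_species[name] = sp
            continue
        leaf.taxon = None
        for t in range(1, k + 1):
            name = f"{sp}_t{t:02d}"
            child = leaf.new_child(edge_length=float(rng.uniform(0, intra_max / 2)))
            child.taxon = tree.taxon_namespace.new_taxon(label=name)
            terminal_species[name] = sp
    return tree, terminal_species


_BASES = np.arange(4)


def simulate_sequences(
    tree: dendropy.Tree,
    length: int,
    seed: int,
    gamma_shape: float | None = None,
) -> Alignment:
    """Site-independent Jukes-Cantor simulation along the tree.

    A site on a branch of length d differs from its ancestor with
    probability 3/4 (1 - e^(-4d/3)); optional gamma-distributed site rates
    (mean 1) rescale d per site.
    """
    rng = np.random.default_rng(seed)
    rates = (
        rng.gamma(gamma_shape, 1.0 / gamma_shape, size=length)
        if gamma_shape
        else np.ones(length)
    )
    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.integers(0, 4, size=length)
    records = []
    for node in tree.preorder_node_iter():
        if node is not root:
            parent_seq = seqs[id(node.parent_node)]
            d = (node.edge.length or 0.0) * rates
            p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            hit = rng.random(length) < p_change
            seq = parent_seq.copy()
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()))
                seq[hit] = (seq[hit] + shift) % 4
            seqs[id(node)] = seq
        if node.is_leaf():
            chars = np.array(list("ACGT"))[seqs[id(node)]]
            records.append(SequenceRecord(node.taxon.label, "".join(chars)))
    records.sort(key=lambda r: r.id)
    return Alignment(records)


def assign_geography(
    species: Sequence[str],
    landmasses: Sequence[str],
    endemism_p: float,
    dispersal_p: float,
    seed: int,
) -> dict[str, tuple[str, ...]]:
    """Landmass occupancy per species.

    Each species draws a home landmass uniformly; with probability
    ``endemism_p`` it stays endemic, otherwise each other landmass is added
    independently with probability ``dispersal_p`` (at least one is forced,
    so a non-endemic species really spans >= 2 landmasses).
    """
    rng = np.random.default_rng(seed)
    occupancy: dict[str, tuple[str, ...]] = {}
    lms = list(landmasses)
    for sp in sorted(species):
        home = lms[int(rng.integers(len(lms)))]
        occupied = [home]
        if rng.random() >= endemism_p and len(lms) > 1:
            others = [l for l in lms if l != home]
            added = [l for l in others if rng.random() < dispersal_p]
            if not added:
                added = [others[int(rng.integers(len(others)))]]
            occupied.extend(added)
        occupancy[sp] = tuple(occupied)
    return occupancy


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all generator stages and return the in-memory dataset."""
    streams = np.random.SeedSequence(config.seed).spawn(6)
    seed_of = lambda ss: int(ss.generate_state(1, np.uint32)[0])

    species_tree = simulate_species_tree(
        config.n_species, config.tree_depth, seed_of(streams[0]),
        inter_min=config.inter_min,
    )
    species = sorted(l.taxon.label for l in species_tree.leaf_node_iter())

    lo, hi = config.terminals_per_species
    rng_n = np.random.default_rng(seed_of(streams[1]))
    per_species = {sp: int(rng_n.integers(lo, hi + 1)) for sp in species}
    terminal_tree, terminal_species = simulate_populations(
        species_tree, per_species, config.intra_max, seed_of(streams[1])
    )

    seq_streams = streams[2].spawn(len(config.fragments))
    fragments = []
    for (name, length), ss in zip(config.fragments.items(), seq_streams):
        fragments.append(
            (
                name,
                simulate_sequences(
                    terminal_tree, length, seed_of(ss), config.gamma_shape
                ),
            )
        )

    landmasses = sorted(config.geography)
    occupancy = assign_geography(
        species, landmasses, config.endemism_p, config.dispersal_p,
        seed_of(streams[3]),
    )

    rng_sub = np.random.default_rng(seed_of(streams[4]))
    subtribe = {
        sp: SUBTRIBES[
            int(rng_sub.choice(len(SUBTRIBES), p=SUBTRIBE_WEIGHTS))
        ]
        for sp in species
    }

    # fragment missingness; a terminal that would lose every fragment keeps
    # the most reliably sequenced one (lowest missingness below 1.0), so
    # every emitted terminal yields at least one sequence
    rng_miss = np.random.default_rng(seed_of(streams[5]))
    terminals = sorted(terminal_species)
    frag_names = list(config.fragments)
    fallback = min(
        (n for n in frag_names if config.missingness.get(n, 0.0) < 1.0),
        key=lambda n: config.missingness.get(n, 0.0),
        default=None,
    )
    present: dict[str, set[str]] = {t: set() for t in terminals}
    for t in terminals:
        for name in frag_names:
            if rng_miss.random() >= config.missingness.get(name, 0.0):
                present[t].add(name)
        if not present[t] and fallback is not None:
            present[t].add(fallback)
    fragments = [
        (name, Alignment([rec for rec in aln if name in present[rec.id]]))
        for name, aln in fragments
        if any(name in present[t] for t in terminals)
    ]

    # terminals cycle round-robin over their species' landmasses, so the
    # realized occupancy equals the drawn occupancy whenever a species has
    # at least as many terminals as landmasses
    metadata = []
    realized: dict[str, set[str]] = {sp: set() for sp in species}
    by_species: dict[str, list[str]] = {}
    for t in terminals:
        by_species.setdefault(terminal_species[t], []).append(t)
    for sp, terms in sorted(by_species.items()):
        occ = occupancy[sp]
        for k, t in enumerate(sorted(terms)):
            lm = occ[k % len(occ)]
            realized[sp].add(lm)
            metadata.append(
                VoucherMetadata(
                    terminal_id=t,
                    subtribe=subtribe[sp],
                    subregion=lm,
                    region=config.geography[lm],
                    landmass=lm,
                    fragments_present=frozenset(present[t]),
                )
            )
    truth = SyntheticTruth(
        terminal_species=terminal_species,
        species_occupancy={sp: tuple(sorted(realized[sp])) for sp in species},
        species_subtribe=subtribe,
        species_tree=species_tree,
    )
    return SyntheticDataset(
        fragments=fragments,
        metadata=metadata,
        truth=truth,
        barriers=default_barrier_map(landmasses),
        config=config,
    )


def emit_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a dataset; deterministic under the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(config)
    paths: dict[str, Path] = {}
    for name, aln in ds.fragments:
        p = outdir / f"{name}.fasta"
        write_alignment(aln, p)
        paths[name] = p
    paths["metadata"] = outdir / "metadata.tsv"
    write_metadata(ds.metadata, paths["metadata"])
    paths["species_tree"] = outdir / "species_tree.nwk"
    write_tree(ds.truth.species_tree, paths["species_tree"])
    paths["truth_terminals"] = outdir / "truth_terminals.tsv"
    with open(paths["truth_terminals"], "w") as fh:
        fh.write("terminal_id\tspecies\n")
        for t in sorted(ds.truth.terminal_species):
            fh.write(f"{t}\t{ds.truth.terminal_species[t]}\n")
    paths["truth_occupancy"] = outdir / "truth_occupancy.tsv"
    with open(paths["truth_occupancy"], "w") as fh:
        fh.write("species\tsubtribe\tlandmasses\n")
        for sp, occ in sorted(ds.truth.species_occupancy.items()):
            fh.write(f"{sp}\t{ds.truth.species_subtribe[sp]}\t{','.join(occ)}\n")
    paths["barriers"] = outdir / "barriers.yaml"
    with open(paths["barriers"], "w") as fh:
        yaml.safe_dump(ds.barriers.to_dict(), fh, sort_keys=True)
    return paths
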