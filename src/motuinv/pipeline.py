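"""End-to-end pipeline: data in, inventory tables out.

Wires the stages in the order a DNA-based inventory runs them:
simulate (or load) fragments and metadata -> pairwise distances on the
clustering fragment -> mOTU delimitation at the configured thresholds plus a
threshold sweep -> pruning to one representative per mOTU -> partition QC on
the concatenated supermatrix -> backbone constraint writing and compliance
checking -> replicate-tree stability (Robinson-Foulds) -> per-branch quartet
support -> regional diversity / endemism / turnover tables.

Outputs are plain TSV/newick files in the output directory, plus a manifest
with SHA-256 checksums (identical seed => identical manifest) and a run log
of the decisions taken (thresholds, exclusions, dropped partitions).
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import distances, inventory, motu, qc, quartets, synthetic, treecmp
from .errors import MotuinvError
from .io import (
    Alignment,
    BarrierMap,
    SequenceRecord,
    concatenate_fragments,
    read_alignment,
    read_metadata,
    read_tree,
    write_tree,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = [0.02, 0.05]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise MotuinvError("config must be a YAML mapping")
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping[str, Any]) -> None:
    if "simulate" not in cfg and "input" not in cfg:
        raise MotuinvError(
            "config must contain either a 'simulate' block or an 'input' block"
        )
    if "seed" not in cfg:
        raise MotuinvError("config must declare a seed")
    for t in cfg.get("thresholds", DEFAULT_THRESHOLDS):
        if not 0 <= float(t) <= 1:
            raise MotuinvError(f"threshold {t} outside [0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _bootstrap_alignment(aln: Alignment, rng: np.random.Generator) -> Alignment:
    cols = rng.integers(0, aln.length, size=aln.length)
    mat = aln.to_char_matrix()[:, cols]
    return Alignment(
        [SequenceRecord(i, "".join(row)) for i, row in zip(aln.ids, mat)]
    )


def run_pipeline(config: Mapping[str, Any] | str | Path, outdir: str | Path) -> Path:
    """Execute all stages; returns the output directory.

    Any stage failure aborts with the stage name attached to the error.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    else:
        validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("motuinv")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(dict(config), outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: dict, outdir: Path) -> Path:
    seed = int(cfg["seed"])
    thresholds = [float(t) for t in cfg.get("thresholds", DEFAULT_THRESHOLDS)]
    method = cfg.get("method", "single_linkage")
    min_overlap = int(cfg.get("min_overlap", distances.DEFAULT_MIN_OVERLAP))
    cluster_fragment = cfg.get("cluster_fragment", "cox1")
    outputs: list[Path] = []

    # ---- stage: simulate | load ------------------------------------------
    truth = None
    backbone_tree = None
    described = cfg.get("described")
    if "simulate" in cfg:
        sim_kwargs = dict(cfg.get("simulate") or {})
        sim_kwargs.setdefault("seed", seed)
        if "terminals_per_species" in sim_kwargs:
            sim_kwargs["terminals_per_species"] = tuple(
                sim_kwargs["terminals_per_species"]
            )
        sim_cfg = synthetic.SimulationConfig(**sim_kwargs)
        data_dir = outdir / "data"
        synthetic.emit_dataset(sim_cfg, data_dir)
        ds = synthetic.generate_dataset(sim_cfg)
        fragments, metadata, barriers = ds.fragments, ds.metadata, ds.barriers
        truth = ds.truth
        logger.info(
            "simulated %d species / %d terminals (seed %d)",
            truth.n_species, len(truth.terminal_species), seed,
        )
        if described is None:
            described = {}
            geography = dict(sim_cfg.geography)
            for sp, occ in truth.species_occupancy.items():
                for region in {geography[lm] for lm in occ}:
                    described[region] = described.get(region, 0) + 1
        backbone_tree = truth.species_tree
    else:
        inp = cfg["input"]
        fragments = [
            (name, read_alignment(path))
            for name, path in inp["fragments"].items()
        ]
        regions = inp.get("regions")
        landmasses = inp.get("landmasses")
        metadata = read_metadata(inp["metadata"], regions, landmasses)
        barriers = None
        if inp.get("barriers"):
            with open(inp["barriers"]) as fh:
                barriers = BarrierMap.from_dict(yaml.safe_load(fh))
        if inp.get("backbone"):
            backbone_tree = read_tree(inp["backbone"])
        described = described or {}

    # ---- stage: distances -------------------------------------------------
    frag_map = dict(fragments)
    if cluster_fragment not in frag_map:
        raise MotuinvError(
            f"clustering fragment {cluster_fragment!r} not among fragments "
            f"{sorted(frag_map)}"
        )
    aln = frag_map[cluster_fragment]
    dm = distances.distance_matrix(aln, min_overlap=min_overlap)
    logger.info(
        "distances: %d terminals on %s, %d undefined pairs",
        len(dm), cluster_fragment, dm.n_undefined,
    )

    # ---- stage: cluster + sweep ------------------------------------------
    partitions: dict[str, motu.MotuPartition] = {}
    for t in thresholds:
        label = f"{t * 100:g}%"
        part = motu.cluster(dm, t, method=method, aln=aln)
        motu.select_representatives(part, aln)
        partitions[label] = part
        counted = motu.count_motus(part, metadata, require_fragment=cluster_fragment)
        logger.info(
            "clustering at %s (%s): %d mOTUs (%d with %s)",
            label, method, part.n_clusters, counted, cluster_fragment,
        )
        df = pd.DataFrame(
            sorted(part.assignment.items()), columns=["terminal_id", "motu"]
        )
        p = outdir / f"motus_{t * 100:g}pct.tsv"
        df.to_csv(p, sep="\t", index=False)
        outputs.append(p)
    grid = cfg.get("sweep_grid")
    sweep = motu.threshold_sweep(
        dm, [float(g) for g in grid] if grid else None, method=method, aln=aln
    )
    p = outdir / "sweep.tsv"
    pd.DataFrame(
        {"threshold": sweep.thresholds, "motus": sweep.counts}
    ).to_csv(p, sep="\t", index=False)
    outputs.append(p)

    # ---- stage: representatives ------------------------------------------
    rep_label = f"{thresholds[0] * 100:g}%"
    reps = motu.select_representatives(partitions[rep_label], aln)
    p = outdir / "representatives.txt"
    p.write_text("".join(f"{r}\n" for r in reps))
    outputs.append(p)

    # ---- stage: partition QC ---------------------------------------------
    rep_subset = [r for r in reps]
    concat, scheme = concatenate_fragments(fragments, taxon_union=None)
    qc_taxa = [t for t in rep_subset if t in concat]
    qc_cfg = cfg.get("qc", {}) or {}
    report = qc.partition_qc(
        concat.subset(qc_taxa),
        scheme,
        rcfv_cutoff=float(qc_cfg.get("rcfv_cutoff", qc.RCFV_CUTOFF)),
        symmetry_alpha=float(qc_cfg.get("symmetry_alpha", qc.SYMMETRY_ALPHA)),
    )
    logger.info("qc: kept %s, dropped %s", report.kept, report.dropped)
    p = outdir / "qc_report.tsv"
    report.table.to_csv(p, sep="\t")
    outputs.append(p)

    # ---- stage: representative tree, constraint, compliance ---------------
    rep_dm = dm.subset([r for r in reps])
    nan_free = not np.isnan(rep_dm.d).any()
    rep_tree = None
    if len(rep_dm) >= 3 and nan_free:
        rep_tree = distances.neighbor_joining(rep_dm)
        p = outdir / "representative_tree.nwk"
        write_tree(rep_tree, p)
        outputs.append(p)
    if backbone_tree is not None and rep_tree is not None:
        n_anchors = int(cfg.get("n_anchors", 35))
        if truth is not None:
            # anchor one representative terminal per species where possible
            rep_species = {}
            for r in reps:
                sp = truth.terminal_species.get(r)
                if sp is not None and sp not in rep_species:
                    rep_species[sp] = r
            anchors = dict(sorted(rep_species.items())[:n_anchors])
            bb = backbone_tree.clone(depth=1)
            bb.retain_taxa_with_labels(list(anchors))
            for leaf in bb.leaf_node_iter():
                leaf.taxon.label = anchors[leaf.taxon.label]
            backbone = bb
        else:
            backbone = backbone_tree
        bc = treecmp.BackboneConstraint(backbone, full_taxa=list(rep_dm.ids))
        p = outdir / "constraint.nwk"
        treecmp.write_constraint(bc, p)
        outputs.append(p)
        result = treecmp.check_backbone_compliance(rep_tree, bc)
        p = outdir / "compliance.txt"
        p.write_text(
            f"compliant\t{result.compliant}\n"
            f"violated_splits\t{len(result.violated)}\n"
        )
        outputs.append(p)
        logger.info(
            "compliance: %s (%d violated splits)",
            result.compliant, len(result.violated),
        )

    # ---- stage: replicate-tree stability ----------------------------------
    stab_cfg = cfg.get("stability", {}) or {}
    n_rep = int(stab_cfg.get("n_replicates", 5))
    if rep_tree is not None and n_rep >= 2:
        rep_aln = aln.subset([r for r in reps])
        rng = np.random.default_rng(seed + 1)
        trees = []
        for _ in range(n_rep):
            bdm = distances.distance_matrix(
                _bootstrap_alignment(rep_aln, rng), min_overlap=1
            )
            trees.append(distances.neighbor_joining(bdm))
        mat, summary = treecmp.rf_matrix(trees)
        p = outdir / "rf_matrix.tsv"
        pd.DataFrame(mat).to_csv(p, sep="\t", index=False)
        outputs.append(p)
        p = outdir / "rf_summary.tsv"
        pd.Series(summary).to_csv(p, sep="\t", header=False)
        outputs.append(p)
        logger.info("rf stability over %d replicates: %s", n_rep, summary)

    # ---- stage: quartet support -------------------------------------------
    if rep_tree is not None and len(fragments) >= 2:
        gene_trees = []
        for name, frag in fragments:
            ids = [r for r in reps if r in frag]
            if len(ids) < 4:
                continue
            fdm = distances.distance_matrix(frag.subset(ids), min_overlap=1)
            gene_trees.append(distances.neighbor_joining(fdm))
        if gene_trees:
            table = quartets.branch_quartet_support(
                rep_tree, gene_trees, seed=seed + 2
            )
            p = outdir / "quartet_support.tsv"
            table.to_csv(p, sep="\t", index=False)
            outputs.append(p)

    # ---- stage: inventory tables ------------------------------------------
    region_table = inventory.aggregate_regions(partitions, metadata, described or {})
    endemism, global_prop = inventory.endemism_table(
        partitions[rep_label], metadata, level="landmass"
    )
    tables = {"region_table": region_table, "endemism": endemism}
    if barriers is not None:
        tt = inventory.turnover(partitions[rep_label], metadata, barriers)
        tables["turnover_motus"] = tt.per_motu
        tables["turnover_counts"] = pd.Series(tt.counts, name="motus").to_frame()
    outputs.extend(inventory.render_report(tables, outdir))
    logger.info("endemism (landmass level): global proportion %.3f", global_prop)

    # ---- manifest ----------------------------------------------------------
    extra = sorted(outdir.glob("data/*")) if (outdir / "data").exists() else []
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        for path in sorted(set(outputs) | set(extra)):
            fh.write(f"{path.relative_to(outdir)}\t{_sha256(path)}\n")
    return outdir
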