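import itertools

import numpy as np
import pytest

from motuinv.distances import distance_matrix, p_distance
from motuinv.errors import MotuinvError
from motuinv.io import read_alignment, read_metadata, read_tree, tree_to_newick
from motuinv.motu import cluster_greedy, cluster_single_linkage, count_motus
from motuinv.synthetic import (
    SimulationConfig,
    assign_geography,
    emit_dataset,
    generate_dataset,
    simulate_populations,
    simulate_sequences,
    simulate_species_tree,
)


def patristic(tree, a, b):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return pdm.patristic_distance(taxa[a], taxa[b])


class TestSpeciesTree:
    def test_two_species_cherry(self):
        tree = simulate_species_tree(2, depth=0.5, seed=1)
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        assert sorted(leaves) == ["sp0001", "sp0002"]

    def test_deterministic_under_seed(self):
        t1 = simulate_species_tree(10, depth=0.5, seed=7)
        t2 = simulate_species_tree(10, depth=0.5, seed=7)
        assert tree_to_newick(t1) == tree_to_newick(t2)

    def test_min_inter_tip_distance_respects_floor(self):
        floor = 0.08
        for seed in range(15):
            tree = simulate_species_tree(12, depth=0.3, seed=seed,
                                         inter_min=floor)
            labels = [l.taxon.label for l in tree.leaf_node_iter()]
            dmin = min(
                patristic(tree, a, b)
                for a, b in itertools.combinations(labels, 2)
            )
            assert dmin >= floor - 1e-9


class TestPopulations:
    def test_single_terminal_relabels_tip(self):
        st = simulate_species_tree(5, depth=0.5, seed=3)
        tt, truth = simulate_populations(st, 1, intra_max=0.005, seed=0)
        assert sorted(truth) == sorted(l.taxon.label for l in tt.leaf_node_iter())
        assert all(t.endswith("_t01") for t in truth)
        assert len(list(tt.leaf_node_iter())) == 5

    def test_intraspecific_distance_bounded(self):
        st = simulate_species_tree(4, depth=0.5, seed=3)
        tt, truth = simulate_populations(st, 4, intra_max=0.005, seed=1)
        by_sp = {}
        for term, sp in truth.items():
            by_sp.setdefault(sp, []).append(term)
        for terms in by_sp.values():
            for a, b in itertools.combinations(terms, 2):
                assert patristic(tt, a, b) <= 0.005 + 1e-12

    def test_zero_intra_max_gives_identical_sequences(self):
        st = simulate_species_tree(3, depth=0.5, seed=3)
        tt, truth = simulate_populations(st, 3, intra_max=0.0, seed=1)
        aln = simulate_sequences(tt, 300, seed=5)
        by_sp = {}
        for term, sp in truth.items():
            by_sp.setdefault(sp, []).append(term)
        for terms in by_sp.values():
            seqs = {aln[t].seq for t in terms}
            assert len(seqs) == 1


class TestSequences:
    def test_zero_length_branch_identical(self):
        tree = read_tree("(a:0.0,b:0.0);")
        aln = simulate_sequences(tree, 200, seed=2)
        assert aln["a"].seq == aln["b"].seq

    def test_saturation_approaches_three_quarters(self):
        tree = read_tree("(a:15.0,b:15.0);")
        aln = simulate_sequences(tree, 4000, seed=2)
        d = p_distance(aln["a"].seq, aln["b"].seq)
        assert d == pytest.approx(0.75, abs=0.03)

    def test_realized_distance_matches_jc_expectation(self):
        # P(d) = 3/4 (1 - e^(-4d/3)); check within 3 binomial SDs
        d_total = 0.1
        tree = read_tree(f"(a:{d_total / 2},b:{d_total / 2});")
        n = 1000
        expected = 0.75 * (1 - np.exp(-4 * d_total / 3))
        sd = np.sqrt(expected * (1 - expected) / n)
        aln = simulate_sequences(tree, n, seed=8)
        realized = p_distance(aln["a"].seq, aln["b"].seq)
        assert abs(realized - expected) <= 3 * sd

    def test_gamma_rates_lower_mean_observed_distance(self):
        # P(d) is concave in the site rate, so rate heterogeneity pulls the
        # expected p-distance below the equal-rates value (Jensen)
        tree = read_tree("(a:0.1,b:0.1);")
        flat = np.mean([
            p_distance(*(r.seq for r in simulate_sequences(tree, 500, seed=s)))
            for s in range(30)
        ])
        gamma = np.mean([
            p_distance(*(r.seq for r in simulate_sequences(
                tree, 500, seed=s, gamma_shape=0.2)))
            for s in range(30)
        ])
        assert gamma < flat


class TestGeography:
    def test_full_endemism_single_landmass(self):
        occ = assign_geography([f"s{i}" for i in range(40)],
                               ["A", "B", "C"], endemism_p=1.0,
                               dispersal_p=0.5, seed=1)
        assert all(len(v) == 1 for v in occ.values())

    def test_zero_dispersal_still_forces_second_landmass(self):
        # a non-endemic species must span >= 2 landmasses even at dispersal 0
        occ = assign_geography([f"s{i}" for i in range(40)],
                               ["A", "B"], endemism_p=0.0,
                               dispersal_p=0.0, seed=1)
        assert all(len(v) == 2 for v in occ.values())

    def test_multi_landmass_fraction_tracks_endemism(self):
        n = 400
        occ = assign_geography([f"s{i}" for i in range(n)],
                               ["A", "B", "C", "D"], endemism_p=0.8,
                               dispersal_p=0.5, seed=3)
        frac_multi = sum(1 for v in occ.values() if len(v) > 1) / n
        # binomial 3-sigma band around 1 - endemism_p
        sd = np.sqrt(0.2 * 0.8 / n)
        assert abs(frac_multi - 0.2) <= 3 * sd


class TestEmit:
    def test_no_missingness_all_fragments_present(self, tmp_path):
        cfg = SimulationConfig(
            seed=5, n_species=4, terminals_per_species=(2, 2),
            fragments={"cox1": 300, "rrnL": 200},
            missingness={"cox1": 0.0, "rrnL": 0.0},
        )
        paths = emit_dataset(cfg, tmp_path)
        meta = read_metadata(paths["metadata"])
        assert all(m.fragments_present == {"cox1", "rrnL"} for m in meta)
        assert len(read_alignment(paths["cox1"])) == 8

    def test_total_cox1_missingness_zeroes_motu_count(self):
        cfg = SimulationConfig(
            seed=5, n_species=4, terminals_per_species=(2, 2),
            fragments={"cox1": 300, "rrnL": 300},
            missingness={"cox1": 1.0, "rrnL": 0.0},
        )
        ds = generate_dataset(cfg)
        frag = dict(ds.fragments)
        assert "cox1" not in frag  # nobody carries it
        dm = distance_matrix(frag["rrnL"], min_overlap=50)
        part = cluster_single_linkage(dm, 0.05)
        assert count_motus(part, ds.metadata, require_fragment="cox1") == 0

    def test_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_species=5, terminals_per_species=(2, 3),
                               fragments={"cox1": 200},
                               missingness={"cox1": 0.1})
        p1 = emit_dataset(cfg, tmp_path / "r1")
        p2 = emit_dataset(cfg, tmp_path / "r2")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_overlapping_scales_rejected_without_override(self):
        with pytest.raises(MotuinvError, match="barcode gap"):
            SimulationConfig(seed=1, intra_max=0.1, inter_min=0.05)
        cfg = SimulationConfig(seed=1, intra_max=0.1, inter_min=0.05,
                               allow_gap_overlap=True)
        assert cfg.intra_max == 0.1

    def test_every_terminal_has_truth_row(self):
        cfg = SimulationConfig(seed=2, n_species=6, terminals_per_species=(1, 4),
                               fragments={"cox1": 200},
                               missingness={"cox1": 0.0})
        ds = generate_dataset(cfg)
        emitted = {m.terminal_id for m in ds.metadata}
        assert emitted == set(ds.truth.terminal_species)


class TestPipelineRecovery:
    def test_motu_counts_recover_species_number(self):
        """Clean barcode gap: both methods at 2% and 5% find the truth."""
        cfg = SimulationConfig(
            seed=17, n_species=20, fragments={"cox1": 1000},
            missingness={"cox1": 0.0},
        )
        ds = generate_dataset(cfg)
        aln = dict(ds.fragments)["cox1"]
        dm = distance_matrix(aln)
        for t in (0.02, 0.05):
            assert cluster_single_linkage(dm, t).n_clusters == 20
            assert cluster_greedy(aln, dm, t).n_clusters == 20

    def test_turnover_equals_truth_occupancy(self):
        cfg = SimulationConfig(
            seed=23, n_species=15, fragments={"cox1": 800},
            missingness={"cox1": 0.0}, endemism_p=0.6,
        )
        ds = generate_dataset(cfg)
        from motuinv.inventory import turnover

        aln = dict(ds.fragments)["cox1"]
        part = cluster_single_linkage(distance_matrix(aln), 0.05)
        observed = turnover(part, ds.metadata, ds.barriers)
        # recompute expected counts from the truth occupancy
        expected = {"deep_sea": 0, "shelf": 0, "contiguous": 0}
        for sp, occ in ds.truth.species_occupancy.items():
            if len(occ) < 2:
                continue
            classes = {
                ds.barriers.classify(a, b)
                for a, b in itertools.combinations(occ, 2)
            }
            for cls in classes:
                expected[cls] += 1
        assert observed.counts == expected
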