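import pandas as pd
import pytest

from motuinv.errors import MotuinvError
from motuinv.inventory import (
    OCCURRENCE_ROW,
    TOTAL_ROW,
    aggregate_regions,
    described_ratio,
    endemism_table,
    render_report,
    turnover,
)
from motuinv.io import BarrierMap, VoucherMetadata
from motuinv.motu import MotuPartition


def meta(term, region, landmass, subtribe="Metriorrhynchina", fragments=("cox1",)):
    return VoucherMetadata(term, subtribe, landmass, region, landmass,
                           frozenset(fragments))


def partition(assignment):
    return MotuPartition(0.05, "single_linkage", dict(assignment))


class TestDescribedRatio:
    @pytest.mark.parametrize(
        "analyzed,described,expected",
        [
            (1434, 423, 3.39),
            (33, 104, 0.32),
            (1848, 1574, 1.17),
            (1105, 423, 2.61),
            (0, 10, 0.0),
        ],
    )
    def test_half_up_rounding(self, analyzed, described, expected):
        assert described_ratio(analyzed, described) == expected

    def test_exact_half_rounds_up(self):
        assert described_ratio(125, 1000) == 0.13  # 0.125 -> 0.13, not 0.12

    def test_zero_described_undefined(self):
        assert described_ratio(5, 0) is None

    def test_negative_rejected(self):
        with pytest.raises(MotuinvError):
            described_ratio(-1, 5)


class TestAggregateRegions:
    def setup_method(self):
        # m0 spans two regions; m1, m2 single-region
        self.part = partition({"t1": 0, "t2": 0, "t3": 1, "t4": 2})
        self.meta = [
            meta("t1", "New Guinea", "New Guinea"),
            meta("t2", "Australia", "Australia"),
            meta("t3", "New Guinea", "New Guinea"),
            meta("t4", "Wallacea", "Sulawesi"),
        ]
        self.described = {"New Guinea": 4, "Australia": 1, "Wallacea": 2}

    def test_motu_counted_in_every_region_of_occurrence(self):
        table = aggregate_regions({"5%": self.part}, self.meta, self.described)
        assert table.loc["New Guinea", "motus_5%"] == 2  # m0 and m1
        assert table.loc["Australia", "motus_5%"] == 1  # m0 again

    def test_total_counts_each_motu_once(self):
        table = aggregate_regions({"5%": self.part}, self.meta, self.described)
        assert table.loc[TOTAL_ROW, "motus_5%"] == 3
        assert table.loc[OCCURRENCE_ROW, "motus_5%"] == 4

    def test_ratios_recomputable_from_integer_columns(self):
        table = aggregate_regions({"5%": self.part}, self.meta, self.described)
        for region, row in table.iterrows():
            if row["described"] > 0:
                assert row["ratio_5%"] == described_ratio(
                    int(row["motus_5%"]), int(row["described"])
                )

    def test_terminal_without_region_excluded(self):
        part = partition({"t1": 0, "tx": 1})
        rows = [meta("t1", "Australia", "Australia"),
                meta("tx", "", "")]
        table = aggregate_regions({"5%": part}, rows, {"Australia": 1})
        assert table.loc[TOTAL_ROW, "motus_5%"] == 1


class TestEndemism:
    def test_all_single_region_fully_endemic(self):
        part = partition({"t1": 0, "t2": 1, "t3": 2})
        rows = [meta("t1", "Australia", "Australia"),
                meta("t2", "New Guinea", "New Guinea"),
                meta("t3", "New Guinea", "New Guinea")]
        table, global_prop = endemism_table(part, rows, level="region")
        assert global_prop == 1.0
        assert (table["endemic_prop"] == 1.0).all()

    def test_one_widespread_motu_among_three(self):
        part = partition({"t1": 0, "t2": 0, "t3": 1, "t4": 2})
        rows = [meta("t1", "Australia", "Australia"),
                meta("t2", "New Guinea", "New Guinea"),
                meta("t3", "Australia", "Australia"),
                meta("t4", "Australia", "Australia")]
        _, global_prop = endemism_table(part, rows, level="region")
        assert global_prop == pytest.approx(2 / 3)

    def test_matches_brute_force_scan(self, rng):
        terms = [f"t{i}" for i in range(30)]
        units = ["A", "B", "C"]
        assignment = {t: int(rng.integers(0, 10)) for t in terms}
        rows = [
            meta(t, "r", units[int(rng.integers(0, 3))]) for t in terms
        ]
        part = partition(assignment)
        _, global_prop = endemism_table(part, rows, level="landmass")
        occ = {}
        by_term = {m.terminal_id: m.landmass for m in rows}
        for t, cid in assignment.items():
            occ.setdefault(cid, set()).add(by_term[t])
        expected = sum(1 for s in occ.values() if len(s) == 1) / len(occ)
        assert global_prop == pytest.approx(expected)


class TestTurnover:
    def _barriers(self):
        return BarrierMap({
            ("New Guinea", "Australia"): "shelf",
            ("Sulawesi", "Moluccas"): "deep_sea",
            ("New Guinea", "Sulawesi"): "deep_sea",
            ("New Guinea", "Moluccas"): "deep_sea",
            ("Australia", "Sulawesi"): "deep_sea",
            ("Australia", "Moluccas"): "deep_sea",
        })

    def test_toy_classification(self):
        part = partition({"a1": 0, "a2": 0, "b1": 1, "b2": 1, "c1": 2})
        rows = [
            meta("a1", "New Guinea", "New Guinea"),
            meta("a2", "Australia", "Australia"),
            meta("b1", "Wallacea", "Sulawesi"),
            meta("b2", "Wallacea", "Moluccas"),
            meta("c1", "New Guinea", "New Guinea"),
        ]
        table = turnover(part, rows, self._barriers())
        assert table.counts["shelf"] == 1
        assert table.counts["deep_sea"] == 1
        assert table.counts["contiguous"] == 0
        assert table.n_multi_landmass == 2

    def test_no_multi_landmass_motus_all_zero(self):
        part = partition({"a1": 0, "b1": 1})
        rows = [meta("a1", "New Guinea", "New Guinea"),
                meta("b1", "Australia", "Australia")]
        table = turnover(part, rows, self._barriers())
        assert all(v == 0 for v in table.counts.values())

    def test_invariant_to_duplicate_occurrences(self):
        part1 = partition({"a1": 0, "a2": 0})
        part2 = partition({"a1": 0, "a2": 0, "a3": 0, "a4": 0})
        rows = [
            meta("a1", "New Guinea", "New Guinea"),
            meta("a2", "Australia", "Australia"),
            meta("a3", "New Guinea", "New Guinea"),
            meta("a4", "Australia", "Australia"),
        ]
        t1 = turnover(part1, rows[:2], self._barriers())
        t2 = turnover(part2, rows, self._barriers())
        assert t1.counts == t2.counts

    def test_unclassified_pair_is_an_error(self):
        part = partition({"a1": 0, "a2": 0})
        rows = [meta("a1", "r", "X"), meta("a2", "r", "Y")]
        with pytest.raises(MotuinvError, match="not classified"):
            turnover(part, rows, BarrierMap())


class TestRenderReport:
    def test_round_trip_preserves_integers(self, tmp_path):
        part = partition({"t1": 0, "t2": 1})
        rows = [meta("t1", "Australia", "Australia"),
                meta("t2", "Australia", "Australia")]
        table = aggregate_regions({"5%": part}, rows, {"Australia": 7})
        paths = render_report({"region_table": table}, tmp_path)
        back = pd.read_csv(paths[0], sep="\t", index_col=0)
        assert back.loc["Australia", "motus_5%"] == 2
        assert back.loc["Australia", "described"] == 7
        assert back.loc["Australia", "ratio_5%"] == 0.29

    def test_undefined_ratio_renders_dash(self, tmp_path):
        part = partition({"t1": 0})
        rows = [meta("t1", "Australia", "Australia")]
        table = aggregate_regions({"5%": part}, rows, {"Australia": 0})
        paths = render_report({"t": table}, tmp_path)
        text = paths[0].read_text()
        assert "—" in text

    def test_empty_table_header_only(self, tmp_path):
        empty = pd.DataFrame(columns=["motus", "endemics"])
        paths = render_report({"empty": empty}, tmp_path)
        lines = paths[0].read_text().strip().splitlines()
        assert len(lines) == 1

    def test_totals_equal_recomputed_sums(self, tmp_path):
        part = partition({"t1": 0, "t2": 1, "t3": 2})
        rows = [meta("t1", "Australia", "Australia"),
                meta("t2", "Australia", "Australia"),
                meta("t3", "Wallacea", "Sulawesi")]
        table = aggregate_regions(
            {"5%": part}, rows, {"Australia": 2, "Wallacea": 1}
        )
        body = table.drop(index=[TOTAL_ROW, OCCURRENCE_ROW])
        assert body["motus_5%"].sum() == table.loc[OCCURRENCE_ROW, "motus_5%"]
        assert body["described"].sum() == table.loc[TOTAL_ROW, "described"]
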