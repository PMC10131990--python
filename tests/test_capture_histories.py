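"""Capture-history table construction, validation, pooling and summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crc3s.capture_histories import (
    CaptureHistoryTable,
    CaptureMarginals,
    InconsistentMarginalsError,
    capture_summary,
    marginals_from_table,
    pool_strata,
    read_marginals_csv,
    read_table_csv,
    table_from_marginals,
    write_marginals_csv,
    write_table_csv,
)


class TestTableFromMarginals:
    def test_national_inclusion_exclusion(self, national_table):
        assert national_table.cells == {
            "100": 1532,
            "010": 388,
            "001": 1584,
            "110": 511,
            "101": 212,
            "011": 205,
            "111": 210,
        }
        assert national_table.n_observed == 2465 + 1314 + 2211 - 721 - 422 - 415 + 210 == 4642

    def test_complete_overlap(self):
        m = CaptureMarginals(n=(5, 5, 5), pair_overlaps=(5, 5, 5), triple_overlap=5)
        t = table_from_marginals(m)
        assert t.cells["111"] == 5
        assert all(c == 0 for p, c in t.cells.items() if p != "111")

    def test_strict_mode_flags_inconsistent_western_row(self, western_marginals):
        with pytest.raises(InconsistentMarginalsError) as exc:
            table_from_marginals(western_marginals, policy="strict")
        assert exc.value.pattern == "010"
        assert exc.value.value == -17

    def test_clamp_mode_zeroes_cell_and_warns(self, western_marginals):
        t = table_from_marginals(western_marginals, policy="clamp")
        assert t.cells["010"] == 0
        assert len(t.warnings) == 1 and "010" in t.warnings[0]

    def test_invalid_marginals_rejected(self):
        with pytest.raises(ValueError):
            CaptureMarginals(n=(5, 5, 5), pair_overlaps=(6, 0, 0), triple_overlap=0)
        with pytest.raises(ValueError):
            CaptureMarginals(n=(5, 5, 5), pair_overlaps=(2, 2, 2), triple_overlap=3)


class TestMarginalsFromTable:
    def test_round_trip_national(self, national_table, national_marginals):
        m = marginals_from_table(national_table)
        assert m.n == national_marginals.n
        assert m.pair_overlaps == national_marginals.pair_overlaps
        assert m.triple_overlap == national_marginals.triple_overlap

    def test_eastern_cells_summarise(self):
        cells = {"111": 36, "110": 175, "101": 14, "011": 28, "100": 333, "010": 98, "001": 48}
        m = marginals_from_table(CaptureHistoryTable(3, cells))
        assert m.n == (558, 337, 126)
        assert m.pair_overlaps == (211, 50, 64)
        assert m.triple_overlap == 36

    def test_empty_table(self):
        t = CaptureHistoryTable(3, {p: 0 for p in ("100", "010", "001", "110", "101", "011", "111")})
        m = marginals_from_table(t)
        assert m.n == (0, 0, 0) and m.pair_overlaps == (0, 0, 0) and m.triple_overlap == 0


@st.composite
def consistent_marginals(draw):
    """Random marginals generated from a latent cell table, hence consistent."""
    cells = {
        p: draw(st.integers(min_value=0, max_value=500))
        for p in ("100", "010", "001", "110", "101", "011", "111")
    }
    return marginals_from_table(CaptureHistoryTable(3, cells))


@given(consistent_marginals())
@settings(max_examples=200, deadline=None)
def test_marginals_table_round_trip(m):
    t = table_from_marginals(m, policy="strict")
    back = marginals_from_table(t)
    assert back.n == m.n
    assert back.pair_overlaps == m.pair_overlaps
    assert back.triple_overlap == m.triple_overlap
    # total observed equals both the cell sum and the inclusion-exclusion total
    total = sum(m.n) - sum(m.pair_overlaps) + m.triple_overlap
    assert t.n_observed == total


class TestPooling:
    def test_pooling_commutes_with_construction(self):
        ms = [
            CaptureMarginals(n=(50, 40, 30), pair_overlaps=(20, 10, 8), triple_overlap=5, stratum="a"),
            CaptureMarginals(n=(80, 60, 70), pair_overlaps=(30, 25, 20), triple_overlap=12, stratum="b"),
        ]
        pooled_tables = pool_strata([table_from_marginals(m, "strict") for m in ms])
        pooled_marginals = table_from_marginals(ms[0] + ms[1], "strict")
        assert pooled_tables.cells == pooled_marginals.cells

    def test_single_table_identity(self, national_table):
        assert pool_strata([national_table]).cells == national_table.cells

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pool_strata([])

    def test_mismatched_k_rejected(self, national_table):
        t2 = CaptureHistoryTable(2, {"10": 1, "01": 1, "11": 1})
        with pytest.raises(ValueError):
            pool_strata([national_table, t2])


class TestCaptureSummary:
    def test_printed_percentages(self, national_marginals):
        s = capture_summary(national_marginals, objects_assigned=2723)
        assert s["capture_one_distribution"]["percent"] == 90.53
        assert s["capture_two_tagged"]["percent"] == 54.87
        assert s["capture_three_object"]["percent"] == 19.09
        assert s["capture_three_service"]["percent"] == 18.77

    def test_zero_overlaps_give_zero_percent(self):
        m = CaptureMarginals(n=(10, 10, 10), pair_overlaps=(0, 0, 0), triple_overlap=0)
        s = capture_summary(m)
        assert s["capture_two_tagged"]["percent"] == 0.0

    def test_zero_denominator_flagged_not_raised(self):
        m = CaptureMarginals(n=(10, 0, 10), pair_overlaps=(0, 5, 0), triple_overlap=0)
        s = capture_summary(m)
        assert s["capture_two_tagged"]["undefined"] is True
        assert s["capture_two_tagged"]["percent"] is None


class TestCsvRoundTrips:
    def test_marginals_csv(self, tmp_path, national_marginals):
        path = tmp_path / "m.csv"
        write_marginals_csv([national_marginals], path)
        back = read_marginals_csv(path)
        assert len(back) == 1 and back[0] == national_marginals

    def test_table_csv(self, tmp_path, national_table):
        path = tmp_path / "t.csv"
        write_table_csv([national_table], path)
        back = read_table_csv(path)
        assert back[0].cells == national_table.cells

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("stratum,n1,n2\nx,1,2\n")
        with pytest.raises(ValueError, match="missing"):
            read_marginals_csv(path)
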