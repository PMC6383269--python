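"""Ingestion, bout segmentation, the motivated filter, binning, matrices."""

import numpy as np
import pandas as pd
import pytest

from beepartite import (
    bin_by_bouts,
    build_visitation_matrix,
    filter_motivated,
    make_visit_log,
    read_visit_log,
    segment_bouts,
    write_visit_log,
)
from beepartite.visitlog import SchemaError, ValidationError

from conftest import bout_df


class TestIngestion:
    def test_reads_and_sorts(self, tiny_log_csv):
        log = read_visit_log(tiny_log_csv)
        assert len(log) == 3
        assert log.visits["t_arrival_s"].is_monotonic_increasing
        assert log.visits.loc[1, "bee_id"] == "b2"  # interleaved by time

    def test_schema_map(self, tmp_path, tiny_log_df):
        df = tiny_log_df.rename(columns={"bee_id": "Bee", "t_arrival_s": "arr"})
        path = tmp_path / "v.csv"
        df.to_csv(path, index=False)
        log = read_visit_log(path, schema_map={"bee_id": "Bee", "t_arrival_s": "arr"})
        assert len(log) == 3

    def test_missing_column_is_schema_error(self, tmp_path, tiny_log_df):
        path = tmp_path / "v.csv"
        tiny_log_df.drop(columns=["flower_id"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="flower_id"):
            read_visit_log(path)

    def test_reversed_times_named_row(self, tmp_path, tiny_log_df):
        tiny_log_df.loc[1, "t_departure_s"] = 1.0
        path = tmp_path / "v.csv"
        tiny_log_df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="1"):
            read_visit_log(path)

    def test_unknown_flower_rejected(self, tiny_log_df):
        with pytest.raises(ValidationError, match="F2"):
            make_visit_log(tiny_log_df, flowers=["F1"])

    def test_roundtrip_is_identity(self, tmp_path, planted):
        log, _ = planted
        path = tmp_path / "out.csv"
        write_visit_log(log, path)
        again = read_visit_log(path, flowers=log.flowers)
        pd.testing.assert_frame_equal(
            log.visits.astype({"bout_id": float}), again.visits.astype({"bout_id": float})
        )


class TestBouts:
    def test_explicit_bout_ids_win(self, make_log):
        df = pd.concat([bout_df("b1", 1, 0, 3), bout_df("b1", 1, 1000, 2)], ignore_index=True)
        df["bout_id"] = [7, 7, 7, 9, 9]
        log = make_log(df)
        bouts = segment_bouts(log, gap_threshold=1e9)  # threshold would merge; ids must win
        assert [b.n_visits for b in bouts] == [3, 2]
        assert [b.index for b in bouts] == [1, 2]

    def test_gap_threshold_splits(self, make_log):
        df = pd.concat([bout_df("b1", 1, 0, 3), bout_df("b1", 1, 900, 3)], ignore_index=True)
        bouts = segment_bouts(make_log(df), gap_threshold=300.0)
        assert len(bouts) == 2
        assert all(b.bee_id == "b1" for b in bouts)

    def test_nest_events_define_bouts(self, make_log):
        df = pd.concat([bout_df("b1", 1, 10, 2), bout_df("b1", 1, 200, 2)], ignore_index=True)
        events = pd.DataFrame(
            {
                "bee_id": ["b1"] * 4,
                "day": [1] * 4,
                "t_s": [0.0, 100.0, 150.0, 300.0],
                "direction": ["exit", "entry", "exit", "entry"],
            }
        )
        bouts = segment_bouts(make_log(df), nest_events=events)
        assert len(bouts) == 2
        assert bouts[0].t_start == 0.0 and bouts[0].t_end == 100.0

    def test_visit_outside_intervals_warns_and_assigns(self, make_log):
        df = bout_df("b1", 1, 500, 1)
        events = pd.DataFrame(
            {"bee_id": ["b1"] * 2, "day": [1, 1], "t_s": [0.0, 100.0], "direction": ["exit", "entry"]}
        )
        with pytest.warns(UserWarning, match="outside nest intervals"):
            bouts = segment_bouts(make_log(df), nest_events=events)
        assert len(bouts) == 1

    def test_empty_log_empty_list(self, make_log, tiny_log_df):
        log = filter_motivated(make_log(tiny_log_df), min_visits=100)
        assert segment_bouts(log) == []

    def test_every_visit_in_exactly_one_bout(self, planted):
        log, _ = planted
        bouts = segment_bouts(log)
        assert sum(b.n_visits for b in bouts) == len(log)
        for b in bouts:
            assert (b.visits["t_arrival_s"] >= b.t_start).all()
            assert (b.visits["t_departure_s"] <= b.t_end).all()


class TestMotivatedFilter:
    def test_strict_boundary(self, make_log):
        df = pd.concat(
            [bout_df("b20", 1, 0, 20), bout_df("b21", 1, 0, 21)], ignore_index=True
        )
        kept = filter_motivated(make_log(df))
        assert kept.bees == ("b21",)

    def test_all_below_threshold_warns(self, make_log, tiny_log_df):
        with pytest.warns(UserWarning, match="no bee"):
            out = filter_motivated(make_log(tiny_log_df))
        assert len(out) == 0


class TestBinning:
    def test_single_bee_sixteen_bouts(self, make_log):
        df = pd.concat(
            [bout_df("b1", 1, i * 1000, 2) for i in range(16)], ignore_index=True
        )
        bins = bin_by_bouts(segment_bouts(make_log(df), gap_threshold=300.0))
        assert len(bins) == 2
        assert all(b.bouts_per_bee() == {"b1": 8} for b in bins)

    def test_slower_bee_contributes_partial(self, make_log):
        frames = [bout_df("A", 1, i * 600, 2) for i in range(8)]
        frames += [bout_df("B", 1, i * 1000 + 50, 2) for i in range(5)]
        bins = bin_by_bouts(segment_bouts(make_log(pd.concat(frames, ignore_index=True))))
        first = bins[0]
        per = first.bouts_per_bee()
        assert per["A"] == 8
        # B's bouts completed before A's 8th completion fall in bin 1
        assert 0 < per.get("B", 0) < 8
        # bin closes at A's 8th bout completion unless the tail was merged
        assert first.merged_tail or first.t_end == 7 * 600 + 20 + 5

    def test_whole_day_fallback(self, make_log):
        df = pd.concat([bout_df("b1", 1, i * 1000, 2) for i in range(3)], ignore_index=True)
        with pytest.warns(UserWarning, match="whole-day"):
            bins = bin_by_bouts(segment_bouts(make_log(df)))
        assert len(bins) == 1 and bins[0].whole_day

    def test_bins_do_not_span_days(self, planted):
        log, _ = planted
        bins = bin_by_bouts(segment_bouts(log))
        for b in bins:
            assert len({bt.day for bt in b.bouts}) == 1
        assert [b.index for b in bins] == list(range(1, len(bins) + 1))

    def test_quota_is_exact_in_unflagged_bins(self, planted):
        log, _ = planted
        for b in bin_by_bouts(segment_bouts(log), merge_trailing=False):
            if not (b.whole_day or b.merged_tail):
                assert max(b.bouts_per_bee().values()) == 8


class TestMatrices:
    def test_direct_counts(self, make_log):
        df = pd.concat(
            [bout_df("b1", 1, 0, 2, flower="F1"), bout_df("b1", 1, 50, 1, flower="F2")],
            ignore_index=True,
        )
        log = make_log(df, flowers=["F1", "F2", "F3"])
        bins = bin_by_bouts(segment_bouts(log, gap_threshold=1000.0))
        m = build_visitation_matrix(bins[0], log.flowers)
        assert m.counts[:, 0].tolist() == [2, 1, 0]
        assert m.row_labels == ("F1", "F2", "F3")

    def test_zero_activity_bee_dropped(self, make_log):
        df = pd.concat([bout_df("b1", 1, 0, 3), bout_df("b2", 2, 0, 3)], ignore_index=True)
        log = make_log(df)
        bins = bin_by_bouts(segment_bouts(log))
        m = build_visitation_matrix(bins[0], log.flowers)
        assert "b2" not in m.col_labels
        assert (m.col_margins > 0).all()

    def test_conservation_over_bins(self, planted):
        """Sum of all matrix entries across bins equals the retained visit count."""
        log, _ = planted
        bins = bin_by_bouts(segment_bouts(log))
        total = sum(build_visitation_matrix(b, log.flowers).total for b in bins)
        assert total == len(log)

    def test_margins_consistent(self, planted):
        log, _ = planted
        bins = bin_by_bouts(segment_bouts(log))
        m = build_visitation_matrix(bins[0], log.flowers)
        assert m.row_margins.sum() == m.col_margins.sum() == m.total

    def test_tsv_roundtrip(self, tmp_path, planted):
        log, _ = planted
        bins = bin_by_bouts(segment_bouts(log))
        m = build_visitation_matrix(bins[0], log.flowers)
        m.to_tsv(tmp_path / "m.tsv")
        again = type(m).from_tsv(tmp_path / "m.tsv")
        assert np.array_equal(m.counts, again.counts)
        assert m.row_labels == again.row_labels and m.col_labels == again.col_labels
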