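"""Encounter classification, the model table, and the two mixed models."""

import numpy as np
import pandas as pd
import pytest

from beepartite.interactions import (
    ClassifiedInteraction,
    InteractionEvent,
    build_interaction_table,
    build_revisit_table,
    classify_interaction,
    fit_replacement_model,
    read_interaction_log,
    write_interaction_log,
)


def make_event(first_leaver="joiner", feed=10.0, contact=True, overlap=4.0):
    return InteractionEvent(
        flower_id="F1",
        resident_id="r",
        joiner_id="j",
        day=1,
        t_resident_arrival=100.0 - feed,
        t_joiner_arrival=100.0,
        t_first_departure=100.0 + overlap,
        first_leaver_id="r" if first_leaver == "resident" else "j",
        contact=contact,
    )


class TestClassification:
    def test_joiner_leaves_first_is_resident_stays(self):
        ci = classify_interaction(make_event("joiner"))
        assert ci.outcome == "resident_stays"
        assert ci.replaced == 0

    def test_resident_leaves_on_consumed_flower(self):
        ci = classify_interaction(make_event("resident", feed=10.0))
        assert ci.outcome == "resident_leaves"
        assert ci.reward_status == "consumed"
        assert ci.replaced == 1

    def test_exact_boundary_is_not_consumed_and_flagged(self):
        ci = classify_interaction(make_event(feed=8.0))
        assert ci.reward_status == "not_consumed"
        assert ci.boundary_flag

    def test_four_classes_partition_events(self):
        events = [
            make_event(l, f)
            for l in ("joiner", "resident")
            for f in (3.0, 12.0)
            for _ in range(5)
        ]
        classes = {(c.outcome, c.reward_status) for c in map(classify_interaction, events)}
        assert classes == {
            ("resident_stays", "not_consumed"),
            ("resident_stays", "consumed"),
            ("resident_leaves", "not_consumed"),
            ("resident_leaves", "consumed"),
        }
        assert len([classify_interaction(e) for e in events]) == len(events)

    def test_invalid_time_order_rejected(self):
        with pytest.raises(ValueError):
            InteractionEvent("F1", "r", "j", 1, 100.0, 90.0, 104.0, "r")

    def test_unknown_leaver_rejected(self):
        with pytest.raises(ValueError):
            InteractionEvent("F1", "r", "j", 1, 90.0, 100.0, 104.0, "zz")


class TestInteractionTable:
    def test_standardized_columns(self):
        rng = np.random.default_rng(0)
        classified = [
            classify_interaction(make_event("joiner" if rng.random() < 0.5 else "resident",
                                            feed=float(rng.uniform(1, 20)),
                                            overlap=float(rng.uniform(1, 9))))
            for _ in range(30)
        ]
        table = build_interaction_table(classified)
        assert table["feed_time_z"].mean() == pytest.approx(0.0, abs=1e-10)
        assert table["feed_time_z"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)
        assert table["overlap_z"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_contact_only_filter(self):
        classified = [
            classify_interaction(make_event(contact=(i % 2 == 0))) for i in range(10)
        ]
        assert len(build_interaction_table(classified, contact_only=True)) == 5
        assert len(build_interaction_table(classified, contact_only=False)) == 10

    def test_signed_difference_arithmetic(self):
        metrics = pd.DataFrame(
            {
                "bee_id": ["r", "j"],
                "bin_index": [1, 1],
                "activity": [10, 4],
                "experience": [20, 2],
                "specificity": [0.5, 0.9],
            }
        )
        from beepartite.visitlog import TimeBin

        bins = [TimeBin(1, 1, 0.0, 1000.0)]
        table = build_interaction_table(
            [classify_interaction(make_event())], metrics=metrics, bins=bins,
            body_size=pd.Series({"r": 5.0, "j": 4.0}),
        )
        row = table.iloc[0]
        assert row["d_activity"] == -6  # joiner minus resident
        assert row["d_experience"] == -18
        assert row["d_specificity"] == pytest.approx(0.4)
        assert row["d_size"] == pytest.approx(-1.0)
        assert row["abs_activity"] == 6

    def test_log_roundtrip(self, tmp_path):
        events = [make_event("joiner"), make_event("resident")]
        path = tmp_path / "ix.csv"
        write_interaction_log(events, path)
        again = read_interaction_log(path)
        assert len(again) == 2
        assert again[0].resident_id == "r"
        assert again[1].first_leaver_id == "r"


class TestReplacementModel:
    def test_single_outcome_class_is_separation_error(self):
        table = pd.DataFrame(
            {
                "replaced": [1] * 10,
                "consumed": [0, 1] * 5,
                "feed_time_z": np.linspace(-1, 1, 10),
                "overlap_z": np.linspace(1, -1, 10),
                "resident_id": ["a"] * 10,
                "joiner_id": ["b"] * 10,
            }
        )
        with pytest.raises(ValueError, match="separation"):
            fit_replacement_model(table)

    def test_recovers_planted_reward_effect(self):
        from beepartite.validation import _interaction_table

        rng = np.random.default_rng(1)
        table = _interaction_table(rng, 400, 10, beta_consumed=-1.8)
        fit = fit_replacement_model(table, include_differences=False)
        assert fit.coef("consumed") < 0
        assert fit.stat("consumed") < -2
        assert fit.stat_name == "z"


class TestRevisitTable:
    def test_alignment_with_next_bout(self, sim):
        from beepartite import segment_bouts

        log, events, _ = sim
        bouts = segment_bouts(log)
        classified = [classify_interaction(e) for e in events]
        table = build_revisit_table(classified, bouts)
        assert len(table) > 0
        assert (table["visits_next_bout"] >= 0).all()
        assert set(table["won"]) <= {0, 1}
        # every row's bee actually took part in some encounter
        participants = {e.resident_id for e in events} | {e.joiner_id for e in events}
        assert set(table["bee_id"]) <= participants
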