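"""The planted-module sampler and the flight-cage simulator."""

import numpy as np
import pandas as pd
import pytest

from beepartite import (
    SimConfig,
    bin_by_bouts,
    build_visitation_matrix,
    dirt_lpa_wb_plus,
    plant_modular_log,
    segment_bouts,
    simulate_colony,
)
from beepartite.synthetic_data import cup_volume_after, decagon_coordinates


class TestGeometry:
    def test_decagon_spacing(self):
        xy = decagon_coordinates(9.0)
        d = np.linalg.norm(xy - np.roll(xy, 1, axis=0), axis=1)
        assert np.allclose(d, 9.0)
        # the 9.6-m visual detection range reaches nearest neighbours only
        d2 = np.linalg.norm(xy - np.roll(xy, 2, axis=0), axis=1)
        assert (d < 9.6).all() and (d2 > 9.6).all()


class TestCupDynamics:
    def test_refill_closed_form(self):
        # 40 uL at 3.3 uL/min from empty in ~12.12 min
        t_full = 40.0 / (3.3 / 60.0)
        assert cup_volume_after(t_full) == pytest.approx(40.0)
        assert cup_volume_after(t_full * 0.5) == pytest.approx(20.0)
        assert cup_volume_after(t_full * 2) == 40.0  # capped

    def test_full_cup_drained_in_about_eight_seconds(self):
        # a lone bee at 5 uL/s empties a full 40-uL cup in 8 s
        assert 40.0 / 5.0 == pytest.approx(8.0)


class TestPlantedSampler:
    def test_deterministic(self):
        a, _ = plant_modular_log(seed=5)
        b, _ = plant_modular_log(seed=5)
        pd.testing.assert_frame_equal(a.visits, b.visits)

    def test_full_fidelity_block_diagonal(self):
        log, truth = plant_modular_log(fidelity=1.0, n_bouts_per_day=10, n_days=2, seed=6)
        pooled = pd.crosstab(log.visits["flower_id"], log.visits["bee_id"])
        for bee, own in truth["modules"].items():
            outside = pooled.loc[~pooled.index.isin(own), bee].sum()
            assert outside == 0
        # the pooled network splits exactly into the planted modules
        A = pooled.reindex(index=list(log.flowers)).fillna(0).to_numpy()
        part = dirt_lpa_wb_plus(A, reps=5, rng_seed=0)
        labels = {}
        for j, bee in enumerate(pooled.columns):
            key = tuple(sorted(truth["modules"][bee]))
            labels.setdefault(key, set()).add(part.col_modules[j])
        sets = list(labels.values())
        assert all(len(s) == 1 for s in sets)
        assert sets[0] != sets[1]

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="empty module"):
            plant_modular_log(modules={0: []}, n_bees=1)

    def test_schema_passes_pipeline_stages(self):
        log, _ = plant_modular_log(seed=7, n_days=2)
        bins = bin_by_bouts(segment_bouts(log))
        assert len(bins) >= 2
        m = build_visitation_matrix(bins[0], log.flowers)
        assert m.total > 0


class TestSimulator:
    def test_deterministic(self):
        a = simulate_colony(SimConfig(seed=3, n_days=1))
        b = simulate_colony(SimConfig(seed=3, n_days=1))
        pd.testing.assert_frame_equal(a[0].visits, b[0].visits)
        assert len(a[1]) == len(b[1])

    def test_nectar_conservation(self, sim):
        _, _, truth = sim
        assert truth["max_conservation_residual_uL"] < 1e-6

    def test_visit_log_valid_and_times_in_session(self, sim):
        log, _, _ = sim
        v = log.visits
        assert (v["t_departure_s"] >= v["t_arrival_s"]).all()
        assert (v["t_departure_s"] <= SimConfig().session_length + 1e-9).all()
        assert set(v["flower_id"]) <= set(log.flowers)

    def test_bout_statistics_in_realistic_regime(self, sim):
        log, _, _ = sim
        b = log.visits.groupby(["day", "bee_id", "bout_id"])
        uniq = b["flower_id"].nunique().mean()
        assert 2.5 < uniq < 5.5  # a few unique flowers per crop-limited bout

    def test_interactions_reference_logged_bees(self, sim):
        log, events, _ = sim
        bees = set(log.visits["bee_id"])
        for e in events:
            assert e.resident_id in bees and e.joiner_id in bees
            assert e.t_resident_arrival < e.t_joiner_arrival <= e.t_first_departure

    def test_displacement_history_matches_events(self, sim):
        _, events, truth = sim
        # one displacement record per encounter (one bee leaves empty-handed
        # or is evicted)
        assert len(truth["displacements"]) == len(events)

    def test_nonphysical_config_rejected(self):
        with pytest.raises(ValueError, match="non-physical|positive"):
            SimConfig(refill_rate=-1.0)
        with pytest.raises(ValueError):
            SimConfig(fidelity=1.5)
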