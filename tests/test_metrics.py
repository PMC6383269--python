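"""Activity, experience, specificity, VIF, and the two regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beepartite import (
    activity,
    bin_by_bouts,
    build_visitation_matrix,
    compute_metrics,
    experience,
    fit_modularity_lm,
    fit_specificity_lmm,
    flower_specificity,
    segment_bouts,
    variance_inflation,
)
from beepartite.visitlog import VisitationMatrix


class TestActivity:
    def test_column_sum(self):
        m = VisitationMatrix(np.array([[2, 0], [1, 4]]), ("F1", "F2"), ("b1", "b2"))
        assert activity(m, "b1") == 3

    def test_unknown_bee(self):
        m = VisitationMatrix(np.array([[2]]), ("F1",), ("b1",))
        with pytest.raises(KeyError):
            activity(m, "zz")

    def test_matches_record_count(self, planted):
        log, _ = planted
        bins = bin_by_bouts(segment_bouts(log))
        m = build_visitation_matrix(bins[0], log.flowers)
        vis = pd.concat([b.visits for b in bins[0].bouts])
        bee = m.col_labels[0]
        assert activity(m, bee) == (vis["bee_id"] == bee).sum()


class TestExperience:
    def test_first_bin_zero(self):
        tab = pd.DataFrame({"bee_id": ["b1"], "bin_index": [1], "activity": [5]})
        assert experience(tab, "b1", 1) == 0

    def test_cumulative(self):
        tab = pd.DataFrame({"bee_id": ["b1", "b1"], "bin_index": [1, 2], "activity": [5, 7]})
        assert experience(tab, "b1", 3) == 12

    def test_telescoping_identity(self, planted):
        """experience(k+1) - experience(k) == activity(k) whenever present."""
        log, _ = planted
        bins = bin_by_bouts(segment_bouts(log))
        metrics = compute_metrics([build_visitation_matrix(b, log.flowers) for b in bins])
        for _, row in metrics.iterrows():
            nxt = experience(metrics, row["bee_id"], row["bin_index"] + 1)
            cur = experience(metrics, row["bee_id"], row["bin_index"])
            assert nxt - cur == row["activity"]


class TestSpecificity:
    @pytest.mark.parametrize("n_flowers", [2, 5, 10, 17])
    def test_single_flower_endpoint(self, n_flowers):
        v = np.zeros(n_flowers)
        v[0] = 10
        assert flower_specificity(v) == pytest.approx(1.0)

    @pytest.mark.parametrize("n_flowers", [2, 5, 10, 17])
    def test_uniform_endpoint(self, n_flowers):
        assert flower_specificity(np.full(n_flowers, 3)) == pytest.approx(0.0)

    def test_two_of_ten_worked_case(self):
        # mean 1, population SD 2, CV 2, normalizer sqrt(9) = 3
        v = [5, 5, 0, 0, 0, 0, 0, 0, 0, 0]
        assert flower_specificity(v) == pytest.approx(2 / 3)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            flower_specificity(np.zeros(10))

    @given(
        counts=st.lists(st.integers(0, 50), min_size=2, max_size=12).filter(lambda c: sum(c) > 0),
        scale=st.integers(2, 9),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_and_range(self, counts, scale):
        v = np.array(counts, dtype=float)
        s = flower_specificity(v)
        assert 0.0 <= s <= 1.0 + 1e-12
        assert flower_specificity(v * scale) == pytest.approx(s)
        uniform = np.allclose(v, v.mean())
        assert (s == pytest.approx(0.0)) == uniform
        assert (s == pytest.approx(1.0)) == ((v > 0).sum() == 1)


class TestVIF:
    def test_orthogonal_predictors(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        y -= x * (x @ y) / (x @ x)  # exactly orthogonal
        out = variance_inflation(pd.DataFrame({"x": x - x.mean(), "y": y - y.mean()}))
        assert np.allclose(out["vif"], 1.0, atol=1e-6)

    def test_duplicated_predictor_infinite(self):
        x = np.arange(10.0)
        out = variance_inflation(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(out["vif"]).all()
        assert out["flagged"].all()

    def test_closed_form_two_predictors(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        e = rng.normal(size=500)
        y = 0.6 * x + e
        r = np.corrcoef(x, y)[0, 1]
        out = variance_inflation(pd.DataFrame({"x": x, "y": y}))
        expected = 1 / (1 - r**2)
        assert out["vif"].to_numpy() == pytest.approx([expected, expected], rel=1e-6)

    def test_vif_at_least_one(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        assert (variance_inflation(df)["vif"] >= 1 - 1e-12).all()


class TestSpecificityLMM:
    def test_recovers_planted_slope(self):
        from beepartite.validation import _lmm_table

        rng = np.random.default_rng(5)
        table = _lmm_table(rng, 10, 20, -0.1, -0.03, 0.08, 0.05)
        fit = fit_specificity_lmm(table)
        assert fit.coef("activity") == pytest.approx(-0.1, abs=0.02)
        assert fit.method.startswith("LMM")
        assert fit.random_effects == "(1 | bee_id)"

    def test_requires_multiple_bees(self):
        table = pd.DataFrame(
            {"bee_id": ["b"] * 5, "bin_index": range(5), "activity": range(5),
             "experience": range(5), "specificity": np.linspace(0, 1, 5)}
        )
        with pytest.raises(ValueError):
            fit_specificity_lmm(table)


class TestModularityLM:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(3)
        n = 20
        df = pd.DataFrame(
            {
                "mean_activity": rng.normal(size=n),
                "mean_experience": rng.normal(size=n),
                "n_bees": rng.integers(5, 11, size=n).astype(float),
            }
        )
        df["modularity"] = 0.3 + 0.05 * df.mean_activity - 0.02 * df.mean_experience + 0.01 * df.n_bees
        fit = fit_modularity_lm(df)
        assert fit.coef("mean_activity") == pytest.approx(0.05, abs=1e-10)
        assert fit.coef("mean_experience") == pytest.approx(-0.02, abs=1e-10)
        assert fit.coef("n_bees") == pytest.approx(0.01, abs=1e-10)

    def test_planted_negative_experience_effect(self):
        rng = np.random.default_rng(4)
        n = 40
        df = pd.DataFrame(
            {
                "mean_activity": rng.normal(size=n),
                "mean_experience": rng.normal(size=n),
                "n_bees": rng.integers(5, 11, size=n).astype(float),
            }
        )
        df["modularity"] = 0.4 - 0.1 * df.mean_experience + rng.normal(0, 0.02, size=n)
        fit = fit_modularity_lm(df)
        assert fit.coef("mean_experience") < 0
        assert fit.pvalue("mean_experience") < 0.01

    def test_too_few_rows(self):
        df = pd.DataFrame(
            {"modularity": [0.1, 0.2], "mean_activity": [1, 2], "mean_experience": [1, 2], "n_bees": [3, 4]}
        )
        with pytest.raises(ValueError):
            fit_modularity_lm(df)
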