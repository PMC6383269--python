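"""Validation experiments: oracle agreement, null calibration, power, and
parameter recovery.

These routines generate data with known ground truth, push it through the
package's estimators, and measure agreement rates. They are used both by
the test suite and by the acceptance runner, with the experiment sizes
passed in by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interactions import fit_replacement_model, fit_revisit_model
from .metrics import fit_specificity_lmm
from .modularity import dirt_lpa_wb_plus, exhaustive_modularity
from .nullmodels import modularity_zscore, patefield_sample

__all__ = [
    "oracle_agreement",
    "patefield_two_table_check",
    "null_type1_rate",
    "planted_power",
    "planted_matrix",
    "lmm_slope_recovery",
    "replacement_effect_recovery",
    "revisit_effect_recovery",
]


def oracle_agreement(n_matrices: int = 100, reps: int = 5, max_nodes: int = 10, seed: int = 0) -> float:
    """Fraction of small random integer matrices on which the multi-start
    label-propagation Q equals the exhaustive-search optimum."""
    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_matrices):
        R = int(rng.integers(2, 5))
        C = int(rng.integers(2, min(6, max_nodes - R) + 1))
        A = rng.integers(0, 6, size=(R, C))
        if A.sum() == 0:
            A[0, 0] = 1
        q_star = exhaustive_modularity(A, max_nodes=max_nodes).Q
        q_lpa = dirt_lpa_wb_plus(A, reps=reps, rng_seed=int(rng.integers(2**31))).Q
        if q_lpa > q_star + 1e-9:
            raise AssertionError("heuristic exceeded the exhaustive optimum")
        agree += q_lpa > q_star - 1e-9
    return agree / n_matrices


def patefield_two_table_check(n_draws: int = 10_000, seed: int = 0) -> dict:
    """Margins (1,1)/(1,1) admit exactly two tables, each with probability
    1/2. Returns the identity-table frequency, its 3-sigma band half-width,
    and the fraction of draws conserving the margins."""
    draws = patefield_sample([1, 1], [1, 1], rng_seed=seed, size=n_draws)
    conserve = np.mean(
        (draws.sum(axis=2) == [1, 1]).all(axis=1) & (draws.sum(axis=1) == [1, 1]).all(axis=1)
    )
    freq_identity = np.mean(draws[:, 0, 0] == 1)
    sigma = 0.5 / np.sqrt(n_draws)
    return {
        "freq_identity": float(freq_identity),
        "three_sigma": 3 * sigma,
        "margin_conservation": float(conserve),
    }


def planted_matrix(
    rng: np.random.Generator,
    n_flowers: int = 10,
    n_bees: int = 8,
    visits_per_bee: int = 40,
    within_prob: float = 0.95,
    n_modules: int = 2,
) -> np.ndarray:
    """Flower x bee count matrix with planted block structure: each visit of
    a bee lands in its module's flower block with probability
    ``within_prob``, else uniformly outside."""
    blocks = np.array_split(np.arange(n_flowers), n_modules)
    A = np.zeros((n_flowers, n_bees), dtype=int)
    for j in range(n_bees):
        own = blocks[j % n_modules]
        other = np.setdiff1d(np.arange(n_flowers), own)
        n = rng.poisson(visits_per_bee)
        for _ in range(max(n, 1)):
            fl = rng.choice(own) if (len(other) == 0 or rng.random() < within_prob) else rng.choice(other)
            A[fl, j] += 1
    return A


def _uniform_matrix(rng: np.random.Generator, n_flowers: int, n_bees: int, visits_per_bee: int) -> np.ndarray:
    A = np.zeros((n_flowers, n_bees), dtype=int)
    for j in range(n_bees):
        n = max(rng.poisson(visits_per_bee), 1)
        idx = rng.integers(0, n_flowers, size=n)
        np.add.at(A[:, j], idx, 1)
    return A


def null_type1_rate(
    n_replicates: int = 200,
    n_null: int = 100,
    reps: int = 1,
    module_guess_range=range(2, 5),
    n_flowers: int = 10,
    n_bees: int = 8,
    visits_per_bee: int = 40,
    seed: int = 0,
) -> float:
    """Fraction of margin-matched random networks flagged significant.

    Each replicate draws an 'observed' matrix by Patefield sampling from the
    margins of a preference-free matrix, so the z > 2 rule should fire at
    most at its nominal one-sided rate.
    """
    rng = np.random.default_rng(seed)
    flagged = 0
    for i in range(n_replicates):
        base = _uniform_matrix(rng, n_flowers, n_bees, visits_per_bee)
        obs = patefield_sample(base.sum(axis=1), base.sum(axis=0), rng, size=1)[0]
        comp = modularity_zscore(
            obs, n_null=n_null, reps=reps, module_guess_range=module_guess_range,
            rng_seed=int(rng.integers(2**31)),
        )
        flagged += bool(comp.significant)
    return flagged / n_replicates


def planted_power(
    n_replicates: int = 200,
    n_null: int = 100,
    reps: int = 1,
    module_guess_range=range(2, 5),
    within_prob: float = 0.95,
    n_flowers: int = 10,
    n_bees: int = 8,
    visits_per_bee: int = 40,
    seed: int = 0,
) -> float:
    """Fraction of strongly block-structured networks flagged significant."""
    rng = np.random.default_rng(seed)
    flagged = 0
    for i in range(n_replicates):
        obs = planted_matrix(rng, n_flowers, n_bees, visits_per_bee, within_prob)
        comp = modularity_zscore(
            obs, n_null=n_null, reps=reps, module_guess_range=module_guess_range,
            rng_seed=int(rng.integers(2**31)),
        )
        flagged += bool(comp.significant)
    return flagged / n_replicates


# ---------------------------------------------------------------------------
# model parameter recovery
# ---------------------------------------------------------------------------

def _lmm_table(rng, n_bees, n_bins, slope_act, slope_exp, sd_bee, sd_eps):
    rows = []
    u = rng.normal(0, sd_bee, size=n_bees)
    for b in range(n_bees):
        for k in range(1, n_bins + 1):
            act = rng.normal(0, 1)
            exp_ = rng.normal(0, 1)
            y = 0.5 + slope_act * act + slope_exp * exp_ + u[b] + rng.normal(0, sd_eps)
            rows.append({"bee_id": f"B{b}", "bin_index": k, "activity": act, "experience": exp_, "specificity": y})
    return pd.DataFrame(rows)


def lmm_slope_recovery(
    n_replicates: int = 100,
    slopes: tuple[float, float] = (-0.1, -0.03),
    n_bees: int = 10,
    n_bins: int = 15,
    sd_bee: float = 0.08,
    sd_eps: float = 0.1,
    seed: int = 0,
) -> dict:
    """Simulate mixed-model data with known slopes and measure 95%-interval
    coverage of both fixed effects across replicates."""
    rng = np.random.default_rng(seed)
    cover_act = cover_exp = 0
    for _ in range(n_replicates):
        table = _lmm_table(rng, n_bees, n_bins, slopes[0], slopes[1], sd_bee, sd_eps)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_specificity_lmm(table)
        lo, hi = fit.conf_int("activity")
        cover_act += lo <= slopes[0] <= hi
        lo, hi = fit.conf_int("experience")
        cover_exp += lo <= slopes[1] <= hi
    return {
        "coverage_activity": cover_act / n_replicates,
        "coverage_experience": cover_exp / n_replicates,
    }


def _interaction_table(rng, n_events, n_bees, beta_consumed, sd_bee=0.3):
    u = rng.normal(0, sd_bee, size=n_bees)
    rows = []
    for _ in range(n_events):
        res, join = rng.choice(n_bees, size=2, replace=False)
        consumed = int(rng.random() < 0.5)
        feed_z = rng.normal()
        over_z = rng.normal()
        eta = 0.0 + beta_consumed * consumed + u[res] + u[join]
        rows.append(
            {
                "replaced": int(rng.random() < 1 / (1 + np.exp(-eta))),
                "consumed": consumed,
                "feed_time_z": feed_z,
                "overlap_z": over_z,
                "resident_id": f"B{res}",
                "joiner_id": f"B{join}",
            }
        )
    return pd.DataFrame(rows)


def replacement_effect_recovery(
    n_replicates: int = 100,
    beta_consumed: float = -1.5,
    n_events: int = 300,
    n_bees: int = 10,
    seed: int = 0,
) -> dict:
    """Plant a reward-status effect on replacement probability and measure
    how often the mixed logit recovers its sign and significance (or, for a
    zero effect, how often the 95% interval covers 0)."""
    rng = np.random.default_rng(seed)
    hits = 0
    n_ok = 0
    for _ in range(n_replicates):
        table = _interaction_table(rng, n_events, n_bees, beta_consumed)
        if table["replaced"].nunique() < 2:
            continue
        n_ok += 1
        fit = fit_replacement_model(table, include_differences=False)
        if beta_consumed == 0:
            lo, hi = fit.conf_int("consumed")
            hits += lo <= 0 <= hi
        else:
            z = fit.stat("consumed")
            hits += (np.sign(fit.coef("consumed")) == np.sign(beta_consumed)) and abs(z) > 1.96
    return {"recovery_rate": hits / max(n_ok, 1), "n_fitted": n_ok}


def revisit_effect_recovery(
    n_replicates: int = 50,
    beta_interaction: float = 0.6,
    n_events: int = 300,
    n_bees: int = 10,
    seed: int = 0,
) -> dict:
    """Plant a 'won on a rewarding flower -> return more' effect on
    next-bout visit counts and measure sign+significance recovery."""
    rng = np.random.default_rng(seed)
    hits = 0
    n_ok = 0
    for _ in range(n_replicates):
        u = rng.normal(0, 0.2, size=n_bees)
        rows = []
        for _e in range(n_events):
            bee, partner = rng.choice(n_bees, size=2, replace=False)
            won = int(rng.random() < 0.5)
            consumed = int(rng.random() < 0.5)
            eta = 0.2 + beta_interaction * won * consumed + u[bee]
            rows.append(
                {
                    "bee_id": f"B{bee}",
                    "partner_id": f"B{partner}",
                    "visits_next_bout": rng.poisson(np.exp(eta)),
                    "won": won,
                    "consumed": consumed,
                }
            )
        table = pd.DataFrame(rows)
        if (table["visits_next_bout"] == 0).all():
            continue
        n_ok += 1
        fit = fit_revisit_model(table)
        if beta_interaction == 0:
            lo, hi = fit.conf_int("won:consumed")
            hits += lo <= 0 <= hi
        else:
            hits += (fit.coef("won:consumed") > 0) and fit.stat("won:consumed") > 1.96
    return {"recovery_rate": hits / max(n_ok, 1), "n_fitted": n_ok}
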