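"""Marginals-preserving null models for visitation matrices.

Observed modularity is judged against an ensemble of random contingency
tables sharing the observed row and column totals, drawn uniformly by the
Patefield algorithm (sequential hypergeometric cell filling). The observed
Q is standardized against the null mean and SD; a network is called
significantly modular when its z-score exceeds 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .modularity import dirt_lpa_wb_plus

__all__ = ["NullComparison", "patefield_sample", "modularity_zscore"]

Z_THRESHOLD = 2.0


@dataclass
class NullComparison:
    """Observed modularity against a fixed-margins null ensemble."""

    Q_obs: float
    null_Qs: np.ndarray
    null_mean: float
    null_sd: float
    z: float  # NaN when the null ensemble is degenerate (sd == 0)
    significant: bool
    degenerate: bool = False
    bin_index: int | None = None

    def to_dict(self) -> dict:
        return {
            "Q_obs": self.Q_obs,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": None if np.isnan(self.z) else self.z,
            "significant": bool(self.significant),
            "degenerate": self.degenerate,
            "n_null": int(len(self.null_Qs)),
        }


def patefield_sample(row_margins, col_margins, rng_seed=0, size: int = 1) -> np.ndarray:
    """Draw uniform random contingency tables with the given margins.

    Uses Patefield's sequential hypergeometric construction (each cell
    drawn conditionally on the remaining row and column totals), which
    samples exactly from the uniform-multivariate-hypergeometric law over
    all tables with those margins.

    Returns an array of shape ``(size, R, C)``; ``size=1`` still keeps the
    leading axis for uniformity.
    """
    r = np.asarray(row_margins, dtype=int)
    c = np.asarray(col_margins, dtype=int)
    if (r < 0).any() or (c < 0).any():
        raise ValueError("margins must be nonnegative")
    if r.sum() != c.sum():
        raise ValueError(f"margin sums differ: rows {r.sum()} vs columns {c.sum()}")
    if r.sum() == 0:
        raise ValueError("margin sums must be positive")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if len(r) == 1 or len(c) == 1:
        # forced table: a single row (or column) must equal its margins
        forced = np.outer(r, c) // max(r.sum(), 1)
        return np.broadcast_to(forced, (size, len(r), len(c))).copy()
    dist = stats.random_table(r, c)
    draws = dist.rvs(size, method="patefield", random_state=rng)
    return np.asarray(draws, dtype=int).reshape(size, len(r), len(c))


def modularity_zscore(
    matrix,
    n_null: int = 100,
    reps: int = 10,
    module_guess_range=None,
    rng_seed: int = 0,
) -> NullComparison:
    """Standardize the observed modularity against ``n_null`` fixed-margins
    random tables.

    Each null matrix is maximized with the same multi-start settings as the
    observed one, on an independent substream of the master seed. The null
    SD uses the sample (n-1) denominator; ``significant`` is the one-sided
    rule z > 2.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    counts = np.asarray(getattr(matrix, "counts", matrix))
    ss = np.random.SeedSequence(rng_seed)
    subs = ss.spawn(n_null + 1)
    obs = dirt_lpa_wb_plus(counts, reps=reps, module_guess_range=module_guess_range,
                           rng_seed=int(subs[0].generate_state(1)[0] % (2**31)))
    r = counts.sum(axis=1).astype(int)
    c = counts.sum(axis=0).astype(int)
    null_Qs = np.empty(n_null)
    for i, child in enumerate(subs[1:]):
        rng = np.random.default_rng(child)
        null = patefield_sample(r, c, rng, size=1)[0]
        null_Qs[i] = dirt_lpa_wb_plus(
            null, reps=reps, module_guess_range=module_guess_range,
            rng_seed=int(child.generate_state(2)[1] % (2**31)),
        ).Q
    mu = float(null_Qs.mean())
    sd = float(null_Qs.std(ddof=1))
    if sd == 0.0:
        return NullComparison(obs.Q, null_Qs, mu, sd, float("nan"), False, degenerate=True)
    z = (obs.Q - mu) / sd
    return NullComparison(obs.Q, null_Qs, mu, sd, float(z), bool(z > Z_THRESHOLD))
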