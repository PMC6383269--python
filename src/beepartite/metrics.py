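"""Per-bee foraging metrics and the two regressions built on them.

For every bee in every eight-bout bin we measure:

* **activity** — the bee's total flower visits inside the bin;
* **experience** — its cumulative visits over all earlier bins;
* **flower specificity** — the normalized coefficient of variation of its
  visit distribution over the full flower set: the population CV of the R
  per-flower counts divided by sqrt(R - 1), which is 0 for perfectly uniform
  use of all flowers and 1 when every visit lands on a single flower.

Specificity is then modelled on activity and experience with a linear mixed
model (random intercept per bee, REML), and per-bin modularity on mean
activity, mean experience and the number of bees foraging with an ordinary
least-squares model. A variance-inflation-factor screen guards both against
collinear predictors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .visitlog import VisitationMatrix

__all__ = [
    "BeeBinMetrics",
    "ModelFit",
    "activity",
    "experience",
    "flower_specificity",
    "compute_metrics",
    "variance_inflation",
    "fit_specificity_lmm",
    "fit_modularity_lm",
]


@dataclass
class ModelFit:
    """A fitted regression summarized as aligned per-term vectors."""

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    stats: np.ndarray  # t or z, matching `stat_name`
    pvalues: np.ndarray
    stat_name: str = "t"
    random_effects: str | None = None
    method: str = "OLS"
    notes: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.bse[self.terms.index(term)])

    def stat(self, term: str) -> float:
        return float(self.stats[self.terms.index(term)])

    def pvalue(self, term: str) -> float:
        return float(self.pvalues[self.terms.index(term)])

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        q = norm.ppf(0.5 + level / 2)
        i = self.terms.index(term)
        return float(self.params[i] - q * self.bse[i]), float(self.params[i] + q * self.bse[i])

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "random_effects": self.random_effects,
            "stat_name": self.stat_name,
            "terms": {
                t: {
                    "estimate": float(self.params[i]),
                    "se": float(self.bse[i]),
                    self.stat_name: float(self.stats[i]),
                    "p": float(self.pvalues[i]),
                }
                for i, t in enumerate(self.terms)
            },
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [f"{self.method}" + (f" (random: {self.random_effects})" if self.random_effects else "")]
        lines.append(f"{'term':<28}{'estimate':>12}{'SE':>12}{self.stat_name:>10}{'p':>12}")
        for i, t in enumerate(self.terms):
            lines.append(
                f"{t:<28}{self.params[i]:>12.4f}{self.bse[i]:>12.4f}"
                f"{self.stats[i]:>10.3f}{self.pvalues[i]:>12.4g}"
            )
        for n in self.notes:
            lines.append(f"  note: {n}")
        return "\n".join(lines)


# alias used in type hints / docs: a long table with one row per (bee, bin)
BeeBinMetrics = pd.DataFrame


def activity(matrix: VisitationMatrix, bee: str) -> int:
    """Visit count of one bee within one bin (its column sum)."""
    if bee not in matrix.col_labels:
        raise KeyError(f"bee {bee!r} is not a column of this matrix")
    j = matrix.col_labels.index(bee)
    return int(matrix.counts[:, j].sum())


def experience(metrics: pd.DataFrame, bee: str, bin_index: int) -> int:
    """Cumulative activity of a bee over bins strictly before ``bin_index``."""
    if bin_index < 1:
        raise ValueError("bin_index is 1-based")
    sub = metrics[(metrics["bee_id"] == bee) & (metrics["bin_index"] < bin_index)]
    return int(sub["activity"].sum())


def flower_specificity(visit_counts) -> float:
    """Normalized coefficient of variation of a visit distribution.

    ``visit_counts`` is the vector of per-flower counts over the *full*
    declared flower set (zeros included). The population CV (n-denominator
    SD over mean) is divided by sqrt(R - 1), pinning the endpoints: 0 for a
    uniform distribution, 1 when a single flower receives every visit.
    """
    x = np.asarray(visit_counts, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("visit_counts must be a vector over >= 2 flowers")
    if (x < 0).any():
        raise ValueError("visit counts must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("specificity undefined for an all-zero visit vector")
    mean = x.mean()
    cv = x.std(ddof=0) / mean
    return float(cv / np.sqrt(len(x) - 1))


def compute_metrics(matrices: list[VisitationMatrix]) -> pd.DataFrame:
    """Long table of (bee, bin) metrics from per-bin visitation matrices.

    Rows exist only where a bee made >= 1 visit in the bin; experience still
    accumulates over all prior bins.
    """
    rows = []
    cum: dict[str, int] = {}
    for m in sorted(matrices, key=lambda m: m.bin_index or 0):
        for j, bee in enumerate(m.col_labels):
            col = m.counts[:, j]
            act = int(col.sum())
            if act == 0:
                continue
            rows.append(
                {
                    "bee_id": bee,
                    "bin_index": m.bin_index,
                    "activity": act,
                    "experience": cum.get(bee, 0),
                    "specificity": flower_specificity(col),
                }
            )
        for j, bee in enumerate(m.col_labels):
            cum[bee] = cum.get(bee, 0) + int(m.counts[:, j].sum())
    return pd.DataFrame(rows, columns=["bee_id", "bin_index", "activity", "experience", "specificity"])


def variance_inflation(design: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """VIF of each predictor from regressing it on all the others.

    Returns a frame with columns ``vif`` and ``flagged`` (vif > threshold).
    Perfect collinearity yields ``inf``.
    """
    X = design.astype(float)
    if X.shape[1] < 2:
        raise ValueError("need at least two predictors")
    out = []
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2 = sm.OLS(X[col], others).fit().rsquared
        vif = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        out.append({"predictor": col, "vif": vif, "flagged": vif > threshold})
    return pd.DataFrame(out).set_index("predictor")


def fit_specificity_lmm(table: pd.DataFrame) -> ModelFit:
    """Linear mixed model: specificity ~ activity + experience with a
    random intercept per bee, fitted by REML. Falls back to OLS with a
    warning when the random-effect variance is singular or the fit fails."""
    required = {"bee_id", "activity", "experience", "specificity"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must contain columns {sorted(required)}")
    if table["bee_id"].nunique() < 2:
        raise ValueError("need >= 2 bees for a mixed model")
    notes: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("specificity ~ activity + experience", table, groups=table["bee_id"])
            res = model.fit(reml=True)
        if not res.converged or np.isnan(res.bse.iloc[:3]).any():
            raise np.linalg.LinAlgError("singular mixed-model fit")
        terms = ["Intercept", "activity", "experience"]
        return ModelFit(
            terms,
            res.params[terms].to_numpy(),
            res.bse[terms].to_numpy(),
            res.tvalues[terms].to_numpy(),
            res.pvalues[terms].to_numpy(),
            stat_name="t",
            random_effects="(1 | bee_id)",
            method="LMM (REML)",
            notes=notes,
        )
    except (np.linalg.LinAlgError, ValueError) as err:
        warnings.warn(f"mixed model failed ({err}); falling back to OLS")
        notes.append("random-intercept fit singular; plain OLS fallback")
        res = smf.ols("specificity ~ activity + experience", table).fit()
        terms = ["Intercept", "activity", "experience"]
        return ModelFit(
            terms,
            res.params[terms].to_numpy(),
            res.bse[terms].to_numpy(),
            res.tvalues[terms].to_numpy(),
            res.pvalues[terms].to_numpy(),
            stat_name="t",
            method="OLS (fallback)",
            notes=notes,
        )


def fit_modularity_lm(network_summaries: pd.DataFrame) -> ModelFit:
    """OLS of per-bin modularity on mean activity, mean experience and the
    number of bees foraging in the bin."""
    required = {"modularity", "mean_activity", "mean_experience", "n_bees"}
    if not required.issubset(network_summaries.columns):
        raise ValueError(f"table must contain columns {sorted(required)}")
    if len(network_summaries) < 5:
        raise ValueError("need more bins than parameters")
    res = smf.ols("modularity ~ mean_activity + mean_experience + n_bees", network_summaries).fit()
    terms = list(res.params.index)
    return ModelFit(
        terms,
        res.params.to_numpy(),
        res.bse.to_numpy(),
        res.tvalues.to_numpy(),
        res.pvalues.to_numpy(),
        stat_name="t",
        method="OLS",
    )
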