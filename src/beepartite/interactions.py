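"""Two-bee encounters on flowers: classification and outcome models.

When a bee lands on an occupied flower, the encounter resolves either with
the joiner leaving first (*resident stays*) or the resident being replaced
(*resident leaves*). Crossing that outcome with the flower's inferred reward
state gives four classes: the reward is deemed *consumed* when the resident
fed for more than 8 s before being joined (the time a lone bee takes to
drain a full 40-uL cup), otherwise *not consumed*.

Encounter outcomes are modelled with a binomial mixed model (logit link) of
replacement probability on reward status, the resident's pre-arrival feeding
time, the encounter's duration, their interactions, and joiner-minus-resident
differences in activity, experience, specificity and body size, with crossed
random intercepts for the two bee identities. The carry-over of an encounter
into the next foraging bout is modelled with a Poisson mixed model of
next-bout visit counts to the contested flower. Both mixed models are
estimated by Laplace (posterior-mode) approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM, PoissonBayesMixedGLM

from .metrics import ModelFit
from .visitlog import ForagingBout, TimeBin

__all__ = [
    "InteractionEvent",
    "ClassifiedInteraction",
    "classify_interaction",
    "read_interaction_log",
    "build_interaction_table",
    "build_revisit_table",
    "fit_replacement_model",
    "fit_revisit_model",
]

CONSUMED_THRESHOLD_S = 8.0

INTERACTION_COLUMNS = [
    "flower_id", "day", "resident_id", "joiner_id",
    "t_resident_arrival_s", "t_joiner_arrival_s", "t_first_departure_s",
    "first_leaver_id", "contact",
]


@dataclass
class InteractionEvent:
    """One two-bee encounter on a flower (>= 3-bee clips excluded upstream)."""

    flower_id: str
    resident_id: str
    joiner_id: str
    day: int
    t_resident_arrival: float
    t_joiner_arrival: float
    t_first_departure: float
    first_leaver_id: str
    contact: bool = True
    resident_feed_time: float | None = None  # seconds fed before being joined

    def __post_init__(self) -> None:
        if not (self.t_resident_arrival < self.t_joiner_arrival <= self.t_first_departure):
            raise ValueError(
                "need t_resident_arrival < t_joiner_arrival <= t_first_departure "
                f"(got {self.t_resident_arrival}, {self.t_joiner_arrival}, {self.t_first_departure})"
            )
        if self.first_leaver_id not in (self.resident_id, self.joiner_id):
            raise ValueError("first_leaver_id must be one of the two bees")
        if self.resident_feed_time is None:
            # without finer feeding data, the resident is assumed feeding from arrival
            self.resident_feed_time = self.t_joiner_arrival - self.t_resident_arrival

    @property
    def overlap_duration(self) -> float:
        return self.t_first_departure - self.t_joiner_arrival


@dataclass
class ClassifiedInteraction:
    event: InteractionEvent
    outcome: str  # "resident_stays" | "resident_leaves"
    reward_status: str  # "consumed" | "not_consumed"
    boundary_flag: bool = False  # feed time exactly at the threshold
    tie_flag: bool = False  # simultaneous departures resolved by rule

    @property
    def replaced(self) -> int:
        """1 when the joiner replaced the resident."""
        return int(self.outcome == "resident_leaves")


def classify_interaction(
    event: InteractionEvent,
    consumed_threshold_s: float = CONSUMED_THRESHOLD_S,
    tie_rule: str = "resident_stays",
) -> ClassifiedInteraction:
    """Assign an encounter its outcome and reward-status classes.

    The reward is *consumed* only under the strict rule
    ``resident_feed_time > consumed_threshold_s``; an exact-boundary event
    is classed not-consumed and flagged.
    """
    outcome = "resident_leaves" if event.first_leaver_id == event.resident_id else "resident_stays"
    feed = float(event.resident_feed_time)
    status = "consumed" if feed > consumed_threshold_s else "not_consumed"
    return ClassifiedInteraction(
        event,
        outcome,
        status,
        boundary_flag=(feed == consumed_threshold_s),
    )


def read_interaction_log(path) -> list[InteractionEvent]:
    """Read the encounter CSV (one row per two-bee event)."""
    df = pd.read_csv(path)
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    events = []
    for _, row in df.iterrows():
        events.append(
            InteractionEvent(
                flower_id=str(row["flower_id"]),
                resident_id=str(row["resident_id"]),
                joiner_id=str(row["joiner_id"]),
                day=int(row["day"]),
                t_resident_arrival=float(row["t_resident_arrival_s"]),
                t_joiner_arrival=float(row["t_joiner_arrival_s"]),
                t_first_departure=float(row["t_first_departure_s"]),
                first_leaver_id=str(row["first_leaver_id"]),
                contact=bool(row["contact"]),
            )
        )
    return events


def write_interaction_log(events: list[InteractionEvent], path) -> None:
    rows = [
        {
            "flower_id": e.flower_id, "day": e.day,
            "resident_id": e.resident_id, "joiner_id": e.joiner_id,
            "t_resident_arrival_s": e.t_resident_arrival,
            "t_joiner_arrival_s": e.t_joiner_arrival,
            "t_first_departure_s": e.t_first_departure,
            "first_leaver_id": e.first_leaver_id, "contact": e.contact,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=INTERACTION_COLUMNS).to_csv(path, index=False)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        warnings.warn("degenerate standardization (zero variance); column centred only")
        return x - x.mean()
    return (x - x.mean()) / sd


def _bin_of(day: int, t: float, bins: list[TimeBin]) -> int | None:
    for b in bins:
        if b.day == day and b.t_start <= t <= b.t_end:
            return b.index
    # fall back to the last bin of that day (events after the final close)
    day_bins = [b for b in bins if b.day == day]
    return day_bins[-1].index if day_bins else None


def build_interaction_table(
    classified: list[ClassifiedInteraction],
    metrics: pd.DataFrame | None = None,
    bins: list[TimeBin] | None = None,
    body_size: pd.Series | None = None,
    contact_only: bool = True,
) -> pd.DataFrame:
    """One model row per (contact) encounter.

    Columns: ``replaced`` (joiner replaced resident), ``consumed`` (0/1),
    standardized ``feed_time_z`` and ``overlap_z``, and joiner-minus-resident
    signed and absolute differences in activity, experience, specificity and
    body size where the inputs allow. Metric differences require ``metrics``
    (a (bee, bin) long table) together with ``bins`` to place each event in
    its bin.
    """
    rows = []
    for ci in classified:
        if contact_only and not ci.event.contact:
            continue
        e = ci.event
        row = {
            "replaced": ci.replaced,
            "consumed": int(ci.reward_status == "consumed"),
            "feed_time": float(e.resident_feed_time),
            "overlap": float(e.overlap_duration),
            "resident_id": e.resident_id,
            "joiner_id": e.joiner_id,
            "flower_id": e.flower_id,
            "day": e.day,
        }
        if metrics is not None and bins is not None:
            k = _bin_of(e.day, e.t_joiner_arrival, bins)
            for name in ("activity", "experience", "specificity"):
                vals = {}
                for role, bee in (("joiner", e.joiner_id), ("resident", e.resident_id)):
                    sub = metrics[(metrics["bee_id"] == bee) & (metrics["bin_index"] == k)]
                    vals[role] = float(sub[name].iloc[0]) if len(sub) else np.nan
                row[f"d_{name}"] = vals["joiner"] - vals["resident"]
        if body_size is not None:
            try:
                row["d_size"] = float(body_size[e.joiner_id]) - float(body_size[e.resident_id])
            except KeyError:
                row["d_size"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) == 0:
        return df
    df["feed_time_z"] = _standardize(df["feed_time"].to_numpy())
    df["overlap_z"] = _standardize(df["overlap"].to_numpy())
    for c in [c for c in df.columns if c.startswith("d_")]:
        df[f"abs_{c[2:]}"] = df[c].abs()
    return df


def _laplace_glmm(model_cls, formula: str, vc_formulas: dict, ident_data: pd.DataFrame) -> ModelFit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = model_cls.from_formula(formula, vc_formulas, ident_data)
        res = model.fit_map()
    names = list(model.exog_names)
    params = np.asarray(res.fe_mean)
    ses = np.asarray(res.fe_sd)
    z = params / ses
    p = 2 * (1 - norm.cdf(np.abs(z)))
    return ModelFit(
        names, params, ses, z, p,
        stat_name="z",
        random_effects=" + ".join(f"(1 | {k})" for k in vc_formulas),
        method=f"{model_cls.__name__} (Laplace / posterior mode)",
    )


def fit_replacement_model(
    table: pd.DataFrame,
    include_differences: bool = True,
    include_specificity: bool = True,
) -> ModelFit:
    """Binomial (logit) mixed model of replacement probability.

    Fixed effects: reward status, standardized pre-arrival feeding time and
    encounter duration, each also interacted with reward status, plus the
    available joiner-minus-resident difference covariates. Crossed random
    intercepts for resident and joiner identity, estimated by Laplace
    approximation.
    """
    if table["replaced"].nunique() < 2:
        raise ValueError("complete separation: only one outcome class present")
    terms = ["consumed", "feed_time_z", "overlap_z", "feed_time_z:consumed", "overlap_z:consumed"]
    if include_differences:
        for c in ("d_activity", "d_experience", "d_specificity", "d_size"):
            if c in table.columns and table[c].notna().all():
                if c == "d_specificity" and not include_specificity:
                    continue
                terms.append(c)
    # a constant column (e.g. every encounter on a drained cup) carries no
    # information and breaks the design matrix
    terms = [
        t for t in terms
        if all(table[p].nunique() > 1 for p in t.split(":") if p in table.columns)
    ]
    if not terms:
        raise ValueError("no informative predictors (all columns constant)")
    formula = "replaced ~ " + " + ".join(terms)
    vc = {"resident": "0 + C(resident_id)", "joiner": "0 + C(joiner_id)"}
    return _laplace_glmm(BinomialBayesMixedGLM, formula, vc, table)


def build_revisit_table(
    classified: list[ClassifiedInteraction],
    bouts: list[ForagingBout],
) -> pd.DataFrame:
    """Align each encounter with each participant's next foraging bout.

    For both bees of every encounter, the response is the number of visits
    the bee made to the contested flower during its next bout after the one
    containing the encounter; ``won`` records whether the bee held or took
    the flower (1) or was the first to leave (0), and ``consumed`` the
    flower's reward status at the encounter.
    """
    by_bee: dict[str, list[ForagingBout]] = {}
    for b in bouts:
        by_bee.setdefault(b.bee_id, []).append(b)
    for seq in by_bee.values():
        seq.sort(key=lambda b: (b.day, b.t_start))
    rows = []
    for ci in classified:
        e = ci.event
        for bee, won in ((e.resident_id, ci.outcome == "resident_stays"),
                         (e.joiner_id, ci.outcome == "resident_leaves")):
            seq = by_bee.get(bee, [])
            cur = next(
                (i for i, b in enumerate(seq)
                 if b.day == e.day and b.t_start <= e.t_joiner_arrival <= b.t_end),
                None,
            )
            if cur is None or cur + 1 >= len(seq):
                continue
            nxt = seq[cur + 1]
            n_visits = int((nxt.visits["flower_id"] == e.flower_id).sum())
            partner = e.joiner_id if bee == e.resident_id else e.resident_id
            rows.append(
                {
                    "bee_id": bee,
                    "partner_id": partner,
                    "flower_id": e.flower_id,
                    "day": e.day,
                    "visits_next_bout": n_visits,
                    "won": int(won),
                    "consumed": int(ci.reward_status == "consumed"),
                }
            )
    return pd.DataFrame(rows)


def fit_revisit_model(table: pd.DataFrame) -> ModelFit:
    """Poisson mixed model of next-bout visits to the contested flower on
    the encounter outcome, reward status, and their interaction, with
    crossed random intercepts for the two bee identities."""
    if len(table) == 0 or (table["visits_next_bout"] == 0).all():
        raise ValueError("all-zero response: revisit model is undefined")
    terms = [t for t in ("won", "consumed", "won:consumed")
             if all(table[p].nunique() > 1 for p in t.split(":"))]
    if not terms:
        raise ValueError("no informative predictors (all columns constant)")
    formula = "visits_next_bout ~ " + " + ".join(terms)
    vc = {"bee": "0 + C(bee_id)", "partner": "0 + C(partner_id)"}
    return _laplace_glmm(PoissonBayesMixedGLM, formula, vc, table)
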