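"""Ingestion and structuring of flower-visit logs.

A visit log records one row per landing of an individually tagged bee on an
artificial flower: the day of the session, the bee and flower identities,
arrival and departure times in seconds from the start of that day's session,
and whether the bee collected sucrose. From such a log we reconstruct
foraging bouts (round trips from the nest), restrict attention to motivated
foragers, cut each day into bins defined by the time the fastest bee needs
to complete eight bouts, and tabulate flower-by-bee visitation matrices,
one per bin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order for a visit log
VISIT_COLUMNS = ["day", "bee_id", "flower_id", "t_arrival_s", "t_departure_s", "fed", "bout_id"]

REQUIRED_COLUMNS = ["day", "bee_id", "flower_id", "t_arrival_s", "t_departure_s"]


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class ValidationError(ValueError):
    """A row violates the visit-record contract."""


@dataclass
class VisitLog:
    """A validated, time-sorted table of flower visits.

    Attributes
    ----------
    visits :
        DataFrame with the canonical columns ``day, bee_id, flower_id,
        t_arrival_s, t_departure_s, fed, bout_id`` sorted by
        ``(day, t_arrival_s)``. ``bout_id`` may be all-NA when the source
        log carries no bout delimiters.
    flowers :
        The declared flower set, in display order. Flowers never visited
        still appear as matrix rows downstream.
    """

    visits: pd.DataFrame
    flowers: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.visits)

    @property
    def bees(self) -> tuple[str, ...]:
        return tuple(sorted(self.visits["bee_id"].unique()))

    def per_bee_totals(self) -> pd.Series:
        return self.visits.groupby("bee_id").size().sort_values(ascending=False)

    def per_flower_totals(self) -> pd.Series:
        return self.visits.groupby("flower_id").size().reindex(list(self.flowers), fill_value=0)

    @property
    def has_bout_ids(self) -> bool:
        return self.visits["bout_id"].notna().all() and len(self.visits) > 0


@dataclass
class ForagingBout:
    """One round trip: nest departure, a run of flower visits, nest return."""

    bee_id: str
    index: int  # per-bee ordinal, 1-based, time ordered
    day: int
    t_start: float
    t_end: float
    visits: pd.DataFrame

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def n_unique_flowers(self) -> int:
        return self.visits["flower_id"].nunique()


@dataclass
class TimeBin:
    """A within-day interval closed when the first bee completes its
    ``bouts_per_bin``-th bout since the interval opened."""

    index: int  # global, 1-based across days
    day: int
    t_start: float
    t_end: float
    bouts: list[ForagingBout] = field(default_factory=list)
    whole_day: bool = False  # fallback: no bee reached the bout quota
    merged_tail: bool = False  # trailing partial period folded in

    def bouts_per_bee(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.bouts:
            out[b.bee_id] = out.get(b.bee_id, 0) + 1
        return out

    @property
    def bees(self) -> tuple[str, ...]:
        return tuple(sorted({b.bee_id for b in self.bouts}))


@dataclass
class VisitationMatrix:
    """Nonnegative integer flower x bee visit-count matrix for one bin."""

    counts: np.ndarray
    row_labels: tuple[str, ...]  # flowers
    col_labels: tuple[str, ...]  # bees
    bin_index: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match counts shape")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_bees(self) -> int:
        return len(self.col_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "flower_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "VisitationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=int), tuple(df.index.astype(str)), tuple(df.columns.astype(str)))


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def read_visit_log(
    path,
    schema_map: Mapping[str, str] | None = None,
    flowers: Sequence[str] | None = None,
) -> VisitLog:
    """Read and validate a visit-log CSV.

    Parameters
    ----------
    path :
        CSV file with a header row.
    schema_map :
        Optional mapping from canonical column names (``day``, ``bee_id``,
        ``flower_id``, ``t_arrival_s``, ``t_departure_s``, ``fed``,
        ``bout_id``) to the column names used in the file.
    flowers :
        The declared flower set. When omitted it is inferred from the data
        (sorted unique flower ids); any flower id outside a declared set is
        a validation error.

    Returns
    -------
    VisitLog sorted by ``(day, t_arrival_s)``.
    """
    raw = pd.read_csv(path)
    schema_map = dict(schema_map or {})
    rename = {schema_map.get(c, c): c for c in VISIT_COLUMNS if schema_map.get(c, c) in raw.columns}
    df = raw.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "fed" not in df.columns:
        df["fed"] = True
    if "bout_id" not in df.columns:
        df["bout_id"] = pd.NA

    df = df[VISIT_COLUMNS].copy()
    df["day"] = df["day"].astype(int)
    df["bee_id"] = df["bee_id"].astype(str)
    df["flower_id"] = df["flower_id"].astype(str)
    df["t_arrival_s"] = df["t_arrival_s"].astype(float)
    df["t_departure_s"] = df["t_departure_s"].astype(float)
    df["fed"] = df["fed"].astype(bool)

    return _validate(df, flowers)


def _validate(df: pd.DataFrame, flowers: Sequence[str] | None) -> VisitLog:
    bad = df.index[df["t_departure_s"] < df["t_arrival_s"]]
    if len(bad):
        raise ValidationError(f"t_departure_s < t_arrival_s on row(s) {list(bad)}")
    bad = df.index[df["day"] < 1]
    if len(bad):
        raise ValidationError(f"day < 1 on row(s) {list(bad)}")
    if flowers is None:
        flowers = tuple(sorted(df["flower_id"].unique()))
    else:
        flowers = tuple(str(f) for f in flowers)
        unknown = set(df["flower_id"]) - set(flowers)
        if unknown:
            rows = df.index[df["flower_id"].isin(unknown)]
            raise ValidationError(f"unknown flower id(s) {sorted(unknown)} on row(s) {list(rows)}")
    df = df.sort_values(["day", "t_arrival_s"], kind="mergesort").reset_index(drop=True)
    log = VisitLog(df, flowers)
    logger.info(
        "read %d visits, %d bees, %d flowers", len(df), df["bee_id"].nunique(), len(flowers)
    )
    return log


def make_visit_log(df: pd.DataFrame, flowers: Sequence[str] | None = None) -> VisitLog:
    """Validate an in-memory DataFrame as a VisitLog (same contract as
    :func:`read_visit_log`)."""
    df = df.copy()
    for c in ("fed", "bout_id"):
        if c not in df.columns:
            df[c] = True if c == "fed" else pd.NA
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return _validate(df[VISIT_COLUMNS], flowers)


def write_visit_log(log: VisitLog, path) -> None:
    log.visits.to_csv(path, index=False)


def read_nest_events(path) -> pd.DataFrame:
    """Read a nest-entrance event CSV: ``bee_id, day, t_s, direction``."""
    df = pd.read_csv(path)
    missing = [c for c in ("bee_id", "day", "t_s", "direction") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if not df["direction"].isin(["exit", "entry"]).all():
        raise ValidationError("direction must be 'exit' or 'entry'")
    df["bee_id"] = df["bee_id"].astype(str)
    return df.sort_values(["bee_id", "day", "t_s"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# bouts
# ---------------------------------------------------------------------------

def segment_bouts(
    log: VisitLog,
    nest_events: pd.DataFrame | None = None,
    gap_threshold: float = 300.0,
) -> list[ForagingBout]:
    """Partition each bee's visits into foraging bouts.

    Precedence of evidence: an explicit ``bout_id`` column wins; otherwise
    nest exit/entry intervals are used when supplied; otherwise a new bout
    starts whenever the gap between a departure and the next arrival exceeds
    ``gap_threshold`` seconds (and at every day boundary).

    Bout start/end times are the nest exit/entry times when nest events are
    available, else the first arrival / last departure of the bout's visits.
    Per-bee bout indices are contiguous from 1 in time order.
    """
    if len(log) == 0:
        return []
    df = log.visits
    bouts: list[ForagingBout] = []
    for bee, sub in df.groupby("bee_id", sort=True):
        sub = sub.sort_values(["day", "t_arrival_s"], kind="mergesort")
        if log.has_bout_ids:
            groups = _groups_from_bout_ids(sub)
        elif nest_events is not None:
            groups = _groups_from_nest_events(sub, nest_events[nest_events["bee_id"] == bee])
        else:
            groups = _groups_from_gaps(sub, gap_threshold)
        for idx, (day, t0, t1, vis) in enumerate(groups, start=1):
            bouts.append(ForagingBout(str(bee), idx, int(day), float(t0), float(t1), vis))
    logger.info("segmented %d bouts for %d bees", len(bouts), df["bee_id"].nunique())
    return bouts


def _groups_from_bout_ids(sub: pd.DataFrame):
    out = []
    for (day, _bid), vis in sub.groupby(["day", "bout_id"], sort=True):
        out.append((day, vis["t_arrival_s"].min(), vis["t_departure_s"].max(), vis.reset_index(drop=True)))
    out.sort(key=lambda g: (g[0], g[1]))
    return out


def _groups_from_gaps(sub: pd.DataFrame, gap_threshold: float):
    out = []
    for day, dsub in sub.groupby("day", sort=True):
        arr = dsub["t_arrival_s"].to_numpy()
        dep = dsub["t_departure_s"].to_numpy()
        new_bout = np.ones(len(dsub), dtype=bool)
        new_bout[1:] = (arr[1:] - dep[:-1]) > gap_threshold
        ids = np.cumsum(new_bout)
        for _k, vis in dsub.groupby(ids, sort=True):
            out.append((day, vis["t_arrival_s"].min(), vis["t_departure_s"].max(), vis.reset_index(drop=True)))
    return out


def _groups_from_nest_events(sub: pd.DataFrame, events: pd.DataFrame):
    out = []
    for day, dsub in sub.groupby("day", sort=True):
        ev = events[events["day"] == day].sort_values("t_s")
        intervals: list[tuple[float, float]] = []
        t_exit = None
        for _, row in ev.iterrows():
            if row["direction"] == "exit":
                t_exit = row["t_s"]
            elif t_exit is not None:
                intervals.append((t_exit, row["t_s"]))
                t_exit = None
        if t_exit is not None:  # open-ended final trip
            intervals.append((t_exit, np.inf))
        if not intervals:
            warnings.warn(f"no nest intervals for bee on day {day}; treating day as one bout")
            out.append((day, dsub["t_arrival_s"].min(), dsub["t_departure_s"].max(), dsub.reset_index(drop=True)))
            continue
        assigned = np.empty(len(dsub), dtype=int)
        for i, t in enumerate(dsub["t_arrival_s"].to_numpy()):
            hit = [k for k, (a, b) in enumerate(intervals) if a <= t <= b]
            if hit:
                assigned[i] = hit[0]
            else:
                mids = [min(abs(t - a), abs(t - b)) for a, b in intervals]
                assigned[i] = int(np.argmin(mids))
                warnings.warn(f"visit at t={t} (day {day}) outside nest intervals; assigned to nearest")
        for k in sorted(set(assigned)):
            vis = dsub.iloc[assigned == k]
            a, b = intervals[k]
            b = vis["t_departure_s"].max() if not np.isfinite(b) else b
            out.append((day, a, b, vis.reset_index(drop=True)))
    return out


# ---------------------------------------------------------------------------
# motivated-bee filter
# ---------------------------------------------------------------------------

def filter_motivated(log: VisitLog, min_visits: int = 21) -> VisitLog:
    """Retain only motivated bees: total visits strictly greater than
    ``min_visits - 1`` (default: more than 20 visits over the whole study)."""
    totals = log.per_bee_totals()
    keep = totals.index[totals >= min_visits]
    if len(keep) == 0:
        warnings.warn("no bee passed the motivated-forager filter; empty log")
    out = log.visits[log.visits["bee_id"].isin(keep)].reset_index(drop=True)
    logger.info("motivated filter: retained %d of %d bees", len(keep), len(totals))
    return VisitLog(out, log.flowers)


# ---------------------------------------------------------------------------
# eight-bout bins
# ---------------------------------------------------------------------------

def bin_by_bouts(
    bouts: Iterable[ForagingBout],
    bouts_per_bin: int = 8,
    merge_trailing: bool = True,
) -> list[TimeBin]:
    """Cut each day into intervals, each closing when the first bee completes
    ``bouts_per_bin`` bouts since the interval opened.

    Bout completions (nest-return times) are scanned in chronological order
    within each day; per-bee counters reset at each bin close. A trailing
    partial period at day end is merged into that day's last closed bin
    (``merged_tail`` flag) or kept as its own partial bin when
    ``merge_trailing`` is false. If no bee ever reaches the quota in a day
    the whole day becomes one flagged bin.
    """
    bouts = sorted(bouts, key=lambda b: (b.day, b.t_end, b.bee_id))
    bins: list[TimeBin] = []
    for day in sorted({b.day for b in bouts}):
        day_bouts = [b for b in bouts if b.day == day]
        day_bins: list[TimeBin] = []
        open_start = min(b.t_start for b in day_bouts)
        counters: dict[str, int] = {}
        current: list[ForagingBout] = []
        for b in day_bouts:
            current.append(b)
            counters[b.bee_id] = counters.get(b.bee_id, 0) + 1
            if counters[b.bee_id] == bouts_per_bin:
                day_bins.append(TimeBin(0, day, open_start, b.t_end, current))
                open_start = b.t_end
                counters = {}
                current = []
        if current:
            if day_bins and merge_trailing:
                tail_end = max(b.t_end for b in current)
                last = day_bins[-1]
                last.bouts.extend(current)
                last.t_end = max(last.t_end, tail_end)
                last.merged_tail = True
            elif day_bins:
                day_bins.append(TimeBin(0, day, open_start, max(b.t_end for b in current), current))
                day_bins[-1].merged_tail = True
            else:
                warnings.warn(f"day {day}: no bee completed {bouts_per_bin} bouts; whole-day bin")
                day_bins.append(
                    TimeBin(0, day, open_start, max(b.t_end for b in current), current, whole_day=True)
                )
        bins.extend(day_bins)
    for i, bn in enumerate(bins, start=1):
        bn.index = i
    logger.info("built %d bins over %d days", len(bins), len({b.day for b in bins}))
    return bins


def build_visitation_matrix(
    time_bin: TimeBin, flower_set: Sequence[str], bin_index: int | None = None
) -> VisitationMatrix:
    """Tabulate visits in one bin into a flower x bee count matrix.

    All declared flowers are kept as rows even when unvisited; bees with zero
    visits inside the bin contribute no column.
    """
    if not time_bin.bouts:
        raise ValueError(f"bin {time_bin.index} is empty")
    vis = pd.concat([b.visits for b in time_bin.bouts], ignore_index=True)
    if len(vis) == 0:
        raise ValueError(f"bin {time_bin.index} contains no visits")
    flowers = [str(f) for f in flower_set]
    bees = sorted(vis["bee_id"].unique())
    tab = pd.crosstab(vis["flower_id"], vis["bee_id"]).reindex(
        index=flowers, columns=bees, fill_value=0
    )
    return VisitationMatrix(
        tab.to_numpy(dtype=int),
        tuple(flowers),
        tuple(bees),
        bin_index=time_bin.index if bin_index is None else bin_index,
    )
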