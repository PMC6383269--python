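"""Synthetic foraging data with known ground truth.

Two generators feed the test-bed:

* :func:`plant_modular_log` — a fast sampler that plants bee-flower module
  structure directly: each visit of a bee targets a flower inside its
  planted module with probability ``fidelity``, else uniformly outside it.
  Bout and day scaffolding is laid out on a regular schedule so that bout
  segmentation and eight-bout binning operate exactly as on real logs.

* :func:`simulate_colony` — a spatially explicit, event-driven flight-cage
  simulation: ten artificial flowers on a decagon with 9-m nearest-neighbour
  spacing, feeding cups of 40 uL refilling at 3.3 uL/min (primed with 20 uL
  at session start), bees that drain cups at ~5 uL/s until their crop is
  full and then return to the nest, movement restricted to flowers within
  visual detection range (9.6 m) of the current position, and two-bee
  encounters on occupied flowers resolved by displacement probabilities
  conditioned on cup fullness. Bees avoid, in their next bout, flowers from
  which they were displaced.

Both generators are fully deterministic under their seed and emit logs in
the canonical visit-log / interaction-log schemas.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactions import InteractionEvent
from .visitlog import VisitLog, make_visit_log

__all__ = ["SimConfig", "decagon_coordinates", "plant_modular_log", "simulate_colony", "cup_volume_after"]

SESSION_LENGTH_S = 6 * 3600.0


def decagon_coordinates(nearest_neighbour_m: float = 9.0) -> np.ndarray:
    """(10, 2) coordinates of a regular decagon with the given side length,
    centred at the origin, F1 at angle 0."""
    radius = nearest_neighbour_m / (2 * math.sin(math.pi / 10))
    ang = 2 * math.pi * np.arange(10) / 10
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


def default_modules(n_bees: int, n_flowers: int, n_modules: int = 2) -> dict[int, list[int]]:
    """Split flowers into contiguous blocks and deal bees round-robin."""
    flowers = np.array_split(np.arange(n_flowers), n_modules)
    return {b: list(flowers[b % n_modules]) for b in range(n_bees)}


@dataclass
class SimConfig:
    """Flight-cage simulation parameters (units in field names' docs).

    Rates and geometry default to the experimental apparatus: cups of 40 uL
    refilled at 3.3 uL/min, primed with 20 uL, drained at ~5 uL/s; flowers
    on the 9-m decagon with 9.6-m visual detection range. Behavioural
    parameters (flight speed, crop capacity, nest turnaround, displacement
    probabilities, module fidelity) are free knobs with defaults chosen to
    put the emergent bout statistics in a realistic regime.
    """

    flower_coordinates: np.ndarray = None  # metres; default decagon
    nest_position: np.ndarray = None  # metres; default 12.5 m outward of F1
    n_bees: int = 10
    refill_rate: float = 3.3 / 60.0  # uL/s (3.3 uL/min)
    cup_capacity: float = 40.0  # uL
    initial_cup: float = 20.0  # uL primed before release
    feed_rate: float = 5.0  # uL/s
    crop_capacity: float = 150.0  # uL
    flight_speed: float = 1.0  # m/s
    detection_radius: float = 9.6  # m
    fidelity: float = 0.9  # probability a choice stays within the bee's module
    module_assignment: dict[int, list[int]] = None
    displacement_prob_full: float = 0.2  # P(resident leaves | cup holds reward)
    displacement_prob_empty: float = 0.7  # P(resident leaves | cup drained)
    revisit_suppression: float = 0.8  # weight cut on flowers lost last bout
    exploration_prob: float = 0.05  # long-range jump past detection limit
    contact_prob: float = 0.7  # encounters involving physical contact
    handling_time_s: float = 5.0  # mean lingering on the flower after the cup is drained
    nest_turnaround_s: float = 900.0  # mean unloading/rest time in the nest
    max_bout_s: float = 1500.0  # hard cap before returning with a partial crop
    give_up_after: int = 3  # consecutive near-empty visits before heading home
    give_up_low_uL: float = 2.0  # a visit yielding less than this counts as near-empty
    session_length: float = SESSION_LENGTH_S
    n_days: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flower_coordinates is None:
            self.flower_coordinates = decagon_coordinates()
        self.flower_coordinates = np.asarray(self.flower_coordinates, dtype=float)
        if self.nest_position is None:
            f1 = self.flower_coordinates[0]
            self.nest_position = f1 + 12.5 * f1 / np.linalg.norm(f1)
        self.nest_position = np.asarray(self.nest_position, dtype=float)
        if self.module_assignment is None:
            self.module_assignment = default_modules(self.n_bees, len(self.flower_coordinates))
        for name in ("refill_rate", "cup_capacity", "feed_rate", "crop_capacity",
                     "flight_speed", "detection_radius", "session_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"non-physical config: {name} must be positive")
        if self.initial_cup < 0 or self.initial_cup > self.cup_capacity:
            raise ValueError("initial_cup must lie in [0, cup_capacity]")
        for name in ("fidelity", "displacement_prob_full", "displacement_prob_empty",
                     "revisit_suppression", "exploration_prob", "contact_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for b, fls in self.module_assignment.items():
            if len(fls) == 0:
                raise ValueError(f"empty module for bee {b}")

    @property
    def n_flowers(self) -> int:
        return len(self.flower_coordinates)


def cup_volume_after(t_s: float, start_volume: float = 0.0,
                     refill_rate: float = 3.3 / 60.0, cup_capacity: float = 40.0) -> float:
    """Cup volume after ``t_s`` seconds of undisturbed secretion."""
    return min(cup_capacity, start_volume + refill_rate * t_s)


# ---------------------------------------------------------------------------
# planted-module sampler
# ---------------------------------------------------------------------------

def plant_modular_log(
    n_bees: int = 10,
    n_flowers: int = 10,
    modules: dict[int, list[int]] | None = None,
    fidelity: float = 0.9,
    mean_visits_per_bout: float = 7.0,
    n_bouts_per_day: int = 18,
    n_days: int = 5,
    session_length: float = SESSION_LENGTH_S,
    seed: int = 0,
) -> tuple[VisitLog, dict]:
    """Sample a visit log with planted module structure.

    Each bee owns a planted flower subset (``modules``, flower indices per
    bee; default two balanced modules). Every visit targets a flower drawn
    uniformly from the bee's module with probability ``fidelity``, else
    uniformly from the remaining flowers. Visits per bout are
    1 + Poisson(``mean_visits_per_bout`` - 1). Bouts are laid out on a
    regular within-day schedule (staggered across bees) so completions
    interleave the way binning expects.

    Returns the log and a ground-truth record ``{"modules": ..., "fidelity": ...}``.
    """
    if mean_visits_per_bout <= 1:
        raise ValueError("mean_visits_per_bout must exceed 1")
    rng = np.random.default_rng(seed)
    if modules is None:
        modules = default_modules(n_bees, n_flowers)
    for b, fls in modules.items():
        if len(fls) == 0:
            raise ValueError(f"empty module for bee {b}")
        if not set(fls) <= set(range(n_flowers)):
            raise ValueError("modules must partition the declared flower set")
    flowers = [f"F{i + 1}" for i in range(n_flowers)]
    bees = [f"B{b + 1:02d}" for b in range(n_bees)]
    bout_spacing = session_length / n_bouts_per_day
    rows = []
    for day in range(1, n_days + 1):
        for b in range(n_bees):
            own = np.array(modules[b])
            other = np.array([f for f in range(n_flowers) if f not in set(modules[b])])
            offset = rng.uniform(0, 60) + b * 17.0  # stagger bout completions across bees
            for bout in range(1, n_bouts_per_day + 1):
                t = (bout - 1) * bout_spacing + offset
                n_vis = 1 + rng.poisson(mean_visits_per_bout - 1)
                for _v in range(n_vis):
                    if len(other) == 0 or rng.random() < fidelity:
                        fl = int(rng.choice(own))
                    else:
                        fl = int(rng.choice(other))
                    dur = rng.uniform(2, 8)
                    rows.append(
                        {
                            "day": day,
                            "bee_id": bees[b],
                            "flower_id": flowers[fl],
                            "t_arrival_s": round(t, 2),
                            "t_departure_s": round(t + dur, 2),
                            "fed": True,
                            "bout_id": bout,
                        }
                    )
                    t += dur + rng.uniform(5, 15)
    df = pd.DataFrame(rows)
    log = make_visit_log(df, flowers)
    truth = {
        "modules": {bees[b]: [flowers[f] for f in fls] for b, fls in modules.items()},
        "fidelity": fidelity,
        "seed": seed,
    }
    return log, truth


# ---------------------------------------------------------------------------
# flight-cage simulator
# ---------------------------------------------------------------------------

@dataclass
class _Flower:
    vol: float
    last_update: float
    secreted: float = 0.0
    consumed: float = 0.0
    initial: float = 0.0
    occupants: dict = field(default_factory=dict)  # bee -> dict(feed_start, planned, arrival)

    def refill_to(self, now: float, rate: float, cap: float) -> None:
        dt = now - self.last_update
        if dt > 0:
            add = min(max(cap - self.vol, 0.0), rate * dt)
            self.vol += add
            self.secreted += add
            self.last_update = now

    def take(self, amount: float) -> None:
        self.vol -= amount
        self.consumed += amount

    def check_conservation(self) -> float:
        return abs(self.initial + self.secreted - self.consumed - self.vol)


@dataclass
class _Bee:
    idx: int
    crop: float = 0.0
    bout: int = 0
    bout_start: float = 0.0
    lost_last_bout: set = field(default_factory=set)
    lost_this_bout: set = field(default_factory=set)
    visited_this_bout: list = field(default_factory=list)
    empty_streak: int = 0


def simulate_colony(config: SimConfig) -> tuple[VisitLog, list[InteractionEvent], dict]:
    """Run the event-driven flight-cage simulation.

    Returns ``(visit_log, interaction_events, ground_truth)``. The ground
    truth carries the planted module assignment, the per-flower nectar
    ledger (largest conservation residual observed at any event step), and
    the displacement history, for recovery and invariant tests.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    coords = cfg.flower_coordinates
    nF = cfg.n_flowers
    flower_ids = [f"F{i + 1}" for i in range(nF)]
    bee_ids = [f"B{b + 1:02d}" for b in range(cfg.n_bees)]
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    nest_dist = np.linalg.norm(coords - cfg.nest_position, axis=1)

    visits: list[dict] = []
    events: list[InteractionEvent] = []
    displacements: list[dict] = []
    max_resid = 0.0

    for day in range(1, cfg.n_days + 1):
        flowers = [_Flower(vol=cfg.initial_cup, last_update=0.0, initial=cfg.initial_cup) for _ in range(nF)]
        bees = [_Bee(b) for b in range(cfg.n_bees)]
        heap: list = []
        seq = 0

        def push(t: float, kind: str, *args) -> None:
            nonlocal seq
            heapq.heappush(heap, (t, seq, kind, args))
            seq += 1

        def choose_flower(bee: _Bee, at: int | None) -> int | None:
            """Next target from current position (flower index or nest=None)."""
            if at is None:
                cand = np.arange(nF)
            else:
                near = dist[at] <= cfg.detection_radius
                near[at] = False
                if rng.random() < cfg.exploration_prob or not near.any():
                    cand = np.array([f for f in range(nF) if f != at])
                else:
                    cand = np.flatnonzero(near)
            own = set(cfg.module_assignment[bee.idx])
            w = np.array([cfg.fidelity if f in own else 1 - cfg.fidelity for f in cand], dtype=float)
            for i, f in enumerate(cand):
                if f in bee.lost_last_bout:
                    w[i] *= 1 - cfg.revisit_suppression
            if w.sum() <= 0:
                w = np.ones(len(cand))
            return int(rng.choice(cand, p=w / w.sum()))

        def record_visit(bee: _Bee, fl: int, t_arr: float, t_dep: float, amount: float) -> None:
            visits.append(
                {
                    "day": day,
                    "bee_id": bee_ids[bee.idx],
                    "flower_id": flower_ids[fl],
                    "t_arrival_s": t_arr,
                    "t_departure_s": t_dep,
                    "fed": amount > 0,
                    "bout_id": bee.bout,
                }
            )
            bee.visited_this_bout.append(fl)

        def go_home(bee: _Bee, t: float, frm: int) -> None:
            push(t + nest_dist[frm] / cfg.flight_speed, "home", bee.idx)

        def next_move(bee: _Bee, t: float, at: int) -> None:
            if (
                bee.crop >= cfg.crop_capacity - 1e-9
                or t - bee.bout_start > cfg.max_bout_s
                or bee.empty_streak >= cfg.give_up_after
            ):
                go_home(bee, t, at)
                return
            target = choose_flower(bee, at)
            push(t + dist[at, target] / cfg.flight_speed, "arrive", bee.idx, target)

        def finish_feeding(bee: _Bee, fl: int, t: float, interrupted_at: float | None = None) -> float:
            """Settle a feeding episode ending at t; returns amount drunk."""
            f = flowers[fl]
            info = f.occupants.pop(bee_ids[bee.idx])
            dur = (interrupted_at if interrupted_at is not None else t) - info["feed_start"]
            amount = min(info["planned"], max(dur, 0.0) * cfg.feed_rate)
            f.refill_to(t, cfg.refill_rate, cfg.cup_capacity)
            amount = min(amount, f.vol)
            f.take(amount)
            bee.crop += amount
            bee.empty_streak = 0 if amount >= cfg.give_up_low_uL else bee.empty_streak + 1
            record_visit(bee, fl, info["arrival"], t, amount)
            return amount

        # staggered release at session start
        for bee in bees:
            push(rng.exponential(120.0), "depart", bee.idx)

        while heap:
            t, _s, kind, args = heapq.heappop(heap)
            if t > cfg.session_length:
                break
            if kind == "depart":
                bee = bees[args[0]]
                bee.bout += 1
                bee.bout_start = t
                bee.lost_last_bout = bee.lost_this_bout
                bee.lost_this_bout = set()
                bee.visited_this_bout = []
                bee.crop = 0.0
                bee.empty_streak = 0
                target = choose_flower(bee, None)
                push(t + nest_dist[target] / cfg.flight_speed, "arrive", bee.idx, target)

            elif kind == "home":
                bee = bees[args[0]]
                push(t + 60.0 + rng.exponential(cfg.nest_turnaround_s), "depart", bee.idx)

            elif kind == "arrive":
                bee, fl = bees[args[0]], args[1]
                f = flowers[fl]
                f.refill_to(t, cfg.refill_rate, cfg.cup_capacity)
                if len(f.occupants) >= 2:
                    # crowded flower: veer off without landing
                    next_move(bee, t, fl)
                elif len(f.occupants) == 1:
                    res_id = next(iter(f.occupants))
                    res = bees[bee_ids.index(res_id)]
                    info = f.occupants[res_id]
                    feed_time = t - info["feed_start"]
                    has_reward = f.vol - cfg.feed_rate * feed_time > 1.0
                    p_leave = cfg.displacement_prob_full if has_reward else cfg.displacement_prob_empty
                    resident_leaves = rng.random() < p_leave
                    overlap = 0.5 + rng.exponential(2.0)
                    t_dep = min(t + overlap, cfg.session_length)
                    events.append(
                        InteractionEvent(
                            flower_id=flower_ids[fl],
                            resident_id=res_id,
                            joiner_id=bee_ids[bee.idx],
                            day=day,
                            t_resident_arrival=info["arrival"],
                            t_joiner_arrival=t,
                            t_first_departure=t_dep,
                            first_leaver_id=res_id if resident_leaves else bee_ids[bee.idx],
                            contact=bool(rng.random() < cfg.contact_prob),
                            resident_feed_time=feed_time,
                        )
                    )
                    if resident_leaves:
                        finish_feeding(res, fl, t_dep, interrupted_at=t)
                        res.lost_this_bout.add(fl)
                        displacements.append({"day": day, "bee_id": res_id, "flower_id": flower_ids[fl], "t_s": t_dep})
                        next_move(res, t_dep, fl)
                        # joiner takes over the (possibly drained) cup
                        f.refill_to(t_dep, cfg.refill_rate, cfg.cup_capacity)
                        drink = min(f.vol, cfg.crop_capacity - bee.crop)
                        f.occupants[bee_ids[bee.idx]] = {"feed_start": t_dep, "planned": drink, "arrival": t, "token": seq}
                        stay = max(drink / cfg.feed_rate, 1.0) + rng.exponential(cfg.handling_time_s)
                        push(t_dep + stay, "finish", bee.idx, fl, seq)
                    else:
                        # joiner lands, contests, leaves empty-handed
                        record_visit(bee, fl, t, t_dep, 0.0)
                        bee.empty_streak += 1
                        bee.lost_this_bout.add(fl)
                        displacements.append({"day": day, "bee_id": bee_ids[bee.idx], "flower_id": flower_ids[fl], "t_s": t_dep})
                        next_move(bee, t_dep, fl)
                else:
                    drink = min(f.vol, cfg.crop_capacity - bee.crop)
                    f.occupants[bee_ids[bee.idx]] = {"feed_start": t, "planned": drink, "arrival": t, "token": seq}
                    stay = max(drink / cfg.feed_rate, 1.0) + rng.exponential(cfg.handling_time_s)
                    push(t + stay, "finish", bee.idx, fl, seq)

            elif kind == "finish":
                bee, fl, token = bees[args[0]], args[1], args[2]
                info = flowers[fl].occupants.get(bee_ids[bee.idx])
                if info is None or info["token"] != token:
                    continue  # displaced earlier; episode already settled
                finish_feeding(bee, fl, t)
                max_resid = max(max_resid, flowers[fl].check_conservation())
                next_move(bee, t, fl)

        # close out any feeding episodes still open at session end
        for fl, f in enumerate(flowers):
            for bid in list(f.occupants):
                finish_feeding(bees[bee_ids.index(bid)], fl, cfg.session_length)
            max_resid = max(max_resid, f.check_conservation())

    df = pd.DataFrame(visits, columns=["day", "bee_id", "flower_id", "t_arrival_s", "t_departure_s", "fed", "bout_id"])
    log = make_visit_log(df, flower_ids)
    truth = {
        "modules": {bee_ids[b]: [flower_ids[f] for f in fls] for b, fls in cfg.module_assignment.items()},
        "fidelity": cfg.fidelity,
        "displacements": displacements,
        "max_conservation_residual_uL": max_resid,
        "seed": cfg.seed,
    }
    return log, events, truth
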