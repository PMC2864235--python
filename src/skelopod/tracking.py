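"""Backward-in-time clustering of activities into pseudopod lineages.

Pseudopod dynamics are modelled as a second-order autoregressive
process: position and angle change little between consecutive
activities of the same pseudopod, and when they do change the rate of
change tends to stay constant.  Because pseudopods split frequently,
activities are tracked *backwards* in time: walking from the last frame
to the first, each not-yet-assigned activity is scored against every
already-assigned activity up to ``T`` seconds later, and joins the
best-scoring pseudopod if that score is under ``dist_threshold`` —
otherwise it seeds a new pseudopod.  A split is recorded when the tails
of two tracks both lie within ``dist_threshold`` of the same earlier
activity: the lower-scoring track keeps continuity through the common
ancestor (it becomes the parent lineage) and the other track is marked
as originating from the split.

The distance score combines spatial and angular first/second-order
differences, weighted ``beta`` / ``1 - beta``, normalised by the cell
radius ``R``, and grows with the square root of the time gap:

    score = R * sqrt( [beta * (dS * dt)^2 / R^2
                       + (1-beta) * (dA * dt)^2] * (t2 - t1) / dt )

with ``dS``/``dA`` the spatial (px/s) and angular (rad/s) pair costs,
``dt`` the frame interval and ``R`` in pixels.  The overall factor R
puts the score in pixels, commensurate with the threshold (a fraction
of the cell perimeter); the angular term R*dA*dt is the membrane arc
length swept by the angular change.  The exact functional form is
isolated in :func:`score_from_deltas` so alternatives can be swapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import Activity


@dataclass
class TrackingConfig:
    """Backward-tracking parameters.

    ``T`` (s): maximum time gap between activities of one pseudopod;
    ``alpha``: weight of the first-order difference in the pair cost;
    ``beta``: weight of the spatial (vs angular) distance;
    ``R``: cell radius in pixels (5 um divided by the pixel size);
    ``dist_threshold`` (px): score threshold to join a pseudopod,
    1/10 of the cell perimeter.
    """

    T: float = 50.0
    alpha: float = 0.5
    beta: float = 0.5
    R: float = 25.0
    dist_threshold: float = 15.0

    def __post_init__(self) -> None:
        if self.T <= 0 or self.R <= 0 or self.dist_threshold <= 0:
            raise ValueError("T, R and dist_threshold must be > 0")
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1):
            raise ValueError("alpha and beta must lie in [0, 1]")


@dataclass
class Pseudopod:
    """Time-ordered activity history of a single pseudopod."""

    id: int
    activities: list[Activity] = field(default_factory=list)
    origin: str = "de_novo"  # or "split"
    parent_id: int | None = None
    split_events: list[tuple[float, int]] = field(default_factory=list)

    @property
    def t_start(self) -> float:
        return min(a.t for a in self.activities)

    @property
    def t_end(self) -> float:
        return max(a.t for a in self.activities)

    @property
    def n_activities(self) -> int:
        return len(self.activities)


def _wrap_deg(d: float) -> float:
    """Wrap an angle difference onto (-180, 180]."""
    d = (d + 180.0) % 360.0 - 180.0
    return 180.0 if d == -180.0 else d


def order_difference(d_prev, d_mid, d_next, dt1: float, dt2: float,
                     angular: bool = False) -> tuple[float, float]:
    """First- and second-order differences of three measurements.

    ``d_prev``, ``d_mid``, ``d_next`` are measurements at t - dt2, t and
    t + dt1; scalars, angles (degrees, differenced on the circle) or 2-D
    points.  Returns (|rate|, |change of rate|), the discrete analogues
    of the first and second time derivatives.
    """
    if dt1 <= 0 or dt2 <= 0:
        raise ValueError("dt1 and dt2 must be > 0")
    if angular:
        v1 = _wrap_deg(float(d_next) - float(d_mid)) / dt1
        v2 = _wrap_deg(float(d_mid) - float(d_prev)) / dt2
        return abs(v1), abs(v1 - v2)
    a, m, n = (np.atleast_1d(np.asarray(v, dtype=float))
               for v in (d_prev, d_mid, d_next))
    v1 = (n - m) / dt1
    v2 = (m - a) / dt2
    return float(np.linalg.norm(v1)), float(np.linalg.norm(v1 - v2))


def _rate(a, b, dt: float, angular: bool) -> float:
    if angular:
        return abs(_wrap_deg(float(b) - float(a))) / dt
    d = np.asarray(b, float) - np.asarray(a, float)
    return float(np.linalg.norm(d)) / dt


def pair_cost(values: tuple, times: tuple, alpha: float,
              angular: bool = False) -> float:
    """AR(2) pair cost: alpha * first-order + (1-alpha) * second-order.

    The first-order difference is always taken on the pair being scored
    (the earlier two points), so the cost penalises the jump of the
    candidate link itself; with a third (already linked, later) point
    the second-order difference adds the change-of-rate penalty.  With
    only two points the cost is just the first-order difference.
    """
    if len(values) == 3:
        t1, t2, t3 = times
        first = _rate(values[0], values[1], t2 - t1, angular)
        _, second = order_difference(values[0], values[1], values[2],
                                     dt1=t3 - t2, dt2=t2 - t1,
                                     angular=angular)
        return alpha * first + (1.0 - alpha) * second
    if len(values) == 2:
        t1, t2 = times
        return _rate(values[0], values[1], t2 - t1, angular)
    raise ValueError("pair_cost needs 2 or 3 data points")


def score_from_deltas(d_spatial: float, d_angular_deg: float, time_gap: float,
                      cfg: TrackingConfig, frame_interval: float) -> float:
    """Distance score from precomputed pair costs (per-second rates).

    The rate costs are integrated over the link's time gap (giving the
    px / radian change of the link itself) before the time factor
    f = (t2 - t1)/frame_interval is applied, so that, all else fixed,
    a link over twice the time gap scores sqrt(2) higher — activities
    far apart in time are less likely to share a pseudopod.  Monotone
    increasing in the spatial gap, the angular gap and the time gap.
    """
    dsp = d_spatial * time_gap                      # px over the link
    dang = math.radians(d_angular_deg) * time_gap   # rad over the link
    f_t = time_gap / frame_interval                 # frames
    return cfg.R * math.sqrt(
        (cfg.beta * (dsp / cfg.R) ** 2 + (1.0 - cfg.beta) * dang ** 2) * f_t)


def distance_score(p1: Activity, p2: Activity, p3: Activity | None,
                   cfg: TrackingConfig, frame_interval: float = 1.0) -> float:
    """Distance score between an unassigned p1 and an assigned later p2.

    ``p3`` is the activity already assigned after p2 in p2's pseudopod
    (if any); with it, second-order differences enter the pair costs.
    """
    if p2.t <= p1.t:
        raise ValueError("p2 must be later than p1")
    if p3 is not None:
        if p3.t <= p2.t:
            raise ValueError("p3 must be later than p2")
        values_sp = ((p1.y, p1.x), (p2.y, p2.x), (p3.y, p3.x))
        values_an = (p1.theta, p2.theta, p3.theta)
        times = (p1.t, p2.t, p3.t)
    else:
        values_sp = ((p1.y, p1.x), (p2.y, p2.x))
        values_an = (p1.theta, p2.theta)
        times = (p1.t, p2.t)
    dsp = pair_cost(values_sp, times, cfg.alpha)
    dang = pair_cost(values_an, times, cfg.alpha, angular=True)
    return score_from_deltas(dsp, dang, p2.t - p1.t, cfg, frame_interval)


def backward_track(activities: list[Activity], cfg: TrackingConfig,
                   frame_interval: float = 1.0) -> list[Pseudopod]:
    """Cluster detected activities into pseudopod lineages.

    Frames are processed from last to first; within a frame activities
    are processed in order of |theta| (deterministic).  Ties in the
    minimal score are broken toward the candidate with the smaller time
    gap.  Each activity ends up in exactly one pseudopod.
    """
    if not activities:
        return []
    pods: list[Pseudopod] = []
    pod_of: dict[int, Pseudopod] = {}     # id(activity) -> pseudopod
    succ: dict[int, Activity] = {}        # id(activity) -> next later activity
    tail: dict[int, Activity] = {}        # pseudopod id -> earliest activity
    # provisional split marks: child pod id -> (parent pod id, time)
    split_mark: dict[int, tuple[int, float]] = {}

    frames = sorted({a.frame_index for a in activities}, reverse=True)
    by_frame = {f: sorted([a for a in activities if a.frame_index == f],
                          key=lambda a: (abs(a.theta), a.theta, a.x, a.y))
                for f in frames}
    assigned: list[Activity] = []

    def _score(a: Activity, b: Activity) -> float:
        return distance_score(a, b, succ.get(id(b)), cfg, frame_interval)

    for f in frames:
        for a in by_frame[f]:
            # a will become the new earliest member of the pod it joins,
            # so only pods whose current tail is strictly later qualify
            cands = [b for b in assigned
                     if 0 < b.t - a.t <= cfg.T
                     and tail[pod_of[id(b)].id].t > a.t]
            best, best_key = None, None
            for b in cands:
                key = (_score(a, b), b.t - a.t, pod_of[id(b)].id)
                if best_key is None or key < best_key:
                    best, best_key = b, key
            if best is not None and best_key[0] < cfg.dist_threshold:
                # extend that track backward: a becomes its earliest member
                pod = pod_of[id(best)]
                pod.activities.insert(0, a)
                succ[id(a)] = tail[pod.id]
                tail[pod.id] = a
                pod_of[id(a)] = pod
                # pod reaching strictly earlier than a recorded split mark
                # means it existed before the claimed split: retract it
                if pod.id in split_mark and a.t < split_mark[pod.id][1]:
                    par_id, t_s = split_mark.pop(pod.id)
                    parent = next(p for p in pods if p.id == par_id)
                    parent.split_events = [
                        e for e in parent.split_events if e != (t_s, pod.id)]
                    pod.origin = "de_novo"
                    pod.parent_id = None
                # other tracks whose tail also claims `a` split off here:
                # the lower-scoring track (pod) keeps continuity through a
                for q in pods:
                    if q.id == pod.id or q.id in split_mark:
                        continue
                    qt = tail[q.id]
                    if not (0 < qt.t - a.t <= cfg.T):
                        continue
                    if _score(a, qt) < cfg.dist_threshold:
                        split_mark[q.id] = (pod.id, a.t)
                        q.origin = "split"
                        q.parent_id = pod.id
                        pod.split_events.append((a.t, q.id))
            else:
                pod_new = Pseudopod(id=len(pods), activities=[a])
                pods.append(pod_new)
                tail[pod_new.id] = a
                pod_of[id(a)] = pod_new
            assigned.append(a)

    for pod in pods:
        pod.activities.sort(key=lambda x: x.t)
        pod.split_events.sort()
        for a in pod.activities:
            a.pseudopod_id = pod.id
    return pods


def pseudopods_to_dataframe(pods: list[Pseudopod]) -> pd.DataFrame:
    cols = ["pseudopod_id", "origin", "parent_id", "t_start", "t_end",
            "n_activities", "n_splits"]
    rows = [{"pseudopod_id": p.id, "origin": p.origin,
             "parent_id": -1 if p.parent_id is None else p.parent_id,
             "t_start": p.t_start, "t_end": p.t_end,
             "n_activities": p.n_activities,
             "n_splits": len(p.split_events)} for p in pods]
    return pd.DataFrame(rows, columns=cols)
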