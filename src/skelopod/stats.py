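"""Per-pseudopod and per-cell morphodynamic statistics.

Quantities follow the standard catalogue for pseudopod behaviour:
lifetime, protrusion/retraction ratios and speeds, persistence measures
(longest consecutive run of one activity kind over the lifetime), angle
dynamics (starting/mean angle, linear drift rate, de-trended variance),
and splitting behaviour; cell-level summaries aggregate them and add
the time-averaged number of coexisting pseudopods, the fraction of
pseudopods born by splitting and the splitting rate.  A hierarchical
ranking orders pseudopods by activity count and selects the smallest
prefix covering a requested fraction of all activities, and protrusion
angle histograms are characterised by a least-squares Gaussian fit.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InsufficientData
from .tracking import Pseudopod


@dataclass
class PseudopodStats:
    pseudopod_id: int
    lifetime: float                 # s
    n_activities: int
    net_speed: float                # um/min (signed)
    protrusion_ratio: float
    retraction_ratio: float
    protrusion_speed: float         # um/min, 0 (flagged) if no protrusions
    retraction_speed: float
    protrusion_persistence: float
    retraction_persistence: float
    state_persistence: float
    starting_angle: float           # deg
    mean_angle: float               # deg (circular mean)
    angle_rate: float               # deg/s, least-squares slope
    detrended_angle_variance: float  # deg^2
    origin: str
    n_splits: int
    has_protrusions: bool = True
    has_retractions: bool = True


@dataclass
class CellStats:
    n_pseudopods: int
    avg_n_pseudopods: float
    ratio_from_splitting: float
    avg_splitting_rate: float       # splits/min
    avg_protrusion_persistence: float
    avg_retraction_persistence: float
    avg_state_persistence: float
    avg_protrusion_speed: float
    avg_retraction_speed: float
    avg_net_speed: float

    def to_json_dict(self) -> dict:
        return asdict(self)


def _longest_run(kinds: list[str], which: set[str]) -> int:
    best = cur = 0
    for k in kinds:
        cur = cur + 1 if k in which else 0
        best = max(best, cur)
    return best


def _circular_mean_deg(angles: np.ndarray) -> float:
    rad = np.radians(angles)
    return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))


def _unwrap_deg(angles: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(np.radians(angles)))


def pseudopod_stats(p: Pseudopod, frame_interval: float,
                    pixel_size: float) -> PseudopodStats:
    """All per-pseudopod quantities in physical units.

    Lifetime is ``t_last - t_first + frame_interval`` (each activity
    represents one frame interval of membrane motion).  Speeds convert
    px/frame to um/min.  Persistences are the longest consecutive run
    of the given kind times the frame interval, divided by the
    lifetime; a single-activity pseudopod has persistence 1 by this
    definition.  The angle rate is the least-squares slope of the
    (unwrapped) activity angle against time, and the de-trended angle
    variance is the variance of the residuals about that line.
    """
    if not p.activities:
        raise ValueError("empty pseudopod")
    acts = sorted(p.activities, key=lambda a: a.t)
    kinds = [a.kind for a in acts]
    times = np.array([a.t for a in acts])
    lengths_px = np.array([a.length for a in acts])
    signed_px = np.array([a.signed_length for a in acts])
    angles = np.array([a.theta for a in acts])

    lifetime = float(times[-1] - times[0]) + frame_interval
    n_pro = kinds.count("protrusion")
    n_ret = kinds.count("retraction")
    n = len(acts)

    um_per_min = pixel_size * 60.0  # (px/s) -> um/min multiplier

    net_px = float(signed_px.sum())
    net_speed = net_px / lifetime * um_per_min

    pro_px = float(lengths_px[[k == "protrusion" for k in kinds]].sum())
    ret_px = float(lengths_px[[k == "retraction" for k in kinds]].sum())
    pro_speed = (pro_px / (n_pro * frame_interval) * um_per_min
                 if n_pro else 0.0)
    ret_speed = (ret_px / (n_ret * frame_interval) * um_per_min
                 if n_ret else 0.0)

    pro_pers = _longest_run(kinds, {"protrusion"}) * frame_interval / lifetime
    ret_pers = _longest_run(kinds, {"retraction"}) * frame_interval / lifetime
    state_pers = max(pro_pers, ret_pers)

    un = _unwrap_deg(angles)
    if n >= 2 and np.ptp(times) > 0:
        slope, intercept = np.polyfit(times, un, 1)
        resid = un - (slope * times + intercept)
        detrended_var = float(np.var(resid))
    else:
        slope, detrended_var = 0.0, 0.0

    return PseudopodStats(
        pseudopod_id=p.id, lifetime=lifetime, n_activities=n,
        net_speed=net_speed,
        protrusion_ratio=n_pro / n, retraction_ratio=n_ret / n,
        protrusion_speed=pro_speed, retraction_speed=ret_speed,
        protrusion_persistence=pro_pers, retraction_persistence=ret_pers,
        state_persistence=state_pers,
        starting_angle=float(angles[0]),
        mean_angle=_circular_mean_deg(angles),
        angle_rate=float(slope), detrended_angle_variance=detrended_var,
        origin=p.origin, n_splits=len(p.split_events),
        has_protrusions=n_pro > 0, has_retractions=n_ret > 0)


def cell_stats(pods: list[Pseudopod], movie_duration: float,
               frame_interval: float, pixel_size: float) -> CellStats:
    """Cell-level summary over all pseudopods of one movie.

    ``avg_n_pseudopods`` is the time average, over frames, of the number
    of pseudopods whose [t_start, t_end] covers that frame; speeds and
    persistences are plain means over pseudopods (speed means over the
    pseudopods that have the corresponding kind).
    """
    if not pods:
        raise ValueError("need at least one pseudopod")
    stats = [pseudopod_stats(p, frame_interval, pixel_size) for p in pods]
    n_frames = max(1, int(round(movie_duration / frame_interval)))
    t_grid = np.arange(n_frames) * frame_interval
    alive = np.zeros(n_frames)
    for p in pods:
        alive += (t_grid >= p.t_start) & (t_grid <= p.t_end)
    n_split_origin = sum(1 for p in pods if p.origin == "split")
    total_splits = sum(len(p.split_events) for p in pods)

    def _mean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else 0.0

    return CellStats(
        n_pseudopods=len(pods),
        avg_n_pseudopods=float(alive.mean()),
        ratio_from_splitting=n_split_origin / len(pods),
        avg_splitting_rate=total_splits / (movie_duration / 60.0),
        avg_protrusion_persistence=_mean(s.protrusion_persistence for s in stats),
        avg_retraction_persistence=_mean(s.retraction_persistence for s in stats),
        avg_state_persistence=_mean(s.state_persistence for s in stats),
        avg_protrusion_speed=_mean(s.protrusion_speed for s in stats
                                   if s.has_protrusions),
        avg_retraction_speed=_mean(s.retraction_speed for s in stats
                                   if s.has_retractions),
        avg_net_speed=_mean(s.net_speed for s in stats))


def hierarchy_rank(pods: list[Pseudopod], level: float = 0.5
                   ) -> list[Pseudopod]:
    """Smallest prefix of activity-ranked pseudopods covering ``level``.

    Pseudopods are sorted by descending activity count (ties broken by
    earlier start time, then id) and the shortest prefix whose summed
    activity count reaches ``level`` times the total is returned.
    """
    if not (0 < level <= 1):
        raise ValueError("level must lie in (0, 1]")
    ranked = sorted(pods, key=lambda p: (-p.n_activities, p.t_start, p.id))
    total = sum(p.n_activities for p in ranked)
    out, acc = [], 0
    for p in ranked:
        out.append(p)
        acc += p.n_activities
        if acc >= level * total:
            break
    return out


def hierarchy_table(pods: list[Pseudopod]) -> pd.DataFrame:
    """Rank table: (rank, pseudopod_id, cumulative activity fraction)."""
    ranked = sorted(pods, key=lambda p: (-p.n_activities, p.t_start, p.id))
    total = sum(p.n_activities for p in ranked) or 1
    acc = np.cumsum([p.n_activities for p in ranked]) / total
    return pd.DataFrame({"rank": np.arange(1, len(ranked) + 1),
                         "pseudopod_id": [p.id for p in ranked],
                         "cumulative_fraction": acc})


def fit_angle_distribution(angles_deg, n_bins: int = 36
                           ) -> tuple[float, float, bool]:
    """Least-squares Gaussian fit to a protrusion-angle histogram.

    Returns (mean_deg, std_deg, converged).  The histogram spans
    (-180, 180]; the fit is declared non-converged (no exception) when
    the optimiser fails or the fitted std exceeds 180 deg — a flat,
    non-informative distribution.  A degenerate point mass yields the
    bin width as std.

    Raises
    ------
    InsufficientData
        with fewer than 10 angles.
    """
    angles = np.asarray(list(angles_deg), dtype=float)
    if angles.size < 10:
        raise InsufficientData(f"need >= 10 angles, got {angles.size}")
    counts, edges = np.histogram(angles, bins=n_bins, range=(-180.0, 180.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_width = 360.0 / n_bins

    if np.ptp(angles) == 0:  # point mass: Gaussian degenerates to a spike
        return float(angles[0]), bin_width, False

    def gauss(x, a, mu, sigma):
        return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    a0 = float(counts.max())
    mu0 = float(centers[np.argmax(counts)])
    s0 = max(bin_width, float(np.std(angles)) / 2.0)
    try:
        popt, _ = curve_fit(gauss, centers, counts, p0=(a0, mu0, s0),
                            maxfev=5000)
    except (RuntimeError, ValueError):
        return float(np.mean(angles)), float(np.std(angles)), False
    mu, sigma = float(popt[1]), abs(float(popt[2]))
    converged = sigma <= 180.0 and popt[0] > 0 and math.isfinite(mu)
    return mu, sigma, converged


def pseudopod_stats_table(pods: list[Pseudopod], frame_interval: float,
                          pixel_size: float) -> pd.DataFrame:
    return pd.DataFrame([asdict(pseudopod_stats(p, frame_interval, pixel_size))
                         for p in pods])
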