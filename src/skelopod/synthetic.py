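"""Synthetic amoeboid-cell movies with scripted, ground-truth pseudopods.

The generator renders a blob-like cell (a disk with a smooth static
boundary perturbation) from which finger-shaped pseudopods grow and
shrink according to scripted events.  Every event produces closed-form
truth: per-frame masks, the expected protrusion/retraction activities
(kind, start point, angle, length per frame pair) and the lineage
(which track each activity belongs to, where splits happen).  A
membrane-localised fluorescence channel with a known coupling between
local intensity and activity can be rendered on top, so detection,
tracking, statistics and correlation analysis are all testable without
any real microscopy data.

Default geometry mirrors typical chemotaxing *Dictyostelium*: pixel
size 0.2 um, cell radius 25 px (5 um, body ~10 um), frame interval
10 s, pseudopod growth of a few px/frame (cells move ~10 um/min).

The finger model is a rectangle with a round cap anchored inside the
cell body: it gives closed-form truth lengths and guarantees exactly
one skeleton branch per finger.  Fingers must stay ``width + 4`` px
apart along the membrane arc (except the two children of a split,
which necessarily share their base at first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString
from skimage.draw import polygon as draw_polygon

from .errors import OverlapError
from .segmentation import MovieStack, SegmentedFrame


@dataclass
class PseudopodEvent:
    """One scripted finger.

    ``growth_rate`` > 0 grows the finger from length 0 by that many
    px/frame for ``duration`` seconds and then holds it; < 0 starts the
    finger at its full length and shrinks it to 0 (a pure retraction).
    A grown finger can be scripted to retract again (``retract_rate``
    px/frame, starting ``retract_delay`` s after growth ends), giving
    the protrusion-followed-by-retraction pattern.  ``drift_rate``
    rotates the finger around the cell (deg/s).  ``split_at =
    (time_s, angle_offset_deg)`` bifurcates the tip: at that time a
    second finger with the parent's current length appears offset by
    ``angle_offset_deg`` and both keep growing.
    """

    theta0: float
    t_start: float
    duration: float
    growth_rate: float
    width: float = 7.0
    drift_rate: float = 0.0
    split_at: tuple[float, float] | None = None
    retract_rate: float = 0.0
    retract_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.width < 2:
            raise ValueError("width must be >= 2 px")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a rendered movie."""

    masks: list[SegmentedFrame]
    activities: pd.DataFrame   # frame, kind, x, y, theta, length, track_id
    lineage: pd.DataFrame      # track_id, origin, parent_track, t_start, t_end
    splits: pd.DataFrame       # parent_track, child_track, time_s
    centroids: np.ndarray      # (n_frames, 2) body centers (row, col)
    gradient: dict = field(default_factory=lambda: {"direction_deg": 0.0})


def _unit(theta_deg: float, gradient_deg: float = 0.0) -> np.ndarray:
    """(drow, dcol) unit vector at activity angle theta from the gradient."""
    ang = np.radians(gradient_deg + theta_deg)
    return np.array([-np.sin(ang), np.cos(ang)])  # row decreases upward


class _Finger:
    """Resolved per-frame state of one finger track."""

    def __init__(self, track_id: int, event_idx: int, origin: str,
                 parent: int | None):
        self.track_id = track_id
        self.event_idx = event_idx
        self.origin = origin
        self.parent = parent
        self.theta: dict[int, float] = {}   # frame -> angle (deg)
        self.length: dict[int, float] = {}  # frame -> finger length (px)


def _resolve_events(events: list[PseudopodEvent], n_frames: int,
                    frame_interval: float) -> tuple[list[_Finger], list]:
    """Expand scripted events into per-frame finger states and splits."""
    fingers: list[_Finger] = []
    splits = []  # (parent_track, child_track, time_s)
    for ei, ev in enumerate(events):
        f = _Finger(len(fingers), ei, "de_novo", None)
        i0 = int(round(ev.t_start / frame_interval))
        nd = max(1, int(round(ev.duration / frame_interval)))
        i_split = None
        if ev.split_at is not None:
            i_split = int(round(ev.split_at[0] / frame_interval))
        for i in range(n_frames):
            t = i * frame_interval
            if ev.growth_rate >= 0:
                if i < i0:
                    continue
                L = ev.growth_rate * min(i - i0, nd)
                if ev.retract_rate > 0:
                    i_r = i0 + nd + int(round(ev.retract_delay
                                              / frame_interval))
                    if i > i_r:
                        L = max(0.0, ev.growth_rate * nd
                                - ev.retract_rate * (i - i_r))
                        if L <= 0 and ev.growth_rate * nd \
                                - ev.retract_rate * (i - 1 - i_r) <= 0:
                            continue  # fully retracted since last frame
            else:
                L0 = abs(ev.growth_rate) * nd
                if i < i0:
                    L = L0
                else:
                    L = max(0.0, L0 - abs(ev.growth_rate) * (i - i0))
                    if L <= 0 and i > i0 + nd:
                        continue
            f.theta[i] = ev.theta0 + ev.drift_rate * (t - ev.t_start)
            f.length[i] = L
        fingers.append(f)
        if i_split is not None:
            # tip bifurcation: a sibling finger appears at an angular
            # offset with the parent's current length; both keep growing
            child = _Finger(len(fingers), ei, "split", f.track_id)
            offset = ev.split_at[1]
            base_theta = f.theta.get(i_split, ev.theta0)
            L_split = f.length.get(i_split, 0.0)
            for i in range(i_split, n_frames):
                t = i * frame_interval
                child.theta[i] = base_theta + offset \
                    + ev.drift_rate * (t - ev.split_at[0])
                child.length[i] = L_split + abs(ev.growth_rate) * (i - i_split)
            fingers.append(child)
            splits.append((f.track_id, child.track_id,
                           i_split * frame_interval))
    return fingers, splits


def _body_radius(phis: np.ndarray, cell_radius: float, wobble: np.ndarray
                 ) -> np.ndarray:
    r = np.full_like(phis, float(cell_radius))
    for m, (amp, phase) in enumerate(wobble, start=2):
        r += amp * np.cos(m * phis + phase)
    return r


def render_movie(cell_radius: float = 25.0,
                 events: list[PseudopodEvent] | None = None,
                 n_frames: int = 30, frame_interval: float = 10.0,
                 pixel_size: float = 0.2, noise: float = 5.0,
                 seed: int = 0, shape: tuple[int, int] | None = None,
                 drift_px_per_frame: tuple[float, float] = (0.0, 0.0),
                 gradient: dict | None = None, wobble_amp: float = 1.0,
                 cell_intensity: float = 180.0, background: float = 20.0
                 ) -> tuple[MovieStack, SyntheticTruth]:
    """Render a fluorescence movie of one cell with scripted pseudopods.

    Returns the movie and its ground truth.  All randomness (boundary
    wobble phases, intensity noise) is fixed by ``seed``.

    Raises
    ------
    OverlapError
        if two distinct events' fingers come closer than ``width + 4``
        px along the membrane arc in any frame.
    """
    events = events or []
    gradient = gradient or {"direction_deg": 0.0}
    rng = np.random.default_rng(seed)
    grad_deg = float(gradient.get("direction_deg", 0.0))

    max_len = 0.0
    for ev in events:
        nd = max(1, int(round(ev.duration / frame_interval)))
        max_len = max(max_len, abs(ev.growth_rate) * nd)
    margin = cell_radius + max_len + 12
    if shape is None:
        side = int(2 * margin + abs(drift_px_per_frame[0]) * n_frames
                   + abs(drift_px_per_frame[1]) * n_frames)
        shape = (side, side)
    c0 = np.array([shape[0] / 2.0, shape[1] / 2.0])
    if any(drift_px_per_frame):
        c0 = np.array([margin, margin])

    wobble = [(wobble_amp * rng.uniform(0.3, 1.0), rng.uniform(0, 2 * np.pi))
              for _ in range(3)]
    fingers, split_list = _resolve_events(events, n_frames, frame_interval)

    phis = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    body_r = _body_radius(phis, cell_radius, wobble)

    masks: list[SegmentedFrame] = []
    centroids = np.zeros((n_frames, 2))
    frames = np.zeros((n_frames,) + shape, dtype=np.float64)
    for i in range(n_frames):
        cen = c0 + np.asarray(drift_px_per_frame, float) * i
        centroids[i] = cen
        mask = np.zeros(shape, dtype=bool)
        rr, cc = draw_polygon(cen[0] + body_r * np.sin(phis),
                              cen[1] + body_r * np.cos(phis), shape=shape)
        mask[rr, cc] = True
        # check arc separation between unrelated fingers
        active = [(f, f.theta[i], f.length[i]) for f in fingers
                  if i in f.length]
        for a in range(len(active)):
            for b in range(a + 1, len(active)):
                fa, ta, _ = active[a]
                fb, tb, _ = active[b]
                related = (fa.event_idx == fb.event_idx)
                gap = abs((ta - tb + 180.0) % 360.0 - 180.0)
                arc = np.radians(gap) * cell_radius
                w = max(events[fa.event_idx].width, events[fb.event_idx].width)
                if not related and arc < w + 4:
                    raise OverlapError(
                        f"fingers of events {fa.event_idx} and {fb.event_idx} "
                        f"are {arc:.1f} px apart (< width + 4) at frame {i}")
        for f, th, L in active:
            w = events[f.event_idx].width
            u = _unit(th, grad_deg)
            # cap-adjusted tip: the rounded cap ends at radius
            # cell_radius + L exactly, so the protruding extent is L
            base = cen + (cell_radius - w) * u
            tip = cen + (cell_radius + L - w / 2.0) * u
            poly = LineString([tuple(base), tuple(tip)]).buffer(
                w / 2.0, quad_segs=8)
            ex = np.asarray(poly.exterior.coords)
            rr, cc = draw_polygon(ex[:, 0], ex[:, 1], shape=shape)
            mask[rr, cc] = True
        masks.append(SegmentedFrame(mask, i))
        frames[i] = background + cell_intensity * mask \
            + rng.normal(0.0, noise, size=shape)

    truth_acts = _truth_activities(fingers, centroids, cell_radius,
                                   grad_deg, n_frames)
    lineage = pd.DataFrame(
        [{"track_id": f.track_id, "origin": f.origin,
          "parent_track": -1 if f.parent is None else f.parent,
          "t_start": min(f.length) * frame_interval if f.length else np.nan,
          "t_end": max(f.length) * frame_interval if f.length else np.nan}
         for f in fingers],
        columns=["track_id", "origin", "parent_track", "t_start", "t_end"])
    splits = pd.DataFrame(split_list, columns=["parent_track", "child_track",
                                               "time_s"])
    movie = MovieStack(np.clip(frames, 0, None), frame_interval, pixel_size,
                       "fluorescence", gradient)
    truth = SyntheticTruth(masks=masks, activities=truth_acts,
                           lineage=lineage, splits=splits,
                           centroids=centroids, gradient=gradient)
    return movie, truth


def _truth_activities(fingers, centroids, cell_radius, grad_deg,
                      n_frames) -> pd.DataFrame:
    """Expected activities per frame pair, from the closed-form geometry."""
    from .activity import activity_angle

    rows = []
    for f in fingers:
        for i in range(n_frames - 1):
            if i not in f.length and i + 1 not in f.length:
                continue
            L0 = f.length.get(i, 0.0)
            L1 = f.length.get(i + 1, 0.0)
            dL = L1 - L0
            if abs(dL) < 1e-9:
                continue
            th = f.theta.get(i + 1 if dL > 0 else i,
                             f.theta.get(i, f.theta.get(i + 1)))
            u = _unit(th, grad_deg)
            if dL > 0:
                start = centroids[i] + (cell_radius + L0) * u  # old tip
                kind = "protrusion"
            else:
                start = centroids[i] + (cell_radius + L1) * u  # new tip
                kind = "retraction"
            theta = activity_angle(start, centroids[i],
                                   {"direction_deg": grad_deg})
            rows.append({"frame": i, "kind": kind, "x": start[1],
                         "y": start[0], "theta": theta, "length": abs(dL),
                         "track_id": f.track_id})
    return pd.DataFrame(rows, columns=["frame", "kind", "x", "y", "theta",
                                       "length", "track_id"])


def render_membrane_fluorophore(truth: SyntheticTruth, coupling,
                                noise: float = 2.0, seed: int = 0,
                                band_px: int = 3, scale: float = 100.0,
                                baseline: float = 10.0) -> MovieStack:
    """Render a second channel with intensity painted on the membrane band.

    ``coupling(theta_deg, signed_activity_length)`` gives the relative
    intensity at membrane angle theta in a frame where the activity
    detected at that angle (for the pair starting at this frame) has
    the given signed length (0 if none).  Intensity is
    ``baseline + scale * coupling + N(0, noise)`` within ``band_px`` of
    the cell edge, ``baseline`` + noise elsewhere.
    """
    from scipy import ndimage as ndi

    from .activity import activity_angle

    rng = np.random.default_rng(seed)
    n_frames = len(truth.masks)
    shape = truth.masks[0].mask.shape
    acts = truth.activities
    frames = np.zeros((n_frames,) + shape)
    grad = truth.gradient
    for i in range(n_frames):
        mask = truth.masks[i].mask
        band = mask & ~ndi.binary_erosion(mask, iterations=band_px)
        cen = truth.centroids[i]
        out = np.full(shape, baseline, dtype=float)
        rs, cs = np.nonzero(band)
        sub = acts[acts["frame"] == i]
        ang_act = sub["theta"].to_numpy()
        len_act = np.where(sub["kind"].to_numpy() == "protrusion",
                           sub["length"].to_numpy(), -sub["length"].to_numpy())
        for r, c in zip(rs, cs):
            th = activity_angle((r, c), cen, grad)
            a = 0.0
            if len(ang_act):
                d = np.abs((ang_act - th + 180.0) % 360.0 - 180.0)
                j = int(np.argmin(d))
                if d[j] < 12.0:
                    a = float(len_act[j])
            out[r, c] = baseline + scale * float(coupling(th, a))
        out += rng.normal(0.0, noise, size=shape)
        frames[i] = out
    return MovieStack(frames, frame_interval=10.0, pixel_size=0.2,
                      modality="fluorescence", gradient=grad)
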