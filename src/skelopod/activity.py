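"""Protrusion / retraction detection from consecutive frame pairs.

Between frames *n* and *n+1* the cell gains the *growing* region
(pixels in I_{n+1} but not I_n) and loses the *withdrawing* region
(pixels in I_n but not I_{n+1}).  A **protrusion** is a growing region
entered by an outer branch of the later skeleton S_{n+1}; a
**retraction** is a withdrawing region entered by an outer branch of
the earlier skeleton S_n.  The activity's length is the arc length of
the branch inside the region (the branch is extended along its terminal
tangent to the membrane when the pruned skeleton stops short of it).

The start point of an activity is where the branch, walked from its
root toward its terminal, first enters the difference region — i.e.
where it crosses the membrane that bounds the persistent cell body
(the boundary of I_n for protrusions, of I_{n+1} for retractions).
This convention makes detection exactly time-reversal symmetric:
protrusions of the pair (A, B) equal the retractions of (B, A) in
start point and length.  Activity angles are measured at the earlier
frame's centroid, relative to the 0-degree line pointing up the
chemoattractant gradient, counterclockwise positive, in (-180, 180].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .boundary import BoundaryCurve
from .segmentation import SegmentedFrame
from .skeleton import Skeleton

log = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class DifferenceMap:
    """Growing (gained) and withdrawing (lost) pixels of a frame pair."""

    growing: np.ndarray
    withdrawing: np.ndarray

    def __post_init__(self) -> None:
        self.growing = np.asarray(self.growing, bool)
        self.withdrawing = np.asarray(self.withdrawing, bool)
        if (self.growing & self.withdrawing).any():
            raise ValueError("growing and withdrawing must be disjoint")


@dataclass
class Activity:
    """One detected protrusion or retraction event.

    ``x``/``y`` are image column/row of the start point on the membrane;
    ``theta`` is the activity angle in degrees relative to the gradient;
    ``t`` the time (s) of the earlier frame; ``length`` the step size in
    pixels.
    """

    kind: Literal["protrusion", "retraction"]
    x: float
    y: float
    theta: float
    t: float
    length: float
    frame_index: int
    branch_id: int = -1
    pseudopod_id: int = -1

    @property
    def signed_length(self) -> float:
        return self.length if self.kind == "protrusion" else -self.length


def difference_map(I_n: SegmentedFrame | np.ndarray,
                   I_n1: SegmentedFrame | np.ndarray) -> DifferenceMap:
    """Growing = I_{n+1} \\ I_n ; withdrawing = I_n \\ I_{n+1}."""
    a = I_n.mask if isinstance(I_n, SegmentedFrame) else np.asarray(I_n, bool)
    b = I_n1.mask if isinstance(I_n1, SegmentedFrame) else np.asarray(I_n1, bool)
    if a.shape != b.shape:
        raise ValueError("frames must share dimensions")
    return DifferenceMap(growing=b & ~a, withdrawing=a & ~b)


def activity_angle(start, centroid, gradient: dict) -> float:
    """Signed angle (degrees) of an activity relative to the 0-degree line.

    The 0-degree line is the ray from the cell centroid along the
    steepest chemoattractant increase: for ``{"direction_deg": g}`` it
    is the fixed direction g (degrees CCW from +x with y pointing up);
    for ``{"source_xy": (x, y)}`` it points from the centroid toward
    the source.  Positive angles are counterclockwise; the result lies
    in (-180, 180].
    """
    sy, sx = float(start[0]), float(start[1])
    cy, cx = float(centroid[0]), float(centroid[1])
    if sx == cx and sy == cy:
        raise ValueError("start must differ from centroid")
    # Cartesian frame: x = col, y = -row so CCW is visually CCW
    vx, vy = sx - cx, -(sy - cy)
    if "direction_deg" in gradient:
        g = np.radians(float(gradient["direction_deg"]))
        zx, zy = np.cos(g), np.sin(g)
    else:
        px, py = gradient["source_xy"]
        zx, zy = float(px) - cx, -(float(py) - cy)
    ang = np.degrees(np.arctan2(vy * zx - vx * zy, vx * zx + vy * zy))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def _terminal_tangent(path: np.ndarray, k: int = 5) -> np.ndarray | None:
    """Unit direction of the last <= k px of a root->terminal path."""
    if len(path) < 2:
        return None
    tail = path[-min(k, len(path)):].astype(float)
    v = tail[-1] - tail[0]
    n = np.hypot(*v)
    if n == 0:
        return None
    return v / n


def extend_branch(path: np.ndarray, inside_mask: np.ndarray,
                  max_steps: int | None = None) -> np.ndarray:
    """Prolong a branch path beyond its terminal to the mask boundary.

    The terminal tangent (last-5-px direction) is walked in unit steps
    until the first pixel outside ``inside_mask``; the pixels traversed
    (still inside the mask) are appended to the path.  Returns the path
    unchanged if the terminal already touches the boundary or no tangent
    is defined.
    """
    path = np.asarray(path)
    tang = _terminal_tangent(path)
    if tang is None:
        return path
    if max_steps is None:
        max_steps = int(np.hypot(*inside_mask.shape))
    pos = path[-1].astype(float)
    ext = []
    last = tuple(path[-1])
    for _ in range(max_steps):
        pos = pos + tang
        pix = (int(round(pos[0])), int(round(pos[1])))
        if not (0 <= pix[0] < inside_mask.shape[0]
                and 0 <= pix[1] < inside_mask.shape[1]):
            break
        if not inside_mask[pix]:
            break
        if pix != last:
            ext.append(pix)
            last = pix
    if not ext:
        return path
    return np.vstack([path, np.array(ext)])


def _segment_lengths(path: np.ndarray) -> np.ndarray:
    d = np.diff(path.astype(float), axis=0)
    return np.hypot(d[:, 0], d[:, 1])


def _detect_kind(skel: Skeleton, region: np.ndarray,
                 start_curve: BoundaryCurve, ext_mask: np.ndarray,
                 kind: str, centroid, gradient: dict, t: float,
                 frame_index: int, min_component_area: int) -> list[Activity]:
    """Shared detector: one activity per (outer branch, region component)."""
    labels, n_comp = ndi.label(region, structure=_STRUCT8)
    if n_comp == 0 or skel.is_empty:
        return []
    areas = ndi.sum_labels(region, labels, index=np.arange(1, n_comp + 1))
    valid = {i + 1 for i, a in enumerate(areas) if a >= min_component_area}
    if not valid:
        return []
    tree = cKDTree(start_curve.samples[:-1])
    # a difference component is one activity: if several branches enter
    # it, the branch with the longest arc inside the component measures it
    best: dict[int, tuple] = {}
    for bid, branch in enumerate(skel.outer_branches(both_orientations=True)):
        full = extend_branch(branch.path, ext_mask)
        lab = labels[full[:, 0], full[:, 1]]
        hit = sorted(set(lab[lab > 0]) & valid)
        if not hit:
            continue
        steps = _segment_lengths(full)
        for comp in hit:
            inside = lab == comp
            # arc length: count each step whose far pixel is in the component
            length = float(steps[inside[1:]].sum())
            if length <= 0:
                length = 1.0  # single-pixel overlap still counts one pixel
            first = int(np.argmax(inside))
            if comp in best and best[comp][0] >= length:
                continue
            best[comp] = (length, bid, full[first])
    out: list[Activity] = []
    for comp in sorted(best):
        length, bid, entry = best[comp]
        _, j = tree.query(entry.astype(float))
        start = start_curve.samples[j]
        theta = activity_angle(start, centroid, gradient)
        out.append(Activity(kind=kind, x=float(start[1]), y=float(start[0]),
                            theta=theta, t=t, length=length,
                            frame_index=frame_index, branch_id=bid))
    return out


def detect_activities(S_n: Skeleton, S_n1: Skeleton, diff: DifferenceMap,
                      curve_n: BoundaryCurve, curve_n1: BoundaryCurve,
                      gradient: dict | None = None,
                      frame_interval: float = 1.0,
                      min_component_area: int = 4) -> list[Activity]:
    """Detect all protrusions and retractions of one frame pair.

    Protrusions: outer branches of ``S_n1`` entering growing components;
    retractions: outer branches of ``S_n`` entering withdrawing
    components.  Difference components smaller than
    ``min_component_area`` px^2 are treated as segmentation noise.
    Both kinds carry the time and angle reference of frame *n*.
    """
    gradient = gradient or {"direction_deg": 0.0}
    t = S_n.frame_index * frame_interval
    mask_n = curve_n.to_mask(S_n.shape)
    mask_n1 = (mask_n & ~diff.withdrawing) | diff.growing
    centroid = curve_n.centroid
    acts = _detect_kind(S_n1, diff.growing, curve_n, mask_n1, "protrusion",
                        centroid, gradient, t, S_n.frame_index,
                        min_component_area)
    acts += _detect_kind(S_n, diff.withdrawing, curve_n1, mask_n,
                         "retraction", centroid, gradient, t,
                         S_n.frame_index, min_component_area)
    return acts


def activities_to_dataframe(activities: list[Activity]) -> pd.DataFrame:
    cols = ["frame", "time_s", "kind", "x_px", "y_px", "theta_deg",
            "length_px", "branch_id", "pseudopod_id"]
    rows = [{"frame": a.frame_index, "time_s": a.t, "kind": a.kind,
             "x_px": a.x, "y_px": a.y, "theta_deg": a.theta,
             "length_px": a.length, "branch_id": a.branch_id,
             "pseudopod_id": a.pseudopod_id} for a in activities]
    return pd.DataFrame(rows, columns=cols)
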