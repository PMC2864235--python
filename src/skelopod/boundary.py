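"""Cell boundary extraction and B-spline smoothing.

The raw pixel boundary of a segmented cell is jagged at the pixel scale,
and a medial-axis skeleton is extremely sensitive to such jaggedness:
every bump spawns a spurious branch.  This module traces the ordered
pixel boundary of a mask and fits a closed uniform quadratic B-spline to
it, removing high-frequency spatial fluctuations while retaining
prominent shape features (pseudopods).

The fit follows an iterative data-association scheme: sample the current
spline densely, search along each sample's local normal for the nearest
point of the raw boundary polygon (the *feature point*), then re-estimate
the control points by least squares against the feature points.  A few
iterations suffice; the fit aborts if the mean feature-point distance
grows for three consecutive iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, cKDTree
from shapely.geometry import LinearRing, LineString, Point
from skimage.draw import polygon as draw_polygon

from .errors import DegenerateShape, FitDiverged
from .segmentation import SegmentedFrame

# 8-neighbour offsets indexed anti-clockwise from East (border following)
_DIRS = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


@dataclass
class BoundaryCurve:
    """Smoothed closed cell outline with its geometric descriptors.

    ``samples`` is a dense closed polyline (first point repeated at the
    end) in (row, col) coordinates.  ``body_length`` is the maximum Feret
    diameter of the enclosed region, the "length of the cell body" used
    to scale the pruning thresholds.  ``centroid`` is the area centroid
    of the enclosed region.
    """

    control_points: np.ndarray
    samples: np.ndarray
    centroid: np.ndarray
    perimeter: float
    body_length: float
    frame_index: int = 0

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterise the enclosed region into a boolean mask."""
        rr, cc = draw_polygon(self.samples[:-1, 0], self.samples[:-1, 1],
                              shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask

    def to_csv(self, path) -> None:
        np.savetxt(path, self.samples[:, ::-1], delimiter=",",
                   header="x,y", comments="")


def extract_boundary(frame: SegmentedFrame | np.ndarray) -> np.ndarray:
    """Trace the ordered outer pixel boundary of a single-component mask.

    Moore-neighbour tracing yields each 8-connected boundary pixel in
    order.  The returned polygon is closed implicitly (last point joins
    the first) and oriented with positive shoelace area in (row, col)
    coordinates.

    Raises
    ------
    DegenerateShape
        if the component has fewer than 8 boundary pixels.
    """
    mask = frame.mask if isinstance(frame, SegmentedFrame) else np.asarray(frame, bool)
    if not mask.any():
        raise DegenerateShape("empty mask")
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    start = (rows[0], cols[0])  # topmost, then leftmost foreground pixel

    # inner border following (Sonka et al.): anti-clockwise neighbourhood
    # scan; stop when the first two border elements repeat in order
    contour = [start]
    cur = start
    dirn = 7
    while True:
        first = (dirn + 7) % 8 if dirn % 2 == 0 else (dirn + 6) % 8
        nxt = None
        for k in range(8):
            d = (first + k) % 8
            nb = (cur[0] + _DIRS[d][0], cur[1] + _DIRS[d][1])
            if padded[nb]:
                nxt = nb
                dirn = d
                break
        if nxt is None:  # isolated pixel
            break
        contour.append(nxt)
        cur = nxt
        if (len(contour) >= 4 and contour[-1] == contour[1]
                and contour[-2] == contour[0]):
            contour = contour[:-2]
            break

    poly = np.array(contour, dtype=float) - 1.0  # undo padding offset
    poly = poly[np.concatenate([[True], np.any(np.diff(poly, axis=0) != 0,
                                               axis=1)])]
    if len(poly) < 8:
        raise DegenerateShape(
            f"component has only {len(poly)} boundary pixels (< 8)")
    # canonical orientation: positive shoelace area in (row, col)
    if _signed_area(poly) < 0:
        poly = poly[::-1]
    return poly


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 1], poly[:, 0]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _polyline_length(pts: np.ndarray, closed: bool = True) -> float:
    d = np.diff(pts, axis=0)
    total = float(np.hypot(d[:, 0], d[:, 1]).sum())
    if closed and not np.allclose(pts[0], pts[-1]):
        total += float(np.hypot(*(pts[0] - pts[-1])))
    return total


def _bspline_design(n_control: int, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix of a closed uniform quadratic B-spline.

    Returns (B, dB): value and derivative basis matrices of shape
    (n_samples, n_control) evaluated at uniformly spaced parameters.
    """
    t = np.linspace(0.0, n_control, n_samples, endpoint=False)
    seg = np.floor(t).astype(int)
    u = t - seg
    B = np.zeros((n_samples, n_control))
    dB = np.zeros((n_samples, n_control))
    # quadratic uniform basis on segment k touches controls k-1, k, k+1
    w = np.stack([0.5 * (1 - u) ** 2,
                  -u ** 2 + u + 0.5,
                  0.5 * u ** 2], axis=1)
    dw = np.stack([u - 1.0, 1.0 - 2.0 * u, u], axis=1)
    for j in range(3):
        idx = (seg + j - 1) % n_control
        B[np.arange(n_samples), idx] += w[:, j]
        dB[np.arange(n_samples), idx] += dw[:, j]
    return B, dB


def _resample_closed(poly: np.ndarray, n: int) -> np.ndarray:
    """Uniform arc-length resampling of a closed polygon to n points."""
    pts = np.vstack([poly, poly[:1]])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, pts[:, 0])
    out[:, 1] = np.interp(targets, s, pts[:, 1])
    return out


def fit_bspline(polygon: np.ndarray, n_control: int | None = None,
                n_iterations: int = 5, n_samples: int | None = None,
                normal_search: float = 12.0,
                frame_index: int = 0) -> BoundaryCurve:
    """Fit a closed uniform quadratic B-spline to a boundary polygon.

    Parameters
    ----------
    polygon
        Ordered closed boundary polygon, (row, col), as produced by
        :func:`extract_boundary`.
    n_control
        Number of control points.  Default ``max(8, perimeter / 8)``:
        the control spacing must stay below the width of a pseudopod so
        genuine protrusions survive the smoothing.
    n_iterations
        Normal-search / least-squares refinement passes.
    normal_search
        Half-length (px) of the normal segment searched for a feature
        point before falling back to the nearest boundary point.

    Raises
    ------
    FitDiverged
        if the mean feature-point distance increases for 3 consecutive
        iterations.
    """
    polygon = np.asarray(polygon, dtype=float)
    if n_control is None:
        n_control = max(8, int(round(_polyline_length(polygon) / 8.0)))
    if n_control < 4:
        raise ValueError("n_control must be >= 4")
    if n_samples is None:
        n_samples = max(4 * n_control, 100)

    B, dB = _bspline_design(n_control, n_samples)
    # least-squares with a whisper of ridge for conditioning
    BtB = B.T @ B + 1e-8 * np.eye(n_control)

    control = _resample_closed(polygon, n_control)
    ring = LinearRing(polygon)
    tree = cKDTree(polygon)

    prev_err = np.inf
    n_worse = 0
    best = control
    for _ in range(max(1, n_iterations)):
        samples = B @ control
        tangents = dB @ control
        norms = np.hypot(tangents[:, 0], tangents[:, 1])
        norms[norms == 0] = 1.0
        normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1) / norms[:, None]

        features = np.empty_like(samples)
        for i, (s, nvec) in enumerate(zip(samples, normals)):
            a = s - normal_search * nvec
            b = s + normal_search * nvec
            inter = ring.intersection(LineString([tuple(a), tuple(b)]))
            pt = _nearest_point(inter, s)
            if pt is None:
                # no crossing along the normal: nearest raw boundary pixel
                _, j = tree.query(s)
                pt = polygon[j]
            features[i] = pt

        err = float(np.mean(np.hypot(*(features - samples).T)))
        if err > prev_err + 1e-3:  # tolerate numeric jitter at the plateau
            n_worse += 1
            if n_worse >= 3:
                raise FitDiverged(
                    f"feature distance increased 3 times (last {err:.3f} px)")
        else:
            n_worse = 0
            best = control
        prev_err = min(prev_err, err)
        if err < 1e-3:
            control = best
            break
        control = np.linalg.solve(BtB, B.T @ features)

    samples = B @ control
    closed = np.vstack([samples, samples[:1]])
    return _make_curve(control, closed, frame_index)


def _nearest_point(geom, ref: np.ndarray):
    """Nearest coordinate of a shapely intersection result to ref, or None."""
    if geom.is_empty:
        return None
    pts = []
    stack = [geom]
    while stack:
        g = stack.pop()
        if hasattr(g, "geoms"):
            stack.extend(g.geoms)
        elif isinstance(g, Point):
            pts.append((g.x, g.y))
        elif isinstance(g, LineString):
            pts.extend(g.coords)
    if not pts:
        return None
    pts = np.asarray(pts)
    d = np.hypot(pts[:, 0] - ref[0], pts[:, 1] - ref[1])
    return pts[np.argmin(d)]


def _make_curve(control: np.ndarray, closed_samples: np.ndarray,
                frame_index: int) -> BoundaryCurve:
    centroid = _polygon_centroid(closed_samples)
    perimeter = _polyline_length(closed_samples, closed=False)
    body_length = _max_feret(closed_samples[:-1])
    return BoundaryCurve(control_points=control, samples=closed_samples,
                         centroid=centroid, perimeter=perimeter,
                         body_length=body_length, frame_index=frame_index)


def curve_from_polygon(polygon: np.ndarray, frame_index: int = 0) -> BoundaryCurve:
    """Wrap a raw polygon as a BoundaryCurve without smoothing.

    For spiky cell types where spline smoothing would erase genuine
    features, smoothing can be bypassed and the raw pixel boundary used
    directly.
    """
    closed = np.vstack([polygon, polygon[:1]]).astype(float)
    return _make_curve(polygon.astype(float).copy(), closed, frame_index)


def _polygon_centroid(closed: np.ndarray) -> np.ndarray:
    """Area centroid of a closed polygon (shoelace)."""
    y, x = closed[:-1, 0], closed[:-1, 1]
    y1, x1 = np.roll(y, -1), np.roll(x, -1)
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-9:
        return closed[:-1].mean(axis=0)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    return np.array([cy, cx])


def _max_feret(pts: np.ndarray) -> float:
    """Maximum Feret diameter (max pairwise distance over the convex hull)."""
    if len(pts) < 3:
        return float(np.hypot(*(pts.max(0) - pts.min(0))))
    try:
        hull = pts[ConvexHull(pts).vertices]
    except Exception:  # collinear input
        hull = pts
    d = np.linalg.norm(hull[:, None, :] - hull[None, :, :], axis=-1)
    return float(d.max())


def curve_descriptors(curve: BoundaryCurve) -> tuple[np.ndarray, float, float]:
    """Return (centroid, perimeter, body_length) of a boundary curve."""
    return curve.centroid, curve.perimeter, curve.body_length


def smooth_boundary(frame: SegmentedFrame, smoothing: bool = True,
                    n_control: int | None = None,
                    n_iterations: int = 5) -> BoundaryCurve:
    """Extract and (optionally) spline-smooth the boundary of a mask."""
    poly = extract_boundary(frame)
    idx = frame.frame_index if isinstance(frame, SegmentedFrame) else 0
    if not smoothing:
        return curve_from_polygon(poly, idx)
    return fit_bspline(poly, n_control=n_control, n_iterations=n_iterations,
                       frame_index=idx)
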