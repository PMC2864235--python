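"""Space-time correlation of membrane fluorescence with activities.

Both signals are laid out on a (frame k, membrane angle theta) grid:
``A(k, theta)`` is the signed activity length detected at that frame
and angle (protrusions positive, retractions negative, 0 where nothing
happened) and ``I(k, theta)`` the relative membrane fluorescence
sampled in a band around the boundary point at angle theta.  Their
normalised cross-correlation

    C(dk, dtheta) = < A(k+dk, theta+dtheta) I(k, theta) > / (sigma_A sigma_I)

is a (360/dtheta) x (2N-1) matrix: angle shifts are circular, time
shifts zero-padded (the movie is not time-periodic), and |C| <= 1 under
the biased normalisation used.  Intensity is mean-centred per frame
(averaging over angles only), which removes photobleaching and global
illumination drift before correlating; the activity signal is centred
by its global mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity import Activity
from .boundary import BoundaryCurve
from .errors import DegenerateInput

log = logging.getLogger(__name__)


@dataclass
class AngularActivityMatrix:
    """(n_frames, 360/delta_theta) signed activity lengths."""

    values: np.ndarray
    delta_theta: float

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class AngularIntensityMatrix:
    """(n_frames, 360/delta_theta) membrane intensities."""

    values: np.ndarray
    delta_theta: float
    normalization: str = "raw"  # raw | minmax | zscore

    def normalized(self, mode: str) -> "AngularIntensityMatrix":
        """Return a min-max (0..1) or z-scored copy.

        z-scoring is per frame against the distribution of intensities
        around that cell's periphery, so values read as 'standard
        deviations above the mean membrane fluorescence'.
        """
        v = self.values.astype(float)
        if mode == "minmax":
            lo, hi = v.min(), v.max()
            out = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
        elif mode == "zscore":
            mu = v.mean(axis=1, keepdims=True)
            sd = v.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            out = (v - mu) / sd
        else:
            raise ValueError(f"unknown normalization {mode!r}")
        return AngularIntensityMatrix(out, self.delta_theta, mode)


@dataclass
class CorrelationMap:
    """Cross-correlation on the (angle shift, time shift) grid.

    Row i is the angle shift -(180 - delta_theta) + i*delta_theta ...
    up to +180; column j is the time shift j - (N - 1) frames.
    """

    values: np.ndarray
    delta_theta: float
    n_frames: int

    @property
    def angle_shifts(self) -> np.ndarray:
        n_bins = self.values.shape[0]
        return -(180.0 - self.delta_theta) + self.delta_theta * np.arange(n_bins)

    @property
    def time_shifts(self) -> np.ndarray:
        return np.arange(-(self.n_frames - 1), self.n_frames)

    def peak(self) -> tuple[float, float, float]:
        """(time shift frames, angle shift deg, value) at max |C|."""
        i, j = np.unravel_index(np.argmax(np.abs(self.values)),
                                self.values.shape)
        return (float(self.time_shifts[j]), float(self.angle_shifts[i]),
                float(self.values[i, j]))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.angle_shifts,
                          columns=self.time_shifts)
        df.index.name = "angle_shift_deg"
        df.to_csv(path)


def _bin_index(theta: float, delta_theta: float) -> int:
    """Map an angle in (-180, 180] onto bins centred every delta_theta."""
    n_bins = int(round(360.0 / delta_theta))
    return int(np.floor(((theta + 180.0) % 360.0) / delta_theta)) % n_bins


def sample_membrane_intensity(image: np.ndarray, curve: BoundaryCurve,
                              delta_theta: float = 4.0, band_px: int = 3,
                              gradient: dict | None = None) -> np.ndarray:
    """Average membrane intensity per angle bin for one frame.

    For each bin of the membrane angle (measured at the cell centroid
    relative to the gradient 0-degree line), the boundary sample
    falling in that bin and farthest from the centroid is chosen (the
    farthest crossing handles the rare multi-crossing shapes, which are
    logged), and the image is averaged over ``band_px + 1`` bilinear
    samples taken along the inward radial direction from that point
    (the membrane band).  Empty bins are filled from their nearest
    non-empty angular neighbour.
    """
    from .activity import activity_angle  # local import to avoid cycle

    gradient = gradient or {"direction_deg": 0.0}
    image = np.asarray(image, dtype=float)
    n_bins = int(round(360.0 / delta_theta))
    if abs(n_bins * delta_theta - 360.0) > 1e-9:
        raise ValueError("360 must be divisible by delta_theta")
    cen = curve.centroid
    pts = curve.samples[:-1]
    radii = np.hypot(pts[:, 0] - cen[0], pts[:, 1] - cen[1])
    thetas = np.array([activity_angle(p, cen, gradient) for p in pts])
    bins = np.array([_bin_index(t, delta_theta) for t in thetas])

    from scipy.ndimage import map_coordinates

    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = bins == b
        if not sel.any():
            continue
        idx = np.nonzero(sel)[0]
        if np.ptp(radii[idx]) > 1.5 * band_px:
            log.info("angle bin %d crossed more than once; using farthest", b)
        p = pts[idx[np.argmax(radii[idx])]]
        r = max(np.hypot(p[0] - cen[0], p[1] - cen[1]), 1e-9)
        inward = (cen - p) / r
        depths = np.arange(band_px + 1, dtype=float)
        coords = p[None, :] + depths[:, None] * inward[None, :]
        vals = map_coordinates(image, coords.T, order=1, mode="nearest")
        out[b] = float(vals.mean())
    # fill empty bins from nearest angular neighbour (circular)
    if np.isnan(out).any():
        good = np.nonzero(~np.isnan(out))[0]
        if good.size == 0:
            return np.zeros(n_bins)
        for b in np.nonzero(np.isnan(out))[0]:
            d = np.minimum(np.abs(good - b), n_bins - np.abs(good - b))
            out[b] = out[good[np.argmin(d)]]
    return out


def build_intensity_matrix(images, curves, delta_theta: float = 4.0,
                           band_px: int = 3, gradient: dict | None = None
                           ) -> AngularIntensityMatrix:
    rows = [sample_membrane_intensity(im, cu, delta_theta, band_px, gradient)
            for im, cu in zip(images, curves)]
    return AngularIntensityMatrix(np.asarray(rows), delta_theta)


def build_activity_matrix(activities: list[Activity], delta_theta: float,
                          n_frames: int) -> AngularActivityMatrix:
    """Signed activity lengths on the (frame, angle bin) grid.

    Protrusions positive, retractions negative; if two activities fall
    into the same cell the larger |length| wins (collision logged).
    """
    n_bins = int(round(360.0 / delta_theta))
    vals = np.zeros((n_frames, n_bins))
    for a in activities:
        if not (0 <= a.frame_index < n_frames):
            continue
        b = _bin_index(a.theta, delta_theta)
        s = a.signed_length
        if vals[a.frame_index, b] != 0.0:
            log.info("activity collision at frame %d bin %d", a.frame_index, b)
            if abs(s) <= abs(vals[a.frame_index, b]):
                continue
        vals[a.frame_index, b] = s
    return AngularActivityMatrix(vals, delta_theta)


def cross_correlate(A: AngularActivityMatrix, I: AngularIntensityMatrix
                    ) -> CorrelationMap:
    """Normalised space-time cross-correlation of activity and intensity.

    ``C[i, j]`` correlates ``A`` shifted by (time_shifts[j],
    angle_shifts[i]) against ``I``: a positive peak at (dk, dtheta)
    means activities dk frames after and dtheta degrees away from high
    intensity.  Angle shifts are circular, time shifts zero-padded; the
    biased normalisation (by the full matrix size and the global
    standard deviations) keeps |C| <= 1.

    Raises
    ------
    DegenerateInput
        if either matrix has zero variance.
    """
    if A.values.shape != I.values.shape or A.delta_theta != I.delta_theta:
        raise ValueError("matrices must share shape and delta_theta")
    a = A.values.astype(float)
    iv = I.values.astype(float)
    # averaging structure: global mean for A, per-frame (over angles) for I
    ac = a - a.mean()
    icn = iv - iv.mean(axis=1, keepdims=True)
    sa, si = ac.std(), icn.std()
    if sa == 0 or si == 0:
        raise DegenerateInput("zero-variance input matrix")
    n, m = a.shape
    # circular in angle via FFT along axis 1; zero-pad in time
    pad = np.zeros((3 * n - 2, m))
    pad[n - 1:2 * n - 1] = ac
    out = np.empty((m, 2 * n - 1))
    fi = np.fft.rfft(icn, axis=1)
    for j, dk in enumerate(range(-(n - 1), n)):
        seg = pad[n - 1 + dk:2 * n - 1 + dk]
        fs = np.fft.rfft(seg, axis=1)
        # sum over k of seg(k, theta + dtheta) * icn(k, theta), all dtheta
        corr = np.fft.irfft(fs * np.conj(fi), n=m, axis=1).sum(axis=0)
        out[:, j] = corr
    out /= (n * m * sa * si)
    # rows: angle shift from -(180 - dtheta) to +180
    n_neg = int(round((180.0 - A.delta_theta) / A.delta_theta))
    rows = np.roll(out, n_neg, axis=0)
    return CorrelationMap(rows, A.delta_theta, n)


def activity_site_intensity(activities: list[Activity],
                            I_z: AngularIntensityMatrix,
                            offset_deg: float = 0.0) -> pd.DataFrame:
    """Pair each activity's signed length with membrane intensity.

    The intensity is read from the z-scored matrix at the activity's
    frame and at its angle shifted by ``offset_deg`` (e.g. 180 to look
    at the opposite side of the cell).  Returns a DataFrame with
    columns (frame, kind, signed_length, intensity).
    """
    dth = I_z.delta_theta
    if abs((offset_deg / dth) - round(offset_deg / dth)) > 1e-9:
        raise ValueError("offset_deg must be a multiple of delta_theta")
    rows = []
    n_bins = I_z.values.shape[1]
    for a in activities:
        if not (0 <= a.frame_index < I_z.values.shape[0]):
            continue
        b = (_bin_index(a.theta, dth) + int(round(offset_deg / dth))) % n_bins
        rows.append({"frame": a.frame_index, "kind": a.kind,
                     "signed_length": a.signed_length,
                     "intensity": float(I_z.values[a.frame_index, b])})
    return pd.DataFrame(rows, columns=["frame", "kind", "signed_length",
                                       "intensity"])


def site_intensity_summary(pairs: pd.DataFrame) -> dict:
    """Correlation coefficient and kind-stratified mean intensities."""
    out = {"n": int(len(pairs)), "correlation": float("nan"),
           "mean_intensity_protrusion": float("nan"),
           "mean_intensity_retraction": float("nan"), "degenerate": False}
    if len(pairs) >= 2 and pairs["signed_length"].std() > 0 \
            and pairs["intensity"].std() > 0:
        out["correlation"] = float(
            np.corrcoef(pairs["signed_length"], pairs["intensity"])[0, 1])
    else:
        out["degenerate"] = True
    for kind in ("protrusion", "retraction"):
        sel = pairs[pairs["kind"] == kind]
        if len(sel):
            out[f"mean_intensity_{kind}"] = float(sel["intensity"].mean())
    return out


def length_vs_intensity_profile(pairs: pd.DataFrame, n_bins: int = 8
                                ) -> pd.DataFrame:
    """Mean signed activity length (with SEM) binned by local intensity."""
    if pairs.empty:
        raise ValueError("no activity/intensity pairs")
    edges = np.linspace(pairs["intensity"].min(), pairs["intensity"].max(),
                        n_bins + 1)
    edges[-1] += 1e-9
    which = np.clip(np.digitize(pairs["intensity"], edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = pairs[which == b]
        if sel.empty:
            continue
        sem = (float(sel["signed_length"].std(ddof=1)) / np.sqrt(len(sel))
               if len(sel) > 1 else 0.0)
        rows.append({"bin_center": 0.5 * (edges[b] + edges[b + 1]),
                     "mean_length": float(sel["signed_length"].mean()),
                     "sem": sem, "n": int(len(sel))})
    return pd.DataFrame(rows, columns=["bin_center", "mean_length", "sem", "n"])
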