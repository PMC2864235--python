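"""Cell segmentation for fluorescence, phase-contrast and DIC movies.

Each modality gets its own entry point that turns one grayscale frame
into a single-component binary cell mask (``SegmentedFrame``):

* fluorescence -- global two-class (Otsu) threshold, largest component,
  holes filled;
* phase contrast -- Lucy-Richardson deblurring to remove the phase ring,
  then gradient-magnitude thresholding and morphological closing;
* DIC -- line integration along the prism shear direction (LID) converts
  the differential image into a pseudo-fluorescent one, with total
  variation denoising applied either before integration or after it,
  followed by the fluorescence thresholding path.

After line integration the recovered cell is offset by a constant amount
along the shear direction (the integration constant of the forward
difference).  The offset is identical in every frame, so cell shape and
all shape-derived quantities are unaffected; it is deliberately left
uncorrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.filters import sobel, threshold_otsu
from skimage.morphology import closing, disk, remove_small_objects
from skimage.restoration import denoise_tv_chambolle, richardson_lucy

from .errors import NoCellFound

Modality = Literal["fluorescence", "phase_contrast", "dic"]


@dataclass
class MovieStack:
    """A time-lapse movie: ordered grayscale frames plus acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, H, W)``, arbitrary intensity units.
    frame_interval
        Seconds per frame, > 0.
    pixel_size
        Microns per pixel, > 0.
    modality
        One of ``fluorescence``, ``phase_contrast``, ``dic``.
    gradient
        Chemoattractant geometry: either ``{"direction_deg": float}`` (a
        uniform gradient direction, degrees CCW from +x in image
        coordinates) or ``{"source_xy": (x, y)}`` (a point source).
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float
    modality: Modality = "fluorescence"
    gradient: dict = field(default_factory=lambda: {"direction_deg": 0.0})

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) array")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    @classmethod
    def from_tiff(cls, path, frame_interval: float, pixel_size: float,
                  modality: Modality = "fluorescence",
                  gradient: dict | None = None) -> "MovieStack":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames, frame_interval, pixel_size, modality,
                   gradient or {"direction_deg": 0.0})

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, np.asarray(self.frames),
                         photometric="minisblack")


@dataclass
class SegmentedFrame:
    """Binary segmentation of one frame: 1 inside the cell, 0 background."""

    mask: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        border = np.concatenate([self.mask[0], self.mask[-1],
                                 self.mask[:, 0], self.mask[:, -1]])
        if border.any():
            warnings.warn(
                f"frame {self.frame_index}: cell touches the image border",
                stacklevel=2)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def write_masks_tiff(frames: Sequence[SegmentedFrame], path) -> None:
    """Write per-frame masks as a binary (0/255) multi-page TIFF."""
    stack = np.stack([f.mask.astype(np.uint8) * 255 for f in frames])
    tifffile.imwrite(path, stack, photometric="minisblack")


def _largest_filled_component(fg: np.ndarray, min_area: int) -> np.ndarray:
    """Keep the largest connected foreground component and fill its holes."""
    labels, n = ndi.label(fg)
    if n == 0:
        raise NoCellFound("no foreground component found")
    sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area:
        raise NoCellFound(
            f"largest component has {int(sizes[best - 1])} px < min_area={min_area}")
    return ndi.binary_fill_holes(labels == best)


def segment_fluorescence(image: np.ndarray, min_area: int = 50,
                         frame_index: int = 0) -> SegmentedFrame:
    """Threshold a fluorescence frame between background and cell intensity.

    A global two-class variance-maximising (Otsu) threshold realises the
    "adaptive threshold between background and cell" for bimodal
    fluorescent frames; the result is invariant to affine intensity
    rescaling ``a*I + b`` with ``a > 0``.
    """
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        raise NoCellFound("constant image: no background/cell separation")
    thr = threshold_otsu(image)
    mask = _largest_filled_component(image > thr, min_area)
    return SegmentedFrame(mask, frame_index)


def gaussian_psf(sigma: float = 2.0, size: int | None = None) -> np.ndarray:
    """Isotropic Gaussian point-spread function, normalised to sum 1."""
    if size is None:
        size = int(2 * np.ceil(3 * sigma) + 1)
    ax = np.arange(size) - size // 2
    xx, yy = np.meshgrid(ax, ax)
    psf = np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma ** 2))
    return psf / psf.sum()


def segment_phase_contrast(image: np.ndarray, psf: np.ndarray | None = None,
                           n_iter: int = 10, min_area: int = 50,
                           closing_radius: int = 3,
                           frame_index: int = 0) -> SegmentedFrame:
    """Segment a phase-contrast frame.

    Lucy-Richardson deconvolution removes the phase ring; the Sobel
    gradient magnitude of the deblurred frame is Otsu-thresholded, the
    high-gradient regions are connected by binary closing with a disk,
    and the filled largest component is returned.
    """
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        raise NoCellFound("constant image")
    if psf is None:
        psf = gaussian_psf()
    if psf.sum() <= 0:
        raise ValueError("psf must have positive sum")
    psf = psf / psf.sum()
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    lo, hi = image.min(), image.max()
    scaled = (image - lo) / (hi - lo)
    # identity PSF: deconvolution is a no-op, skip the iterations
    if psf.size == 1 or (psf.max() == 1.0 and np.count_nonzero(psf) == 1):
        deblurred = scaled
    else:
        deblurred = richardson_lucy(scaled, psf, num_iter=n_iter, clip=True)
    grad = sobel(deblurred)
    thr = threshold_otsu(grad)
    fg = remove_small_objects(grad > thr, max_size=16)  # drop noise specks
    fg = closing(fg, disk(closing_radius))
    mask = _largest_filled_component(ndi.binary_fill_holes(fg), min_area)
    # the gradient band straddles the true edge; pull the outline back in
    mask = ndi.binary_erosion(mask, iterations=2)
    if mask.sum() < min_area:
        raise NoCellFound("component shrank below min_area after erosion")
    return SegmentedFrame(mask, frame_index)


def integrate_dic(image: np.ndarray, shear_direction=(1.0, 0.0)) -> np.ndarray:
    """Line-integrated DIC: cumulative sum along the prism shear direction.

    The frame is rotated so the shear direction is horizontal, rows are
    cumulatively summed, each output line's median is removed (suppressing
    the stripe artifact that integration of random noise produces), and
    the result is rotated back.  The output looks like a fluorescence
    image up to a constant spatial offset along the shear direction; the
    offset does not affect cell shape and is not corrected.
    """
    image = np.asarray(image, dtype=float)
    dx, dy = float(shear_direction[0]), float(shear_direction[1])
    norm = np.hypot(dx, dy)
    if not np.isclose(norm, 1.0, atol=1e-6):
        raise ValueError("shear_direction must be a unit vector")
    angle = np.degrees(np.arctan2(dy, dx))
    # work on the rotated image so integration lines are image rows
    if np.isclose(angle % 360, 0):
        work, inv = image, None
    elif np.isclose(angle % 360, 90):
        work, inv = np.rot90(image, k=1), lambda a: np.rot90(a, k=-1)
    elif np.isclose(angle % 360, 180):
        work, inv = np.rot90(image, k=2), lambda a: np.rot90(a, k=-2)
    elif np.isclose(angle % 360, 270):
        work, inv = np.rot90(image, k=-1), lambda a: np.rot90(a, k=1)
    else:
        work = ndi.rotate(image, angle, reshape=False, order=1, mode="nearest")
        inv = lambda a: ndi.rotate(a, -angle, reshape=False, order=1,
                                   mode="nearest")
    out = np.cumsum(work, axis=1)
    # stripe suppression: integration of noise leaves per-line constant
    # offsets; the per-line median estimates the background level without
    # being biased by the cell, so subtracting it cancels the stripes
    out = out - np.median(out, axis=1, keepdims=True)
    return inv(out) if inv is not None else out


def denoise_tv(image: np.ndarray, weight: float = 0.1,
               max_iter: int = 200, tol: float = 2e-4) -> np.ndarray:
    """Total-variation (Rudin-Osher-Fatemi) denoising of one frame.

    Minimises the usual TV energy with the Chambolle dual algorithm; the
    total variation of the output never exceeds that of the input.  If
    the iteration cap is hit before the duality-gap tolerance, the best
    iterate is returned with a warning rather than raising.
    """
    if weight <= 0:
        raise ValueError("weight must be > 0")
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        return image.copy()
    out = denoise_tv_chambolle(image, weight=weight, max_num_iter=max_iter,
                               eps=tol)
    # Chambolle's algorithm returns its last iterate regardless; flag runs
    # where TV failed to drop as non-converged.
    def tv(a):
        return np.abs(np.diff(a, axis=0)).sum() + np.abs(np.diff(a, axis=1)).sum()
    if tv(out) > tv(image) + 1e-9:
        warnings.warn("TV denoising did not reduce total variation; "
                      "returning best iterate", stacklevel=2)
    return out


def segment_dic(image: np.ndarray, shear_direction=(1.0, 0.0),
                pipeline_variant: str = "denoise_first",
                min_area: int = 50, tv_weight: float = 0.1,
                frame_index: int = 0) -> SegmentedFrame:
    """Segment a DIC frame through line integration.

    ``denoise_first`` applies TV denoising to the raw differential image
    before integration; ``texture_after`` integrates first and removes
    the texture (noise) component of the pseudo-fluorescent image by TV
    regularisation afterwards.  Both variants end in the fluorescence
    thresholding path and give closely similar masks.
    """
    if pipeline_variant not in ("denoise_first", "texture_after"):
        raise ValueError(f"unknown pipeline_variant {pipeline_variant!r}")
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        raise NoCellFound("constant image")
    if pipeline_variant == "denoise_first":
        pseudo = integrate_dic(denoise_tv(image, tv_weight), shear_direction)
    else:
        pseudo = denoise_tv(integrate_dic(image, shear_direction), tv_weight)
    return segment_fluorescence(pseudo, min_area=min_area,
                                frame_index=frame_index)


def segment_movie(movie: MovieStack, min_area: int = 50,
                  **kwargs) -> list[SegmentedFrame]:
    """Segment every frame of a movie with the modality-appropriate method."""
    out = []
    for i, frame in enumerate(movie.frames):
        if movie.modality == "fluorescence":
            out.append(segment_fluorescence(frame, min_area, frame_index=i))
        elif movie.modality == "phase_contrast":
            out.append(segment_phase_contrast(frame, min_area=min_area,
                                              frame_index=i, **kwargs))
        else:
            out.append(segment_dic(frame, min_area=min_area, frame_index=i,
                                   **kwargs))
    return out
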