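"""Gradient-based particle segmentation.

Particles are found by thresholding the Sobel gradient magnitude of the height
map rather than the heights themselves, which makes the detection robust to
residual background slope and offset: an additive tilt shifts every height but
contributes only a constant to the gradient.  The binary mask that results is
used for measurement on the *unmodified* heights.

Pipeline: Sobel magnitude -> threshold at ``threshold_factor x base`` (base =
4 x RMS of the gradient, a standard automatic Sobel-edge level) -> morphological
closing (3x3) -> hole filling -> opening (3x3) -> suppression of components
touching the image border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology, segmentation
from skimage.measure import label as sk_label

from .errors import NoParticleError, ParameterError
from .io_formats import HeightMap

# 3x3 Sobel kernels (correlation convention); gradient is in nm per pixel
# index, so thresholds behave identically across scan sizes.
SOBEL_COL = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_ROW = SOBEL_COL.T

#: multiplier on the gradient RMS used as the automatic base threshold
BASE_THRESHOLD_RMS_FACTOR = 4.0

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class ParticleMask:
    """Boolean particle mask aligned with its source HeightMap."""

    mask: np.ndarray
    threshold_factor: float
    base_threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class LabeledParticles:
    """8-connected labeling of a ParticleMask; label 0 is background."""

    labels: np.ndarray
    n_particles: int
    areas_px: np.ndarray   # areas_px[k-1] = pixel count of label k


def sobel_magnitude(hmap: HeightMap) -> np.ndarray:
    """Gradient magnitude ``sqrt(Gx**2 + Gy**2)`` from 3x3 Sobel kernels.

    One pass per axis (vertical and horizontal derivatives), borders handled
    by edge replication; same shape as the input.
    """
    h = hmap.heights
    gx = ndimage.correlate(h, SOBEL_COL, mode="nearest")
    gy = ndimage.correlate(h, SOBEL_ROW, mode="nearest")
    return np.hypot(gx, gy)


def base_threshold(hmap: HeightMap) -> float:
    """Automatic gradient threshold: RMS of the Sobel magnitude times 4."""
    g = sobel_magnitude(hmap)
    return BASE_THRESHOLD_RMS_FACTOR * float(np.sqrt(np.mean(g**2)))


def edge_pixels(hmap: HeightMap, threshold_factor: float) -> np.ndarray:
    """Raw thresholded edge map, before any morphology (monotone in the factor)."""
    if threshold_factor <= 0:
        raise ParameterError(f"threshold_factor must be > 0, got {threshold_factor}")
    g = sobel_magnitude(hmap)
    base = BASE_THRESHOLD_RMS_FACTOR * float(np.sqrt(np.mean(g**2)))
    return g >= threshold_factor * base


def detect_particles(hmap: HeightMap, threshold_factor: float = 1.0) -> ParticleMask:
    """Segment particles from the gradient magnitude.

    Parameters
    ----------
    threshold_factor : float
        User multiplier on the automatic base threshold (the "adjust
        threshold" stringency); must be > 0.
    """
    if threshold_factor <= 0:
        raise ParameterError(f"threshold_factor must be > 0, got {threshold_factor}")
    g = sobel_magnitude(hmap)
    base = BASE_THRESHOLD_RMS_FACTOR * float(np.sqrt(np.mean(g**2)))
    edges = g >= threshold_factor * base

    closed = morphology.closing(edges, footprint=_SQUARE3)
    filled = ndimage.binary_fill_holes(closed)
    opened = morphology.opening(filled, footprint=_SQUARE3)
    # drop components touching the border (8-connected)
    cleared = segmentation.clear_border(sk_label(opened, connectivity=2)) > 0
    return ParticleMask(mask=cleared, threshold_factor=threshold_factor, base_threshold=base)


def estimate_background(hmap: HeightMap, pmask: ParticleMask) -> float:
    """Mean height over pixels outside the detected particles, in nm."""
    outside = ~pmask.mask
    if not outside.any():
        raise NoParticleError("mask covers every pixel; no background to estimate")
    return float(hmap.heights[outside].mean())


def label_and_select_largest(pmask: ParticleMask) -> tuple[LabeledParticles, int]:
    """8-connected labeling; returns the labeling and the largest particle's label.

    Area ties are broken toward the smallest label id (first particle in
    row-major scan order), which makes the selection deterministic.
    """
    labels = sk_label(pmask.mask, connectivity=2)
    n = int(labels.max())
    if n == 0:
        raise NoParticleError("empty mask: no particle to select")
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    selected = int(np.argmax(areas)) + 1          # argmax returns first max
    return LabeledParticles(labels=labels, n_particles=n, areas_px=areas), selected


def intensity_threshold_mask(hmap: HeightMap, fraction_of_max: float) -> ParticleMask:
    """Conventional intensity thresholding baseline: keep pixels >= fraction x max.

    No morphology is applied; this exists as the comparison baseline against
    which the gradient detector's robustness is measured.
    """
    if not 0 < fraction_of_max < 1:
        raise ParameterError(f"fraction_of_max must be in (0, 1), got {fraction_of_max}")
    level = fraction_of_max * float(hmap.heights.max())
    return ParticleMask(
        mask=hmap.heights >= level,
        threshold_factor=fraction_of_max,
        base_threshold=level,
    )


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks (1.0 when both empty)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
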