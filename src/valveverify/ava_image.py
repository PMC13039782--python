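"""Aortic valve area from endoscope-style video frames.

Pipeline per frame: greyscale -> invert (the open orifice looks into the
dark ventricle, so after inversion it is the brightest region) -> min-max
normalise -> fixed intensity threshold -> hole filling -> removal of small
objects -> morphological closing -> circular valve-housing mask -> the two
largest connected components are the orifice -> pixel count to cm^2.

Threshold sensitivity: the extraction is repeated at 110% and 90% of the
threshold, giving a lower and an upper area limit respectively (on the
inverted image a higher threshold selects fewer pixels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu

from .synthetic_mockloop import FrameStack


@dataclass
class AvaImageConfig:
    threshold: float | None = None  # in (0,1); None -> Otsu per stack
    min_object_px: int = 50
    closing_radius_px: int = 2
    valve_center: tuple = (0.0, 0.0)  # (row, col) px
    valve_radius: float = 1.0  # px
    px_per_cm: float = 100.0
    sensitivity: tuple = (0.9, 1.1)

    def __post_init__(self):
        if self.threshold is not None and not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.valve_radius <= 0:
            raise ValueError("valve_radius must be positive")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")


@dataclass
class AVASeries:
    """Valve area over time with threshold-sensitivity envelopes (cm^2)."""

    t: np.ndarray
    area: np.ndarray
    area_lower: np.ndarray
    area_upper: np.ndarray

    def __post_init__(self):
        if np.any(self.area_lower > self.area + 1e-12) or np.any(self.area > self.area_upper + 1e-12):
            raise ValueError("envelope ordering violated: need lower <= area <= upper")

    def per_cycle_max(self, cycle_time: float) -> np.ndarray:
        """Maximum area in each complete cycle."""
        dt = self.t[1] - self.t[0]
        n = int(round(cycle_time / dt))
        n_cyc = len(self.t) // n
        return np.array([self.area[k * n:(k + 1) * n].max() for k in range(n_cyc)])


def preprocess_frame(frame: np.ndarray) -> np.ndarray:
    """Greyscale, invert and min-max normalise a frame to [0, 1]."""
    f = np.asarray(frame, dtype=float)
    if f.ndim == 3:
        f = f @ np.array([0.2125, 0.7154, 0.0721])  # Rec. 709 luma
    if f.max() > 1.0:
        f = f / 255.0
    inv = f.max() - f
    rng = inv.max() - inv.min()
    if rng <= 0:
        warnings.warn("constant frame; returning all-zeros", stacklevel=2)
        return np.zeros_like(inv)
    return (inv - inv.min()) / rng


def binarize_and_clean(grid: np.ndarray, cfg: AvaImageConfig, threshold: float | None = None) -> np.ndarray:
    """Threshold a normalised grid and tidy the mask.

    Order: threshold, fill holes, drop components below ``min_object_px``,
    morphological closing, then zero everything outside the valve circle.
    """
    theta = cfg.threshold if threshold is None else threshold
    if theta is None:
        raise ValueError("no threshold available")
    mask = grid > theta
    mask = ndimage.binary_fill_holes(mask)
    labels, nlab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if nlab:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
        keep = np.flatnonzero(sizes >= cfg.min_object_px) + 1
        mask = np.isin(labels, keep)
    if cfg.closing_radius_px > 0:
        mask = morphology.closing(mask, morphology.disk(cfg.closing_radius_px))
    rr, cc = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    circ = (rr - cfg.valve_center[0]) ** 2 + (cc - cfg.valve_center[1]) ** 2 <= cfg.valve_radius**2
    return mask & circ


def two_largest_area(mask: np.ndarray, px_per_cm: float) -> float:
    """Area (cm^2) of the two largest 8-connected components of a mask."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return 0.0
    sizes = np.sort(ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1)))[::-1]
    n_px = sizes[:2].sum()
    return float(n_px) / px_per_cm**2


def extract_frame_area(frame: np.ndarray, cfg: AvaImageConfig, threshold: float | None = None) -> float:
    grid = preprocess_frame(frame)
    mask = binarize_and_clean(grid, cfg, threshold)
    return two_largest_area(mask, cfg.px_per_cm)


def ava_series_with_bounds(frames: FrameStack, cfg: AvaImageConfig) -> AVASeries:
    """AVA over time with 90%/110% threshold envelopes.

    The nominal area uses threshold theta, the lower envelope 1.1 theta
    (fewer pixels pass a higher threshold on the inverted image) and the
    upper envelope 0.9 theta.  If no fixed threshold is configured, Otsu's
    threshold of the brightest preprocessed frame is used for the whole
    stack.
    """
    theta = cfg.threshold
    if theta is None:
        grids = [preprocess_frame(f) for f in frames.frames]
        ref = grids[int(np.argmax([g.mean() for g in grids]))]
        theta = float(threshold_otsu(ref))
    lo_mult, hi_mult = min(cfg.sensitivity), max(cfg.sensitivity)
    theta_hi = hi_mult * theta
    if theta_hi >= 1.0:
        warnings.warn("upper sensitivity threshold >= 1; clamping", stacklevel=2)
        theta_hi = np.nextafter(1.0, 0.0)
    stack_cfg = AvaImageConfig(threshold=None, min_object_px=cfg.min_object_px,
                               closing_radius_px=cfg.closing_radius_px,
                               valve_center=frames.valve_center, valve_radius=frames.valve_radius,
                               px_per_cm=frames.px_per_cm, sensitivity=cfg.sensitivity)
    area, lower, upper = [], [], []
    for f in frames.frames:
        grid = preprocess_frame(f)
        area.append(two_largest_area(binarize_and_clean(grid, stack_cfg, theta), frames.px_per_cm))
        lower.append(two_largest_area(binarize_and_clean(grid, stack_cfg, theta_hi), frames.px_per_cm))
        upper.append(two_largest_area(binarize_and_clean(grid, stack_cfg, lo_mult * theta), frames.px_per_cm))
    return AVASeries(t=frames.timestamps.copy(), area=np.array(area),
                     area_lower=np.minimum(lower, area), area_upper=np.maximum(upper, area))
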