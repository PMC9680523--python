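"""Per-slice lumen segmentation: Otsu threshold, morphology, contour smoothing."""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage.measure import label
from skimage.morphology import closing, footprint_rectangle, opening

from .core import PolarStack, RadialContour, bin_to_radius, periodic_fill


def otsu_threshold(frame: np.ndarray) -> int:
    """Gray level maximizing between-class variance over all 256 candidates.

    The frame is binned to integer levels 0..255; the returned threshold
    ``t`` separates background (level <= t) from foreground (level > t) and
    is the lowest level attaining the maximal between-class variance.
    A constant frame has no two classes and raises ``ValueError``.
    """
    levels = np.clip(np.rint(np.asarray(frame, dtype=float)), 0, 255).astype(int)
    hist = np.bincount(levels.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: frame has fewer than 2 gray levels")
    p = hist / hist.sum()
    omega0 = np.cumsum(p)                      # P(level <= t), t = 0..255
    mu = np.cumsum(p * np.arange(256))
    mu_total = mu[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega0 - mu) ** 2 / (omega0 * omega1)
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))             # argmax takes the lowest tie


def segment_lumen(frame: np.ndarray, threshold: float,
                  radial_spacing: float = 0.0045,
                  slice_index: int = 0) -> RadialContour:
    """Extract the lumen boundary of one polar frame.

    The frame is binarized at ``threshold`` (tissue = brighter), cleaned by
    morphological opening then closing with a 4-pixel-wide square element to
    erase small noise specks and jump points, and reduced to the largest
    connected tissue component. The lumen radius per A-line is the radius of
    the first remaining tissue pixel; A-lines with no tissue are marked
    invalid (interpolated later).
    """
    tissue = np.asarray(frame, dtype=float) > threshold
    # wrap-pad the angle axis so morphology and labeling see the closed ring
    pad = 8
    t3 = np.concatenate([tissue[-pad:], tissue, tissue[:pad]], axis=0)
    elem = footprint_rectangle((4, 4))
    t3 = opening(t3, elem)
    t3 = closing(t3, elem)
    cleaned = t3[pad:-pad]
    cleaned = _largest_component_wrap(cleaned)
    n_angle, n_rad = cleaned.shape
    first = np.argmax(cleaned, axis=1)
    valid = cleaned.any(axis=1)
    radii = bin_to_radius(first, radial_spacing)
    radii[~valid] = radial_spacing  # placeholder, flagged invalid
    return RadialContour(radii=radii, valid=valid, slice_index=slice_index)


def _largest_component_wrap(mask: np.ndarray) -> np.ndarray:
    """Largest connected tissue component, treating the angle axis as circular."""
    lab = label(mask, connectivity=2)
    if lab.max() == 0:
        return mask
    # union labels that touch across the angular wrap (row 0 vs last row)
    parent = {i: i for i in range(1, lab.max() + 1)}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in zip(lab[0], lab[-1]):
        if a > 0 and b > 0:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    roots = np.zeros(lab.max() + 1, dtype=int)
    for i in range(1, lab.max() + 1):
        roots[i] = find(i)
    merged = roots[lab]
    sizes = np.bincount(merged.ravel())
    sizes[0] = 0
    return merged == np.argmax(sizes)


def smooth_contour(contour: RadialContour, bandwidth: int = 50) -> RadialContour:
    """Circular centered moving average of the contour radii.

    Invalid bins are pre-filled by periodic linear interpolation, then a
    wrap-around boxcar of ``bandwidth`` angle bins is applied. The operator
    is linear and preserves the circular mean of the radii to floating
    tolerance; the output is valid at every bin.
    """
    n = contour.n_angle_bins
    if not (1 <= bandwidth < n):
        raise ValueError("bandwidth must be in [1, n_angle_bins)")
    if int(contour.valid.sum()) < min(bandwidth, n):
        raise ValueError("contour must be valid on at least `bandwidth` bins")
    radii = periodic_fill(contour.radii, contour.valid)
    smoothed = uniform_filter1d(radii, size=bandwidth, mode="wrap")
    return RadialContour(radii=smoothed, valid=np.ones(n, dtype=bool),
                         slice_index=contour.slice_index)


def detect_lumen(stack: PolarStack, bandwidth: int = 50,
                 threshold: Optional[float] = None) -> list[RadialContour]:
    """Otsu -> morphology -> largest component -> 50-bin smoothing, per slice.

    Guidewire-masked A-lines (if the stack carries a mask) are forced
    invalid before smoothing so the shadowed arc is interpolated across.
    """
    out = []
    for s in range(stack.n_slices):
        thr = otsu_threshold(stack.frames[s]) if threshold is None else threshold
        contour = segment_lumen(stack.frames[s], thr, stack.radial_spacing, s)
        if stack.guidewire_mask is not None:
            contour.valid &= ~stack.guidewire_mask[s]
        if not contour.valid.any():
            raise ValueError(f"slice {s}: no usable lumen boundary")
        out.append(smooth_contour(contour, bandwidth))
    return out
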