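"""Intensity windowing, guidewire masking, polar stacking and lumen flattening.

Flattening circularly shifts every A-line so the lumen boundary sits at
radial bin 0; layer boundaries then live at nearly constant depth, which is
what makes 2D edge detection across angle effective. The shift is by whole
bins and every offset is recorded, so unflattening is an exact inverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .core import PolarStack, RadialContour, periodic_fill, radius_to_bin


@dataclass
class WindowConfig:
    """Linear gray-level window: [low, high] maps to [0, 255] with clipping."""

    window_low: float = 0.0
    window_high: float = 255.0

    def __post_init__(self) -> None:
        if not self.window_low < self.window_high:
            raise ValueError("window_low must be < window_high")


def window_intensity(stack: PolarStack, cfg: WindowConfig) -> PolarStack:
    """Rescale intensities so [low, high] spans the full 0-255 range.

    The map is monotone non-decreasing pixelwise; values at or below ``low``
    become 0 and values at or above ``high`` become 255. No rounding is
    applied (frames are floating point), so windowing with [0, 255] is the
    identity.
    """
    out = stack.copy()
    scale = 255.0 / (cfg.window_high - cfg.window_low)
    out.frames = np.clip((out.frames - cfg.window_low) * scale, 0.0, 255.0)
    return out


def detect_guidewire(stack: PolarStack, rel_threshold: float = 0.3,
                     min_width_bins: int = 5,
                     dead_zone_bins: int = 25) -> np.ndarray:
    """Flag A-lines shadowed by the guidewire.

    The guidewire casts a near-total radial shadow, so its A-lines carry far
    less integrated signal than their neighbours. Per slice, the summed
    intensity beyond the catheter dead zone is compared with the slice
    median; contiguous (circularly) runs of at least ``min_width_bins``
    A-lines below ``rel_threshold`` times the median are flagged.

    Returns a boolean (n_slices, n_angle_bins) mask; an all-dark slice is
    flagged entirely (unusable).
    """
    if stack.n_slices == 0:
        raise ValueError("empty stack")
    sums = stack.frames[:, :, dead_zone_bins:].sum(axis=2)
    mask = np.zeros(sums.shape, dtype=bool)
    for s in range(stack.n_slices):
        med = np.median(sums[s])
        if med <= 0:
            mask[s] = True
            continue
        low = sums[s] < rel_threshold * med
        mask[s] = _filter_short_runs(low, min_width_bins)
    return mask


def _filter_short_runs(flags: np.ndarray, min_len: int) -> np.ndarray:
    """Keep only circular runs of True of length >= min_len."""
    n = flags.size
    if flags.all():
        return flags.copy()
    out = np.zeros(n, dtype=bool)
    # rotate so position 0 is False, making runs non-wrapping
    start = int(np.argmin(flags))
    rot = np.roll(flags, -start)
    d = np.diff(np.concatenate([[0], rot.astype(int), [0]]))
    for b, e in zip(np.where(d == 1)[0], np.where(d == -1)[0]):
        if e - b >= min_len:
            out[(np.arange(b, e) + start) % n] = True
    return out


@dataclass
class FlattenOffsets:
    """Integer per-(slice, angle) radial shifts recorded for exact inversion."""

    offsets: np.ndarray  # int, (n_slices, n_angle_bins)

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)


def flatten_to_lumen(stack: PolarStack, lumen: Sequence[RadialContour]
                     ) -> Tuple[PolarStack, FlattenOffsets]:
    """Circularly shift each A-line so the lumen boundary sits at bin 0.

    ``lumen`` must hold one complete (post-smoothing) contour per slice. The
    shift is the nearest radial bin to the lumen radius; the subpixel
    contour itself is kept separately by callers, so no precision is lost.
    """
    if len(lumen) != stack.n_slices:
        raise ValueError("one lumen contour per slice required")
    nr = stack.n_radial_bins
    offsets = np.empty((stack.n_slices, stack.n_angle_bins), dtype=int)
    flat = stack.copy()
    cols = np.arange(nr)
    for s, contour in enumerate(lumen):
        radii = periodic_fill(contour.radii, contour.valid)
        k = np.rint(radius_to_bin(radii, stack.radial_spacing)).astype(int)
        if np.any(k >= nr) or np.any(k < 0):
            raise ValueError(f"lumen radius out of frame depth on slice {s}")
        offsets[s] = k
        idx = (cols[None, :] + k[:, None]) % nr
        flat.frames[s] = stack.frames[s][np.arange(stack.n_angle_bins)[:, None], idx]
    return flat, FlattenOffsets(offsets)


def unflatten_depths(depths: np.ndarray, offsets: FlattenOffsets,
                     slice_index: int) -> np.ndarray:
    """Map flattened-frame depths (bins) back to absolute radial bins."""
    d = np.asarray(depths, dtype=float)
    if d.shape[-1] != offsets.offsets.shape[1]:
        raise ValueError("angle-bin count mismatch with offset record")
    return d + offsets.offsets[slice_index]


def unflatten_stack(flat: PolarStack, offsets: FlattenOffsets) -> PolarStack:
    """Exact inverse of :func:`flatten_to_lumen` on the image stack."""
    if offsets.offsets.shape[0] != flat.n_slices:
        raise ValueError("slice count mismatch with offset record")
    nr = flat.n_radial_bins
    out = flat.copy()
    cols = np.arange(nr)
    for s in range(flat.n_slices):
        idx = (cols[None, :] - offsets.offsets[s][:, None]) % nr
        out.frames[s] = flat.frames[s][np.arange(flat.n_angle_bins)[:, None], idx]
    return out


def cartesian_to_polar(frames_xy: np.ndarray, radial_spacing: float,
                       slice_spacing: float = 0.2,
                       n_angle_bins: int = 360,
                       n_radial_bins: Optional[int] = None,
                       center: Optional[Tuple[float, float]] = None) -> PolarStack:
    """Resample Cartesian frames (slice, y, x) to the internal polar layout.

    Bilinear resampling about ``center`` (pixel coordinates, defaults to the
    frame center). ``radial_spacing`` keeps its mm/pixel meaning assuming
    square Cartesian pixels of the same pitch.
    """
    frames_xy = np.asarray(frames_xy, dtype=float)
    if frames_xy.ndim == 2:
        frames_xy = frames_xy[None]
    ns, ny, nx = frames_xy.shape
    cy, cx = center if center is not None else ((ny - 1) / 2.0, (nx - 1) / 2.0)
    if n_radial_bins is None:
        n_radial_bins = int(min(ny, nx) // 2)
    theta = 2 * np.pi * np.arange(n_angle_bins) / n_angle_bins
    rad = np.arange(n_radial_bins) + 0.5
    yy = cy + rad[None, :] * np.sin(theta)[:, None]
    xx = cx + rad[None, :] * np.cos(theta)[:, None]
    out = np.empty((ns, n_angle_bins, n_radial_bins), dtype=np.float32)
    for s in range(ns):
        out[s] = map_coordinates(frames_xy[s], [yy, xx], order=1, mode="constant")
    return PolarStack(np.clip(out, 0, 255), radial_spacing, slice_spacing)
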