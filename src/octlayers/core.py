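"""Core in-memory containers shared by the segmentation pipeline.

Conventions used everywhere in this package:

* a polar frame is a 2D array indexed ``(angle bin, radial bin)``;
* a pullback is a 3D stack indexed ``(slice, angle bin, radial bin)``;
* angle bin 0 sits at angle 0 and angles increase counterclockwise;
* radius is measured from the catheter center, and the radius attached to
  radial bin ``j`` is the bin center ``(j + 0.5) * radial_spacing`` in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

BOUNDARIES = ("lumen", "IEM", "EEM", "ADV")
#: wall boundaries detected by edge tracking (the lumen has its own detector)
WALL_BOUNDARIES = ("IEM", "EEM", "ADV")


def angle_grid(n_angle_bins: int) -> np.ndarray:
    """Angle (radians) of each angle-bin center, ``2*pi*i/n``."""
    return 2.0 * np.pi * np.arange(n_angle_bins) / n_angle_bins


def bin_to_radius(bins, radial_spacing: float):
    """Radius (mm) of (possibly fractional) radial-bin coordinates."""
    return (np.asarray(bins, dtype=float) + 0.5) * radial_spacing


def radius_to_bin(radius_mm, radial_spacing: float):
    """Fractional radial-bin coordinate of a radius in mm."""
    return np.asarray(radius_mm, dtype=float) / radial_spacing - 0.5


@dataclass
class PolarStack:
    """An OCT pullback stacked in polar coordinates.

    Parameters
    ----------
    frames
        Intensity grid ``(n_slices, n_angle_bins, n_radial_bins)`` on a
        0-255 gray scale (stored as float for processing headroom).
    radial_spacing
        Physical size of one radial bin, mm/pixel.
    slice_spacing
        Pullback step between consecutive frames, mm.
    guidewire_mask
        Optional boolean ``(n_slices, n_angle_bins)`` array; ``True`` marks
        A-lines shadowed by the guidewire (excluded from edge acceptance).
    """

    frames: np.ndarray
    radial_spacing: float
    slice_spacing: float = 0.2
    guidewire_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (slice, angle, radial)")
        if self.radial_spacing <= 0:
            raise ValueError("radial_spacing must be positive")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < -1e-6 or hi > 255 + 1e-3:
            raise ValueError(f"intensities out of [0, 255]: [{lo}, {hi}]")

    @property
    def n_slices(self) -> int:
        return self.frames.shape[0]

    @property
    def n_angle_bins(self) -> int:
        return self.frames.shape[1]

    @property
    def n_radial_bins(self) -> int:
        return self.frames.shape[2]

    @property
    def angles(self) -> np.ndarray:
        return angle_grid(self.n_angle_bins)

    @property
    def max_radius(self) -> float:
        """Outer edge of the imaged field, mm."""
        return self.n_radial_bins * self.radial_spacing

    def copy(self) -> "PolarStack":
        gw = None if self.guidewire_mask is None else self.guidewire_mask.copy()
        return replace(self, frames=self.frames.copy(), guidewire_mask=gw)


@dataclass
class RadialContour:
    """A closed per-slice boundary sampled as radius vs angle bin.

    ``valid`` flags angle bins where the radius is actually observed;
    invalid bins (guidewire shadow, missing tissue) carry a placeholder
    radius and are interpolated across before smoothing.
    """

    radii: np.ndarray  # mm, shape (n_angle_bins,)
    valid: np.ndarray  # bool, same shape
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.radii.shape != self.valid.shape or self.radii.ndim != 1:
            raise ValueError("radii and valid must be matching 1D arrays")
        if np.any(self.radii[self.valid] <= 0):
            raise ValueError("valid radii must be positive")

    @property
    def n_angle_bins(self) -> int:
        return self.radii.size

    def copy(self) -> "RadialContour":
        return RadialContour(self.radii.copy(), self.valid.copy(), self.slice_index)


@dataclass
class LayerContourSet:
    """The four boundaries of one slice, ordered radially outward."""

    lumen: RadialContour
    iem: RadialContour
    eem: RadialContour
    adv: RadialContour
    slice_index: int = 0

    def as_dict(self) -> Dict[str, RadialContour]:
        return {"lumen": self.lumen, "IEM": self.iem, "EEM": self.eem, "ADV": self.adv}

    def ordering_ok(self) -> np.ndarray:
        """Boolean per angle bin: lumen < IEM < EEM < ADV strictly."""
        r = np.vstack([self.lumen.radii, self.iem.radii, self.eem.radii, self.adv.radii])
        return np.all(np.diff(r, axis=0) > 0, axis=0)


@dataclass
class ContourSurface:
    """One boundary's radius over the (angle, slice) grid with known-sample mask.

    This is the object the spline repair completes: angle-periodic,
    holes (``known == False``) correspond to occluded arcs.
    """

    radii: np.ndarray  # mm, shape (n_angle_bins, n_slices)
    known: np.ndarray  # bool, same shape
    boundary: str = "IEM"
    radial_spacing: float = 0.0045

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.known = np.asarray(self.known, dtype=bool)
        if self.radii.shape != self.known.shape or self.radii.ndim != 2:
            raise ValueError("radii and known must be matching 2D (angle, slice) arrays")
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"boundary must be one of {BOUNDARIES}")
        vals = self.radii[self.known]
        if vals.size and np.any(vals <= 0):
            raise ValueError("known radii must be positive")

    @property
    def n_angle_bins(self) -> int:
        return self.radii.shape[0]

    @property
    def n_slices(self) -> int:
        return self.radii.shape[1]

    @property
    def known_fraction(self) -> float:
        return float(self.known.mean())

    def copy(self) -> "ContourSurface":
        return ContourSurface(self.radii.copy(), self.known.copy(), self.boundary,
                              self.radial_spacing)


@dataclass
class GroundTruth:
    """Known layer geometry of a synthetic pullback.

    ``shadow_mask[s, a]`` is True where a lipid-shadow sector makes the deep
    boundaries (IEM/EEM/ADV) unobservable; ``guidewire_mask`` marks the
    guidewire sector.
    """

    contours: List[LayerContourSet]
    shadow_mask: np.ndarray
    guidewire_mask: np.ndarray

    @property
    def n_slices(self) -> int:
        return len(self.contours)

    def boundary_grid(self, boundary: str) -> np.ndarray:
        """Radii of one boundary over (angle, slice), mm."""
        key = {"lumen": "lumen", "IEM": "iem", "EEM": "eem", "ADV": "adv"}[boundary]
        return np.stack([getattr(c, key).radii for c in self.contours], axis=1)


def periodic_fill(radii: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid bins of a circular signal by periodic linear interpolation."""
    valid = np.asarray(valid, bool)
    if valid.all():
        return np.asarray(radii, float).copy()
    if not valid.any():
        raise ValueError("cannot interpolate a contour with no valid bins")
    n = radii.size
    idx = np.arange(n)
    # unwrap the circle: replicate valid samples one period left and right
    xv = idx[valid]
    yv = radii[valid]
    x_ext = np.concatenate([xv - n, xv, xv + n])
    y_ext = np.concatenate([yv, yv, yv])
    out = np.asarray(radii, float).copy()
    out[~valid] = np.interp(idx[~valid], x_ext, y_ext)
    return out
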