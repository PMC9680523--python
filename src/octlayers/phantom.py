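"""Synthetic OCT pullback generator with known ground truth.

The phantom emulates the radial intensity signature an intravascular OCT
catheter records across a coronary wall: a dark lumen, a bright (thickened)
intima, a dark media and a bright adventitia over dim periadventitial
tissue — the "light-dark-light" pattern that makes layer segmentation
possible — modulated by exponential depth attenuation, multiplicative
speckle, lipid-shadow sectors where the deep wall vanishes, and a guidewire
shadow sector.

Every boundary is a smooth low-order Fourier series in angle plus a
band-limited drift along the pullback, so slice-to-slice continuity (the
assumption behind seed-edge propagation) holds by construction, and the
exact boundary radii are returned as :class:`~octlayers.core.GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (BOUNDARIES, GroundTruth, LayerContourSet, PolarStack,
                   RadialContour, angle_grid, bin_to_radius)


@dataclass
class BoundaryModel:
    """Radius-vs-angle model of one boundary: Fourier series + slice drift.

    r(theta, s) = mean_radius
                  + sum_k fourier[k].amp * cos((k+1)*theta + fourier[k].phase)
                  + drift_amp * sin(2*pi*s/n_slices + drift_phase)
    """

    mean_radius: float  # mm
    fourier: Sequence[Tuple[float, float]] = ()  # (amplitude mm, phase rad) per order
    drift_amp: float = 0.0  # mm
    drift_phase: float = 0.0

    def radii(self, angles: np.ndarray, n_slices: int) -> np.ndarray:
        """Boundary radius grid, shape (n_slices, n_angle)."""
        r = np.full((n_slices, angles.size), self.mean_radius)
        for k, (amp, phase) in enumerate(self.fourier):
            r += amp * np.cos((k + 1) * angles + phase)[None, :]
        s = np.arange(n_slices)
        r += (self.drift_amp * np.sin(2 * np.pi * s / max(n_slices, 1)
                                      + self.drift_phase))[:, None]
        return r


@dataclass
class ShadowSector:
    """A lipid-shadow region: signal suppressed beyond ``depth_mm``.

    ``slice_range`` and ``angle_range_deg`` are half-open ``[start, stop)``;
    the angle range may wrap past 360.
    """

    slice_range: Tuple[int, int]
    angle_range_deg: Tuple[float, float]
    depth_mm: float
    suppression: float = 0.02

    def angle_mask(self, n_angle_bins: int) -> np.ndarray:
        deg = np.degrees(angle_grid(n_angle_bins))
        a0, a1 = self.angle_range_deg
        if a1 >= a0:
            return (deg >= a0) & (deg < a1)
        return (deg >= a0) | (deg < a1 % 360.0)

    def slice_mask(self, n_slices: int) -> np.ndarray:
        s = np.arange(n_slices)
        return (s >= self.slice_range[0]) & (s < self.slice_range[1])


@dataclass
class PhantomSpec:
    """Full description of a synthetic pullback.

    Defaults model a diseased coronary segment at the scale the analysis
    pipeline targets: 4.5 um radial pixels, a ~0.85 mm mean lumen radius and
    layer thicknesses near the population means reported for thickened
    intima (~0.65 mm), media (~0.24 mm) and adventitia (~0.22 mm).
    """

    n_slices: int = 60
    n_angle_bins: int = 360
    n_radial_bins: int = 500
    radial_spacing: float = 0.0045  # mm/pixel
    slice_spacing: float = 0.2  # mm
    boundary_models: Dict[str, BoundaryModel] = field(default_factory=lambda: {
        "lumen": BoundaryModel(0.85, [(0.06, 0.3), (0.030, 1.1)], 0.040, 0.0),
        "IEM": BoundaryModel(1.50, [(0.05, 0.5), (0.025, 2.0)], 0.035, 0.7),
        "EEM": BoundaryModel(1.74, [(0.045, 0.8), (0.020, 2.6)], 0.030, 1.2),
        "ADV": BoundaryModel(1.96, [(0.040, 1.0), (0.018, 3.1)], 0.030, 1.8),
    })
    layer_intensities: Dict[str, float] = field(default_factory=lambda: {
        "lumen": 8.0, "intima": 185.0, "media": 70.0,
        "adventitia": 150.0, "periadventitia": 30.0,
    })
    attenuation_coeff: float = 0.5  # per mm, beyond the lumen boundary
    speckle_sigma: float = 0.15
    shadow_sectors: List[ShadowSector] = field(default_factory=lambda: [
        ShadowSector((8, 28), (30.0, 140.0), 1.20, 0.02),
        ShadowSector((35, 55), (200.0, 300.0), 1.25, 0.02),
    ])
    guidewire_sector: Optional[Tuple[float, float, float]] = (262.0, 277.0, 0.05)
    #: (angle start deg, angle stop deg, suppression factor); None disables it
    rng_seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        li = self.layer_intensities
        if not (li["intima"] > li["media"] and li["adventitia"] > li["media"]):
            raise ValueError("layer intensities must be light-dark-light "
                             "(intima > media and adventitia > media)")
        angles = angle_grid(self.n_angle_bins)
        prev = np.zeros((self.n_slices, self.n_angle_bins))
        for name in BOUNDARIES:
            r = self.boundary_models[name].radii(angles, self.n_slices)
            if np.any(r <= prev):
                raise ValueError(f"boundary ordering violated at {name}: "
                                 "lumen < IEM < EEM < ADV must hold everywhere")
            prev = r
        if np.any(prev >= self.n_radial_bins * self.radial_spacing):
            raise ValueError("ADV boundary exceeds the imaged depth")


def _boundary_grids(spec: PhantomSpec) -> Dict[str, np.ndarray]:
    angles = angle_grid(spec.n_angle_bins)
    return {name: spec.boundary_models[name].radii(angles, spec.n_slices)
            for name in BOUNDARIES}


def degrade_with_shadow(stack: PolarStack,
                        sectors: Sequence[ShadowSector]) -> PolarStack:
    """Suppress signal beyond each sector's depth, emulating lipid occlusion.

    Pixels inside a sector and deeper than ``depth_mm`` are multiplied by the
    sector's suppression factor; everything else is untouched. An empty
    sector list returns an identical copy.
    """
    out = stack.copy()
    radii = bin_to_radius(np.arange(stack.n_radial_bins), stack.radial_spacing)
    for sec in sectors:
        if not (0 <= sec.slice_range[0] <= sec.slice_range[1] <= stack.n_slices):
            raise ValueError(f"shadow sector slices {sec.slice_range} out of bounds")
        amask = sec.angle_mask(stack.n_angle_bins)
        smask = sec.slice_mask(stack.n_slices)
        rmask = radii > sec.depth_mm
        sub = out.frames[np.ix_(np.where(smask)[0], np.where(amask)[0],
                                np.where(rmask)[0])]
        out.frames[np.ix_(np.where(smask)[0], np.where(amask)[0],
                          np.where(rmask)[0])] = sub * sec.suppression
    return out


def generate_phantom(spec: PhantomSpec) -> Tuple[PolarStack, GroundTruth]:
    """Render a synthetic pullback and return it with its ground truth.

    The noise-free radial profile at any angle goes up (intima), down
    (media), up (adventitia) and down again — two local maxima with the
    media minimum in between — and decays exponentially with depth beyond
    the lumen. Speckle is mean-one multiplicative log-normal noise, so
    sample means estimate the noise-free intensities. Regeneration with the
    same spec (seed included) is bit-identical.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    grids = _boundary_grids(spec)
    radii = bin_to_radius(np.arange(spec.n_radial_bins), spec.radial_spacing)
    li = spec.layer_intensities

    frames = np.empty((spec.n_slices, spec.n_angle_bins, spec.n_radial_bins),
                      dtype=np.float32)
    for s in range(spec.n_slices):
        r_lum = grids["lumen"][s][:, None]
        r_iem = grids["IEM"][s][:, None]
        r_eem = grids["EEM"][s][:, None]
        r_adv = grids["ADV"][s][:, None]
        r = radii[None, :]
        base = np.select(
            [r < r_lum, r < r_iem, r < r_eem, r < r_adv],
            [li["lumen"], li["intima"], li["media"], li["adventitia"]],
            default=li["periadventitia"])
        depth = np.clip(r - r_lum, 0.0, None)
        frames[s] = base * np.exp(-spec.attenuation_coeff * depth)

    stack = PolarStack(frames, spec.radial_spacing, spec.slice_spacing)
    stack = degrade_with_shadow(stack, spec.shadow_sectors)

    gw_mask = np.zeros((spec.n_slices, spec.n_angle_bins), dtype=bool)
    if spec.guidewire_sector is not None:
        a0, a1, factor = spec.guidewire_sector
        sec = ShadowSector((0, spec.n_slices), (a0, a1), 0.05, factor)
        gw_mask[:] = sec.angle_mask(spec.n_angle_bins)[None, :]
        stack = degrade_with_shadow(stack, [sec])

    if spec.speckle_sigma > 0:
        sig = spec.speckle_sigma
        noise = rng.standard_normal(stack.frames.shape).astype(np.float32)
        stack.frames *= np.exp(sig * noise - 0.5 * sig * sig)
    np.clip(stack.frames, 0.0, 255.0, out=stack.frames)

    shadow_mask = np.zeros((spec.n_slices, spec.n_angle_bins), dtype=bool)
    for sec in spec.shadow_sectors:
        shadow_mask[np.ix_(sec.slice_mask(spec.n_slices),
                           sec.angle_mask(spec.n_angle_bins))] = True

    contours = []
    full = np.ones(spec.n_angle_bins, dtype=bool)
    for s in range(spec.n_slices):
        contours.append(LayerContourSet(
            lumen=RadialContour(grids["lumen"][s], full.copy(), s),
            iem=RadialContour(grids["IEM"][s], full.copy(), s),
            eem=RadialContour(grids["EEM"][s], full.copy(), s),
            adv=RadialContour(grids["ADV"][s], full.copy(), s),
            slice_index=s))
    truth = GroundTruth(contours=contours, shadow_mask=shadow_mask,
                        guidewire_mask=gw_mask)
    return stack, truth


def region_masks(spec: PhantomSpec, truth: GroundTruth,
                 stack: PolarStack) -> Dict[str, np.ndarray]:
    """Boolean per-pixel masks of the five true regions (for evaluation)."""
    radii = bin_to_radius(np.arange(stack.n_radial_bins), stack.radial_spacing)
    r = radii[None, None, :]
    g = {b: truth.boundary_grid(b).T[:, :, None] for b in BOUNDARIES}
    return {
        "lumen": r < g["lumen"],
        "intima": (r >= g["lumen"]) & (r < g["IEM"]),
        "media": (r >= g["IEM"]) & (r < g["EEM"]),
        "adventitia": (r >= g["EEM"]) & (r < g["ADV"]),
        "periadventitia": r >= g["ADV"],
    }
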