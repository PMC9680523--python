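"""Layered arterial constitutive model and in-vivo geometry pre-shrink.

Vessel tissue is modeled as hyperelastic, anisotropic and incompressible
with a modified Mooney-Rivlin strain-energy density:

    W_iso   = c1 (I1 - 3) + c2 (I2 - 3) + D1 [exp(D2 (I1 - 3)) - 1]
    W_aniso = W_iso + (K1 / K2) {exp[K2 (I4 - 1)^2] - 1}

where I1, I2 are the invariants of the right Cauchy-Green tensor C = F'F
and I4 = lam_theta^2 cos^2(phi) + lam_z^2 sin^2(phi) measures stretch along
a fiber family at angle phi from the circumferential direction in the
theta-z plane. The lipid core is isotropic (W_iso only).

Uniaxial Cauchy stress is derived under incompressibility with traction-
free lateral directions: the free in-plane stretch solves the lateral
equilibrium dW/dlam_lateral = 0 and sigma = lam * dW_hat/dlam along the
loaded direction (envelope theorem). Finite-element solving is out of
scope; only the constitutive response and the geometric pre-shrink used to
estimate the unloaded in vivo configuration are provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .core import LayerContourSet, RadialContour

TISSUES = ("lipid", "intima", "media", "adventitia")


@dataclass(frozen=True)
class MaterialParams:
    """Modified Mooney-Rivlin parameters of one tissue.

    c1, c2, D1 and K1 are in kPa; D2, K2 are dimensionless; phi_deg is the
    fiber angle from the circumferential direction (ignored when
    ``isotropic``).
    """

    tissue: str
    c1: float
    c2: float
    D1: float
    D2: float
    K1: float = 0.0
    K2: float = 1.0
    phi_deg: float = 0.0
    isotropic: bool = False


#: Literature parameter sets shipped with the package (kPa / dimensionless).
#: The intima set carries fiber stiffness but no published fiber angle;
#: circumferential fibers (phi = 0) are assumed.
MATERIALS: Dict[str, MaterialParams] = {
    "lipid": MaterialParams("lipid", 0.5, 0.0, 0.5, 1.5, isotropic=True),
    "intima": MaterialParams("intima", -262.76, 22.9, 125.9, 2.0, 7.19, 23.5, 0.0),
    "media": MaterialParams("media", -5.0, -20.0, 20.0, 2.8, 168.0, 57.0, 24.9),
    "adventitia": MaterialParams("adventitia", 6.16, 0.0, 0.03, 30.0,
                                 10.0, 54.0, 75.3),
}


@dataclass
class DeformationState:
    """Principal stretches of an incompressible deformation.

    lam_r is derived from incompressibility (lam_t * lam_z * lam_r = 1).
    """

    lam_theta: float
    lam_z: float

    def __post_init__(self) -> None:
        if self.lam_theta <= 0 or self.lam_z <= 0:
            raise ValueError("principal stretches must be positive")

    @property
    def lam_r(self) -> float:
        return 1.0 / (self.lam_theta * self.lam_z)

    def invariants(self, phi_deg: float) -> Tuple[float, float, float]:
        a, b, r = self.lam_theta, self.lam_z, self.lam_r
        i1 = a * a + b * b + r * r
        i2 = a * a * b * b + a * a * r * r + b * b * r * r
        phi = np.radians(phi_deg)
        i4 = a * a * np.cos(phi) ** 2 + b * b * np.sin(phi) ** 2
        return i1, i2, i4


def strain_energy(params: MaterialParams, state: DeformationState) -> float:
    """Strain-energy density W (kPa); exactly 0 at the identity."""
    i1, i2, i4 = state.invariants(params.phi_deg)
    w = (params.c1 * (i1 - 3.0) + params.c2 * (i2 - 3.0)
         + params.D1 * (np.exp(params.D2 * (i1 - 3.0)) - 1.0))
    if not params.isotropic:
        w += (params.K1 / params.K2) * (np.exp(params.K2 * (i4 - 1.0) ** 2) - 1.0)
    return float(w)


def _dW(params: MaterialParams, a: float, b: float) -> Tuple[float, float]:
    """(dW/da, dW/db) at lam_theta=a, lam_z=b with lam_r = 1/(a b) eliminated."""
    r = 1.0 / (a * b)
    i1 = a * a + b * b + r * r
    i4_a = np.cos(np.radians(params.phi_deg)) ** 2
    i4_b = np.sin(np.radians(params.phi_deg)) ** 2
    dW1 = params.c1 + params.D1 * params.D2 * np.exp(params.D2 * (i1 - 3.0))
    dW2 = params.c2
    # dI1/da with r(a) = -r/a etc.
    dI1_a = 2 * a - 2 * r * r / a
    dI1_b = 2 * b - 2 * r * r / b
    dI2_a = 2 * a * b * b + 2 * a * r * r - 2 * r * r * (a * a + b * b) / a
    dI2_b = 2 * b * a * a + 2 * b * r * r - 2 * r * r * (a * a + b * b) / b
    da = dW1 * dI1_a + dW2 * dI2_a
    db = dW1 * dI1_b + dW2 * dI2_b
    if not params.isotropic:
        i4 = a * a * i4_a + b * b * i4_b
        dW4 = 2.0 * params.K1 * (i4 - 1.0) * np.exp(params.K2 * (i4 - 1.0) ** 2)
        da += dW4 * 2 * a * i4_a
        db += dW4 * 2 * b * i4_b
    return float(da), float(db)


def _free_lateral(params: MaterialParams, lam: float, direction: str,
                  guess: float) -> float:
    """Solve lateral equilibrium dW/dlateral = 0 for the free in-plane stretch."""
    def g(x: float) -> float:
        if direction == "circumferential":
            return _dW(params, lam, x)[1]
        return _dW(params, x, lam)[0]

    lo, hi = guess, guess
    glo = g(lo)
    # expand a bracket around the guess
    for _ in range(80):
        if glo == 0.0:
            return lo
        lo2, hi2 = lo * 0.97, hi * 1.03
        if g(lo2) * g(hi2) < 0:
            return brentq(g, lo2, hi2, xtol=1e-12)
        if g(lo2) * glo < 0:
            return brentq(g, lo2, lo, xtol=1e-12)
        if g(hi2) * g(hi) < 0:
            return brentq(g, hi, hi2, xtol=1e-12)
        lo, hi = lo2, hi2
        glo = g(lo)
    raise RuntimeError(f"no lateral equilibrium found for {params.tissue} "
                       f"at stretch {lam}")


def uniaxial_stress(params: MaterialParams, lam: float,
                    direction: str = "circumferential",
                    _guess: Optional[float] = None) -> float:
    """Uniaxial Cauchy stress (kPa) at stretch ``lam`` along ``direction``.

    Incompressible, traction-free lateral directions; sigma(1) = 0 by
    construction since the identity is an equilibrium of W.
    """
    if lam <= 0:
        raise ValueError("stretch must be positive")
    if direction not in ("circumferential", "axial"):
        raise ValueError("direction must be 'circumferential' or 'axial'")
    guess = _guess if _guess is not None else 1.0 / np.sqrt(lam)
    lat = _free_lateral(params, lam, direction, guess)
    if direction == "circumferential":
        da, _ = _dW(params, lam, lat)
    else:
        _, da = _dW(params, lat, lam)
    return float(lam * da)


def stress_stretch_curve(params: MaterialParams,
                         stretches: Optional[Sequence[float]] = None,
                         direction: str = "circumferential"
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Uniaxial stress over a stretch grid (default 1.0..1.5), with continuation.

    The lateral-equilibrium root at each grid point seeds the next, which
    keeps the solution branch continuous even for the strongly nonconvex
    parameter sets.
    """
    lams = (np.asarray(stretches, float) if stretches is not None
            else np.linspace(1.0, 1.5, 101))
    out = np.empty(lams.size)
    guess = 1.0 / np.sqrt(max(lams[0], 1e-6))
    for i, lam in enumerate(lams):
        lat = _free_lateral(params, lam, direction, guess)
        guess = lat
        if direction == "circumferential":
            out[i] = lam * _dW(params, lam, lat)[0]
        else:
            out[i] = lam * _dW(params, lat, lam)[1]
    return lams, out


def apply_preshrink(contours: Sequence[LayerContourSet], slice_spacing: float,
                    axial_stretch: float = 1.05,
                    circ_shrink: float = 0.0
                    ) -> Tuple[List[LayerContourSet], float]:
    """Shrink imaged geometry toward the unloaded in-vivo configuration.

    OCT frames are acquired with the vessel axially stretched and
    pressurized; to recover the modeling configuration the slice spacing is
    divided by ``axial_stretch`` and every contour radius is scaled by
    (1 - circ_shrink); areas scale by the square. Scaling about the polar
    center differs from scaling about the lumen centroid only by a rigid
    translation of the slice, so the resulting geometry (perimeters,
    thicknesses, areas) is identical. ``circ_shrink`` has no published
    default and must be given by the user; 0 with axial_stretch 1 is the
    identity.
    """
    if not (0.0 <= circ_shrink <= 0.2):
        raise ValueError("circ_shrink must be within [0, 0.2]")
    if axial_stretch <= 0:
        raise ValueError("axial_stretch must be positive")
    factor = 1.0 - circ_shrink
    out = []
    for cs in contours:
        new = {}
        for key, c in (("lumen", cs.lumen), ("iem", cs.iem),
                       ("eem", cs.eem), ("adv", cs.adv)):
            radii = c.radii * factor
            if np.any(radii[c.valid] <= 0):
                raise ValueError("pre-shrink produced non-positive radii")
            new[key] = RadialContour(radii, c.valid.copy(), c.slice_index)
        out.append(LayerContourSet(slice_index=cs.slice_index, **new))
    return out, slice_spacing / axial_stretch
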