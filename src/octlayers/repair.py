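"""Surface repair: complete occluded arcs of stacked boundary contours.

Accepted sparse contours, reverse-flattened to absolute radii, form one
radius surface r(theta, z) per boundary with holes where lipid shadow or
the guidewire hid the wall. Each surface is completed by a tensor-product
cubic spline — periodic uniform B-splines along angle (a vessel contour is
closed) and clamped cubic B-splines along the pullback — fit by penalized
least squares to the known samples. Holes take the spline's value; known
samples are kept verbatim, which makes repairing an already-complete
surface a no-op.

The default smoothing weight is chosen per surface by generalized
cross-validation (GCV) on the known samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.interpolate import BSpline

from .core import (BOUNDARIES, ContourSurface, LayerContourSet, PolarStack,
                   RadialContour, angle_grid)
from .lumen import smooth_contour


# ----------------------------------------------------------------- bases
def periodic_bspline_basis(n_points: int, n_coef: int) -> np.ndarray:
    """Uniform periodic cubic B-spline design matrix (n_points x n_coef).

    Basis function j is the cardinal cubic B-spline centered at knot
    ``j * n_points / n_coef`` wrapped on the circle; rows sum to 1.
    """
    if n_coef < 4:
        raise ValueError("need at least 4 periodic coefficients")
    x = np.arange(n_points) * (n_coef / n_points)  # sample position in knot units
    j = np.arange(n_coef)
    t = x[:, None] - j[None, :]
    t = (t + n_coef / 2.0) % n_coef - n_coef / 2.0  # wrapped distance in knot units
    at = np.abs(t)
    B = np.where(at <= 1, 2.0 / 3.0 - at ** 2 + 0.5 * at ** 3,
                 np.where(at <= 2, (2.0 - at) ** 3 / 6.0, 0.0))
    return B / 1.0


def clamped_bspline_basis(n_points: int, n_coef: int) -> np.ndarray:
    """Clamped uniform cubic B-spline design matrix over [0, 1]."""
    n_coef = max(4, min(n_coef, n_points))
    n_interior = n_coef - 4
    t = np.concatenate([np.zeros(4),
                        np.linspace(0, 1, n_interior + 2)[1:-1],
                        np.ones(4)])
    x = np.linspace(0, 1, n_points) if n_points > 1 else np.array([0.0])
    return BSpline.design_matrix(x, t, 3, extrapolate=False).toarray()


def _second_diff_penalty(n: int, periodic: bool) -> np.ndarray:
    """D'D for second differences of the coefficient vector."""
    if periodic:
        D = np.zeros((n, n))
        for i in range(n):
            D[i, i] = -2.0
            D[i, (i - 1) % n] = 1.0
            D[i, (i + 1) % n] = 1.0
    else:
        if n < 3:
            return np.zeros((n, n))
        D = np.zeros((n - 2, n))
        for i in range(n - 2):
            D[i, i:i + 3] = (1.0, -2.0, 1.0)
    return D.T @ D


@dataclass
class SplineFitReport:
    smoothing: float
    rms_known_residual: float
    n_known: int


def stack_contours(per_slice_radii: Sequence[np.ndarray],
                   per_slice_accepted: Sequence[np.ndarray],
                   boundary: str, radial_spacing: float) -> ContourSurface:
    """Stack per-slice sparse contours (absolute radii, mm) into a surface.

    ``per_slice_radii[s]`` holds radii per angle bin (NaN or arbitrary at
    unaccepted bins); ``per_slice_accepted[s]`` flags the known samples.
    """
    R = np.stack([np.asarray(r, dtype=float) for r in per_slice_radii], axis=1)
    K = np.stack([np.asarray(a, dtype=bool) for a in per_slice_accepted], axis=1)
    R = R.copy()
    R[~K] = np.nan
    R[K & ~np.isfinite(R)] = np.nan
    K = K & np.isfinite(np.where(K, R, np.nan))
    filled = np.where(np.isfinite(R), R, 1.0)
    return ContourSurface(radii=filled, known=K, boundary=boundary,
                          radial_spacing=radial_spacing)


def fit_spline_surface(surface: ContourSurface,
                       smoothing: Union[float, str] = "gcv",
                       n_angle_coef: int = 10,
                       n_slice_coef: Optional[int] = None,
                       min_known_fraction: float = 0.4,
                       min_known_per_slice: float = 0.5
                       ) -> Tuple[ContourSurface, SplineFitReport]:
    """Complete a holed radius surface with a bicubic periodic spline fit.

    The fit solves ``min ||B c - r_known||^2 + lam * pen(c)`` over the
    tensor-product coefficient grid (``n_angle_coef`` periodic x
    ``n_slice_coef`` clamped cubic B-splines); ``smoothing`` is the ridge
    weight ``lam`` (0 = pure least squares) or ``"gcv"`` to select it by
    generalized cross-validation. Unknown bins take the spline value; known
    bins keep their original radii, so a complete surface passes through
    unchanged.

    Raises if overall known fraction is below ``min_known_fraction`` or any
    slice has less than ``min_known_per_slice`` of its angle bins known
    (default half a turn, matching the visibility statistic the repair
    relies on).
    """
    na, ns = surface.radii.shape
    known = surface.known
    if surface.known_fraction < min_known_fraction:
        raise ValueError(f"only {surface.known_fraction:.0%} of bins known; "
                         f"need >= {min_known_fraction:.0%}")
    frac_per_slice = known.mean(axis=0)
    low = np.where(frac_per_slice < min_known_per_slice)[0]
    if low.size:
        raise ValueError("slices below the known-arc threshold: "
                         + ", ".join(map(str, low.tolist())))

    if n_slice_coef is None:
        n_slice_coef = max(4, min(ns, ns // 10 + 2))
    Ba = periodic_bspline_basis(na, n_angle_coef)
    Bs = clamped_bspline_basis(ns, n_slice_coef)

    ai, si = np.where(known)
    A = Ba[ai][:, :, None] * Bs[si][:, None, :]
    A = A.reshape(ai.size, -1)
    y = surface.radii[known]

    P = (np.kron(_second_diff_penalty(n_angle_coef, periodic=True),
                 np.eye(Bs.shape[1]))
         + np.kron(np.eye(n_angle_coef),
                   _second_diff_penalty(Bs.shape[1], periodic=False)))
    AtA = A.T @ A
    Aty = A.T @ y

    def solve(lam: float) -> np.ndarray:
        if lam == 0.0:
            c, *_ = np.linalg.lstsq(A, y, rcond=None)
            return c
        return np.linalg.solve(AtA + lam * P, Aty)

    if smoothing == "gcv":
        lams = 10.0 ** np.arange(-4, 2)
        best = (np.inf, 0.0, None)
        n = y.size
        for lam in lams:
            M = AtA + lam * P
            try:
                c = np.linalg.solve(M, Aty)
                tr = np.trace(np.linalg.solve(M, AtA))
            except np.linalg.LinAlgError:
                continue
            rss = float(np.sum((A @ c - y) ** 2))
            denom = max(n - tr, 1e-9)
            gcv = n * rss / denom ** 2
            if gcv < best[0]:
                best = (gcv, lam, c)
        lam, coef = best[1], best[2]
        if coef is None:
            lam, coef = 0.0, solve(0.0)
    else:
        lam = float(smoothing)
        coef = solve(lam)

    C = coef.reshape(n_angle_coef, Bs.shape[1])
    full = Ba @ C @ Bs.T
    out = surface.copy()
    out.radii = np.where(known, surface.radii, full)
    out.known = np.ones_like(known)
    resid = float(np.sqrt(np.mean((full[known] - surface.radii[known]) ** 2)))
    return out, SplineFitReport(smoothing=lam, rms_known_residual=resid,
                                n_known=int(known.sum()))


def polar_to_cartesian(radii: np.ndarray, center: Tuple[float, float] = (0.0, 0.0)
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """x = r cos(theta) + cx, y = r sin(theta) + cy on the angle-bin grid."""
    theta = angle_grid(radii.shape[0])
    return (radii * np.cos(theta) + center[0],
            radii * np.sin(theta) + center[1])


def finalize_contours(surfaces: Dict[str, ContourSurface],
                      smoothing_window: int = 15,
                      min_separation: float = 1e-4,
                      violation_budget: float = 0.05
                      ) -> Tuple[List[LayerContourSet], int]:
    """Smooth completed surfaces, enforce radial ordering, emit per-slice sets.

    Each boundary is circularly smoothed per slice with the same moving-
    average operator used for the lumen contour, then the radial ordering
    lumen < IEM < EEM < ADV is enforced by minimal outward projection
    (an offending radius is lifted to the inner one plus
    ``min_separation`` mm). If more than ``violation_budget`` of bins need
    projection the repair is considered failed and a ``ValueError`` is
    raised. Returns the per-slice contour sets (Cartesian coordinates are
    obtained with :func:`polar_to_cartesian`) and the number of projected
    bins.
    """
    missing = [b for b in BOUNDARIES if b not in surfaces]
    if missing:
        raise ValueError(f"missing surfaces: {missing}")
    if not all(surfaces[b].known.all() for b in BOUNDARIES):
        raise ValueError("all surfaces must be complete before finalization")
    na = surfaces["lumen"].n_angle_bins
    ns = surfaces["lumen"].n_slices
    sm = {}
    for b in BOUNDARIES:
        grid = np.empty((na, ns))
        for s in range(ns):
            c = RadialContour(surfaces[b].radii[:, s], np.ones(na, bool), s)
            grid[:, s] = smooth_contour(c, smoothing_window).radii
        sm[b] = grid
    n_projected = 0
    for inner, outer in zip(BOUNDARIES[:-1], BOUNDARIES[1:]):
        viol = sm[outer] <= sm[inner]
        n_projected += int(viol.sum())
        sm[outer] = np.where(viol, sm[inner] + min_separation, sm[outer])
    if n_projected > violation_budget * na * ns * 3:
        raise ValueError(f"ordering violations at {n_projected} bins exceed "
                         f"the {violation_budget:.0%} budget")
    out = []
    full = np.ones(na, dtype=bool)
    for s in range(ns):
        out.append(LayerContourSet(
            lumen=RadialContour(sm["lumen"][:, s], full.copy(), s),
            iem=RadialContour(sm["IEM"][:, s], full.copy(), s),
            eem=RadialContour(sm["EEM"][:, s], full.copy(), s),
            adv=RadialContour(sm["ADV"][:, s], full.copy(), s),
            slice_index=s))
    return out, n_projected
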