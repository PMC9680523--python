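"""Thickness and error analytics for layer contours.

Layer thickness is measured at 100 nodal points per slice: the lumen is
split into four quarters by axis-aligned rays from its centroid, each
quarter carries 25 arc-length-evenly spaced nodal points, and each node is
connected outward boundary by boundary (lumen -> IEM -> EEM -> ADV) with a
piecewise equal-step march along local normals. Intima thickness is the
lumen->IEM segment length, media the IEM->EEM length, adventitia the
EEM->ADV length.

Thicknesses live in a tensor T_q(i, j, k) (layer q, point i = 1..100,
slice j, patient k); slice/patient/overall means, signed relative thickness
errors of automatic vs manual contours, point-to-point contour distances
and percentile summaries are computed from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import LineString, LinearRing, Point, Polygon
from shapely.ops import nearest_points

from .core import LayerContourSet, angle_grid

LAYERS = ("intima", "media", "adventitia")
N_NODES = 100
N_PER_QUARTER = 25


# ------------------------------------------------------------------ nodal set
def _contour_xy(radii: np.ndarray, upsample: int = 4) -> np.ndarray:
    """Dense closed polyline (N, 2) of a radius-vs-angle contour."""
    n = radii.size
    theta = angle_grid(n)
    td = np.linspace(0, 2 * np.pi, n * upsample, endpoint=False)
    rd = np.interp(td, np.concatenate([theta, [2 * np.pi]]),
                   np.concatenate([radii, [radii[0]]]))
    return np.column_stack([rd * np.cos(td), rd * np.sin(td)])


def _arclength_resample(poly: np.ndarray, fracs: np.ndarray) -> np.ndarray:
    """Points at given arc-length fractions along an open polyline."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    return np.column_stack([np.interp(fracs * total, s, poly[:, 0]),
                            np.interp(fracs * total, s, poly[:, 1])])


def _tangent_at(poly_closed: np.ndarray, pt: np.ndarray) -> np.ndarray:
    """Unit tangent of the closed polyline at its vertex nearest to pt."""
    d = np.linalg.norm(poly_closed - pt[None, :], axis=1)
    i = int(np.argmin(d))
    n = poly_closed.shape[0]
    t = poly_closed[(i + 1) % n] - poly_closed[(i - 1) % n]
    nt = np.linalg.norm(t)
    return t / nt if nt > 0 else np.array([1.0, 0.0])


@dataclass
class NodalSet:
    """100 matched nodal points per slice with per-layer segment lengths."""

    lumen_points: np.ndarray        # (100, 2) mm
    boundary_points: Dict[str, np.ndarray]   # IEM/EEM/ADV -> (100, 2)
    thickness: np.ndarray           # (3, 100): intima, media, adventitia, mm
    centroid: Tuple[float, float]
    fallback_nodes: List[int] = field(default_factory=list)

    @property
    def total_thickness(self) -> np.ndarray:
        return self.thickness.sum(axis=0)


def build_nodal_set(contours: LayerContourSet, upsample: int = 4) -> NodalSet:
    """Construct the 100-point nodal correspondence for one slice.

    Quarters are bounded by the four axis-aligned rays from the lumen
    centroid; each quarter gets 25 nodal points at arc-length positions
    (m + 0.5)/25 of the quarter, m = 0..24. From each lumen node the march
    steps outward along the local outward normal of the current boundary to
    the nearest intersection with the next boundary; if the normal ray
    misses, the nearest point on the next boundary is used instead and the
    node index is logged in ``fallback_nodes``.
    """
    polys = {name: _contour_xy(c.radii, upsample)
             for name, c in contours.as_dict().items()}
    lum = polys["lumen"]
    ring = Polygon(lum)
    if not ring.is_valid:
        raise ValueError("lumen contour is self-intersecting")
    for name in ("IEM", "EEM", "ADV"):
        if not Polygon(polys[name]).is_valid:
            raise ValueError(f"{name} contour is self-intersecting")
    cx, cy = ring.centroid.x, ring.centroid.y

    # split the closed lumen curve into 4 quarters about the centroid:
    # rotate the polyline to start at the smallest centroid angle, unwrap,
    # and replicate one period on each side so every quarter boundary falls
    # inside an interpolable range
    phi_raw = np.mod(np.arctan2(lum[:, 1] - cy, lum[:, 0] - cx), 2 * np.pi)
    start = int(np.argmin(phi_raw))
    pts = np.roll(lum, -start, axis=0)
    phi = np.unwrap(np.mod(np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx),
                           2 * np.pi))
    if np.any(np.diff(phi) <= 0):
        raise ValueError("lumen contour is not star-shaped about its centroid")
    phi3 = np.concatenate([phi - 2 * np.pi, phi, phi + 2 * np.pi])
    pts3 = np.vstack([pts, pts, pts])
    nodes = []
    for q in range(4):
        lo, hi = q * np.pi / 2, (q + 1) * np.pi / 2
        quarter = _quarter_polyline(pts3, phi3, lo, hi)
        fr = (np.arange(N_PER_QUARTER) + 0.5) / N_PER_QUARTER
        nodes.append(_arclength_resample(quarter, fr))
    lumen_nodes = np.vstack(nodes)

    rings = {name: LinearRing(polys[name]) for name in ("IEM", "EEM", "ADV")}
    max_reach = 4.0 * float(np.max(np.linalg.norm(polys["ADV"], axis=1)))
    boundary_points = {name: np.empty((N_NODES, 2)) for name in rings}
    thickness = np.empty((3, N_NODES))
    fallback: List[int] = []
    order = ("IEM", "EEM", "ADV")
    for i in range(N_NODES):
        cur = lumen_nodes[i]
        cur_poly = lum
        for li, name in enumerate(order):
            tang = _tangent_at(cur_poly, cur)
            normal = np.array([-tang[1], tang[0]])
            if np.dot(normal, cur - np.array([cx, cy])) < 0:
                normal = -normal
            ray = LineString([cur, cur + max_reach * normal])
            inter = ray.intersection(rings[name])
            nxt = _closest_intersection(inter, cur)
            if nxt is None:
                nxt = np.asarray(nearest_points(Point(cur), rings[name])[1].coords[0])
                if i not in fallback:
                    fallback.append(i)
            boundary_points[name][i] = nxt
            thickness[li, i] = np.linalg.norm(nxt - cur)
            cur = nxt
            cur_poly = polys[name]
    return NodalSet(lumen_points=lumen_nodes, boundary_points=boundary_points,
                    thickness=thickness, centroid=(cx, cy),
                    fallback_nodes=fallback)


def _quarter_polyline(pts3: np.ndarray, phi3: np.ndarray, lo: float,
                      hi: float) -> np.ndarray:
    """Sub-polyline with centroid angle in [lo, hi] (phi3 spans 3 periods)."""
    i0 = int(np.searchsorted(phi3, lo, side="right"))
    i1 = int(np.searchsorted(phi3, hi, side="left"))
    seg = [_interp_at(phi3, pts3, lo)]
    seg.extend(pts3[i0:i1])
    seg.append(_interp_at(phi3, pts3, hi))
    out = np.array(seg)
    if out.shape[0] < 2:
        raise ValueError("degenerate quarter; contour not star-shaped")
    return out


def _interp_at(phi2: np.ndarray, pts2: np.ndarray, val: float) -> np.ndarray:
    i = int(np.clip(np.searchsorted(phi2, val), 1, phi2.size - 1))
    t = (val - phi2[i - 1]) / max(phi2[i] - phi2[i - 1], 1e-12)
    return pts2[i - 1] + t * (pts2[i] - pts2[i - 1])


def _closest_intersection(inter, origin: np.ndarray) -> Optional[np.ndarray]:
    if inter.is_empty:
        return None
    pts = []
    if inter.geom_type == "Point":
        pts = [inter]
    elif hasattr(inter, "geoms"):
        for g in inter.geoms:
            if g.geom_type == "Point":
                pts.append(g)
            else:
                pts.extend(Point(c) for c in g.coords)
    else:
        pts = [Point(c) for c in inter.coords]
    if not pts:
        return None
    arr = np.array([[p.x, p.y] for p in pts])
    d = np.linalg.norm(arr - origin[None, :], axis=1)
    return arr[int(np.argmin(d))]


# ------------------------------------------------------------ thickness tensor
@dataclass
class ThicknessTensor:
    """T_q(i, j, k): per-patient arrays of shape (3, 100, m_k), mm."""

    per_patient: List[np.ndarray]

    def __post_init__(self) -> None:
        for a in self.per_patient:
            if a.ndim != 3 or a.shape[0] != 3 or a.shape[1] != N_NODES:
                raise ValueError("each patient array must be (3, 100, m_k)")
            if np.any(a < 0):
                raise ValueError("thicknesses must be non-negative")

    @property
    def n_patients(self) -> int:
        return len(self.per_patient)

    @classmethod
    def from_nodal_sets(cls, per_patient_slices: Sequence[Sequence[NodalSet]]
                        ) -> "ThicknessTensor":
        return cls([np.stack([ns.thickness for ns in slices], axis=2)
                    for slices in per_patient_slices])


def thickness_stats(T: ThicknessTensor, level: str = "all"
                    ) -> Dict[str, np.ndarray]:
    """Mean layer thickness at slice, patient or overall level.

    * ``slice``: mean over the 100 points, per (slice, patient) — a list of
      (3, m_k) arrays.
    * ``patient``: mean over points and slices, per patient — (3, n).
    * ``all``: pooled mean over every (i, j, k) sample (patients weighted by
      their slice counts) plus the equal-patient-weight mean of the
      per-patient values; both returned.
    """
    if T.n_patients == 0 or any(a.shape[2] == 0 for a in T.per_patient):
        raise ValueError("empty thickness tensor")
    slice_means = [a.mean(axis=1) for a in T.per_patient]           # (3, m_k)
    if level == "slice":
        return {"slice_mean": slice_means}
    patient_means = np.stack([a.mean(axis=(1, 2)) for a in T.per_patient],
                             axis=1)                                # (3, n)
    if level == "patient":
        return {"patient_mean": patient_means,
                "patient_sd": np.stack([sm.std(axis=1, ddof=1) if sm.shape[1] > 1
                                        else np.zeros(3) for sm in slice_means],
                                       axis=1)}
    if level == "all":
        pooled = np.concatenate([a.reshape(3, -1) for a in T.per_patient], axis=1)
        return {"all_mean_pooled": pooled.mean(axis=1),
                "all_mean_equal_patient": patient_means.mean(axis=1)}
    raise ValueError(f"unknown level: {level}")


def thickness_error(Tqa: ThicknessTensor, Tqm: ThicknessTensor,
                    level: str = "all") -> Dict[str, object]:
    """Signed relative thickness errors (%) of automatic vs manual contours.

    Per (slice, patient): 100 * mean_i(auto - manual) / mean_i(manual);
    negative means the automatic contours are thinner. Patient level is the
    mean over slices, overall the mean over patients; standard deviations
    accompany each aggregated level. Slices with zero manual mean are
    excluded and counted.
    """
    if Tqa.n_patients != Tqm.n_patients:
        raise ValueError("patient count mismatch")
    slice_err: List[np.ndarray] = []
    n_excluded = 0
    for a, m in zip(Tqa.per_patient, Tqm.per_patient):
        if a.shape != m.shape:
            raise ValueError("shape mismatch between automatic and manual tensors")
        num = a.mean(axis=1) - m.mean(axis=1)     # (3, m_k)
        den = m.mean(axis=1)
        err = np.full(num.shape, np.nan)
        ok = den > 0
        err[ok] = 100.0 * num[ok] / den[ok]
        n_excluded += int((~ok).sum())
        slice_err.append(err)
    if level == "slice":
        return {"slice_error": slice_err, "n_excluded": n_excluded}
    pat = np.stack([np.nanmean(e, axis=1) for e in slice_err], axis=1)   # (3, n)

    def _sd(row: np.ndarray) -> float:
        vals = row[np.isfinite(row)]
        return float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    pat_sd = np.stack([[_sd(e[q]) for q in range(3)] for e in slice_err],
                      axis=1)
    if level == "patient":
        return {"patient_error": pat, "patient_sd": pat_sd,
                "n_excluded": n_excluded}
    if level == "all":
        pooled = np.concatenate(slice_err, axis=1)
        n_ok = np.isfinite(pooled).sum(axis=1)
        sd = np.zeros(3)
        for q in range(3):
            if n_ok[q] > 1:
                sd[q] = np.nanstd(pooled[q], ddof=1)
        return {"all_error": pat.mean(axis=1),
                "all_sd_slices": sd,
                "patient_error": pat, "n_excluded": n_excluded}
    raise ValueError(f"unknown level: {level}")


def contour_distance(auto_radii: np.ndarray, manual_radii: np.ndarray
                     ) -> np.ndarray:
    """Per-angle signed radial distance auto - manual (mm), polar, shared center.

    If the angular grids differ in length the automatic contour is resampled
    onto the manual grid by periodic linear interpolation.
    """
    a = np.asarray(auto_radii, float)
    m = np.asarray(manual_radii, float)
    if a.size != m.size:
        tm = angle_grid(m.size)
        ta = angle_grid(a.size)
        a = np.interp(tm, np.concatenate([ta, [2 * np.pi]]),
                      np.concatenate([a, [a[0]]]))
    return a - m


def distance_stats(per_slice_auto: Sequence[np.ndarray],
                   per_slice_manual: Sequence[np.ndarray]
                   ) -> Dict[str, float]:
    """Mean and SD of point-to-point distances over all slices of one pullback."""
    d = np.concatenate([contour_distance(a, m) for a, m
                        in zip(per_slice_auto, per_slice_manual)])
    return {"mean": float(d.mean()),
            "sd": float(d.std(ddof=1)) if d.size > 1 else 0.0}


def error_percentile(slice_errors: np.ndarray, p: float = 90.0) -> float:
    """p-th percentile of |error| over slices (linear interpolation convention)."""
    e = np.asarray(slice_errors, dtype=float)
    e = e[np.isfinite(e)]
    if e.size == 0:
        raise ValueError("no slice errors supplied")
    return float(np.percentile(np.abs(e), p))
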