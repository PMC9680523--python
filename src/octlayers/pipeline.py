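"""End-to-end orchestration: phantom/input -> contours -> repair -> metrics.

Every stage writes its artifact (windowed stack, lumen CSV, accepted-layer
CSV, repaired CSV, metrics JSON) so failed runs are inspectable, and the
machine-readable report records the config hash, stage timings, gap
fractions and QC flags. Identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from . import io as oio
from .core import (GroundTruth, LayerContourSet, PolarStack, WALL_BOUNDARIES,
                   bin_to_radius, radius_to_bin)
from .layers import (CannyConfig, detect_edge_candidates, propagate_edges,
                     select_seed_edges)
from .lumen import detect_lumen
from .metrics import (ThicknessTensor, build_nodal_set, distance_stats,
                      thickness_error)
from .phantom import PhantomSpec, generate_phantom
from .preprocess import (WindowConfig, detect_guidewire, flatten_to_lumen,
                         window_intensity)
from .repair import finalize_contours, fit_spline_surface, stack_contours


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs."""

    out_dir: str = "octlayers_run"
    stack_path: Optional[str] = None       # input TIFF; None -> phantom
    truth_path: Optional[str] = None       # reference contours CSV
    phantom: Optional[PhantomSpec] = None  # phantom spec when no stack given
    seed: int = 0
    window: WindowConfig = field(default_factory=WindowConfig)
    guidewire_rel_threshold: float = 0.3
    guidewire_min_width_bins: int = 5
    lumen_bandwidth: int = 50
    canny: CannyConfig = field(default_factory=CannyConfig)
    seed_slice: int = 0
    tolerance: float = 10.0
    spline_smoothing: Union[float, str] = "gcv"
    final_smoothing_window: int = 15
    compute_metrics: bool = True

    def hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where outputs land does not change them
        blob = json.dumps(_jsonable(payload), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def truth_to_flat_depths(reference: List[LayerContourSet], offsets,
                         radial_spacing: float) -> Dict[str, np.ndarray]:
    """Reference boundary radii -> flattened depth bins per (slice, angle)."""
    out = {}
    key = {"IEM": "iem", "EEM": "eem", "ADV": "adv"}
    for b in WALL_BOUNDARIES:
        grids = np.stack([getattr(cs, key[b]).radii for cs in reference])
        out[b] = radius_to_bin(grids, radial_spacing) - offsets.offsets
    return out


def run_pipeline(cfg: RunConfig) -> Dict:
    """Run the full segmentation/repair pipeline; return the run report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {"config_hash": cfg.hash(), "seed": cfg.seed,
                    "stages": {}, "qc": {}}
    t0 = time.perf_counter()

    def mark(stage: str) -> None:
        report["stages"][stage] = round(time.perf_counter() - t0, 3)

    # ---------------------------------------------------------------- input
    truth: Optional[GroundTruth] = None
    reference: Optional[List[LayerContourSet]] = None
    if cfg.stack_path is not None:
        stack = oio.read_stack(cfg.stack_path)
        if cfg.truth_path:
            reference = oio.read_truth_csv(cfg.truth_path)
    else:
        spec = cfg.phantom if cfg.phantom is not None else PhantomSpec()
        spec.rng_seed = cfg.seed
        stack, truth = generate_phantom(spec)
        reference = truth.contours
    mark("input")

    stack = window_intensity(stack, cfg.window)
    oio.write_stack(out / "windowed.tiff", stack)
    mark("window")

    stack.guidewire_mask = detect_guidewire(
        stack, cfg.guidewire_rel_threshold, cfg.guidewire_min_width_bins)
    report["qc"]["guidewire_fraction"] = float(stack.guidewire_mask.mean())
    mark("guidewire")

    lumen_contours = detect_lumen(stack, cfg.lumen_bandwidth)
    oio.write_contours_csv(out / "lumen.csv",
                           [_lumen_only(c) for c in lumen_contours])
    mark("lumen")

    flat, offsets = flatten_to_lumen(stack, lumen_contours)
    candidates = detect_edge_candidates(flat, cfg.canny)
    report["qc"]["empty_candidate_slices"] = candidates.flagged_empty
    mark("edges")

    if reference is None:
        raise ValueError("batch runs need a reference contour CSV for seeding "
                         "(interactive seeding is only available via the CLI)")
    ref_depths = truth_to_flat_depths(reference, offsets, stack.radial_spacing)
    seeds = select_seed_edges(candidates, cfg.seed_slice,
                              {b: ref_depths[b][cfg.seed_slice]
                               for b in WALL_BOUNDARIES})
    tracked = propagate_edges(candidates, seeds, cfg.tolerance)
    gap_frac = {b: float(1.0 - tracked[b][1].mean()) for b in WALL_BOUNDARIES}
    report["qc"]["gap_fraction"] = gap_frac
    mark("propagate")

    # -------------------------------------------------- unflatten and repair
    surfaces = {}
    for b in WALL_BOUNDARIES:
        depth, acc = tracked[b]
        radii_mm = bin_to_radius(depth + offsets.offsets, stack.radial_spacing)
        surfaces[b] = stack_contours(list(radii_mm), list(acc), b,
                                     stack.radial_spacing)
    lum_grid = np.stack([c.radii for c in lumen_contours], axis=1)
    lum_known = ~stack.guidewire_mask.T
    surfaces["lumen"] = stack_contours(list(lum_grid.T), list(lum_known.T),
                                       "lumen", stack.radial_spacing)
    fit_reports = {}
    for b, surf in surfaces.items():
        surfaces[b], rep = fit_spline_surface(surf, cfg.spline_smoothing)
        fit_reports[b] = {"smoothing": rep.smoothing,
                          "rms_known_residual_mm": rep.rms_known_residual,
                          "n_known": rep.n_known}
    report["qc"]["spline_fits"] = fit_reports
    mark("repair")

    final, n_projected = finalize_contours(surfaces, cfg.final_smoothing_window)
    report["qc"]["ordering_projected_bins"] = n_projected
    report["qc"]["ordering_ok_fraction"] = float(
        np.mean([cs.ordering_ok().mean() for cs in final]))
    oio.write_contours_csv(out / "repaired.csv", final)
    mark("finalize")

    if cfg.compute_metrics and reference is not None:
        report["metrics"] = evaluate_against_reference(
            final, reference, stack.radial_spacing)
        (out / "metrics.json").write_text(
            json.dumps(_jsonable(report["metrics"]), indent=2))
        mark("metrics")

    report["runtime_s"] = round(time.perf_counter() - t0, 3)
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report


def _lumen_only(c) -> LayerContourSet:
    return LayerContourSet(lumen=c, iem=c, eem=c, adv=c, slice_index=c.slice_index)


def evaluate_against_reference(auto: List[LayerContourSet],
                               reference: List[LayerContourSet],
                               radial_spacing: float) -> Dict:
    """Thickness-error (relative, %), contour-distance and lumen accuracy
    summary of automatic contours against a reference pullback."""
    auto_nodes = [build_nodal_set(cs) for cs in auto]
    ref_nodes = [build_nodal_set(cs) for cs in reference]
    Ta = ThicknessTensor.from_nodal_sets([auto_nodes])
    Tm = ThicknessTensor.from_nodal_sets([ref_nodes])
    err = thickness_error(Ta, Tm, level="all")
    lum_d = distance_stats([cs.lumen.radii for cs in auto],
                           [cs.lumen.radii for cs in reference])
    dists = {}
    for b, key in (("lumen", "lumen"), ("IEM", "iem"),
                   ("EEM", "eem"), ("ADV", "adv")):
        dists[b] = distance_stats([getattr(cs, key).radii for cs in auto],
                                  [getattr(cs, key).radii for cs in reference])
    return {
        "thickness_error_pct": {layer: float(err["all_error"][i])
                                for i, layer in
                                enumerate(("intima", "media", "adventitia"))},
        "thickness_error_sd_pct": {layer: float(err["all_sd_slices"][i])
                                   for i, layer in
                                   enumerate(("intima", "media", "adventitia"))},
        "lumen_mae_bins": float(abs(np.concatenate(
            [_signed_diff(a.lumen.radii, r.lumen.radii) for a, r
             in zip(auto, reference)])).mean() / radial_spacing),
        "lumen_distance_mm": lum_d,
        "contour_distance_mm": dists,
    }


def _signed_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.asarray(a, float) - np.asarray(b, float)
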