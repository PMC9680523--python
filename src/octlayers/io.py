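"""Readers and writers for stacks, contours and parameter registries.

All on-disk formats are plain: multi-frame grayscale TIFF for image stacks,
tidy CSV for contours and ground truth, YAML for configuration and the
material registry.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (BOUNDARIES, ContourSurface, GroundTruth, LayerContourSet,
                   PolarStack, RadialContour, angle_grid)


def write_stack(path, stack: PolarStack) -> None:
    """Write a polar stack as a multi-frame uint8 TIFF (one frame per slice)."""
    tifffile.imwrite(str(path),
                     np.clip(np.rint(stack.frames), 0, 255).astype(np.uint8),
                     photometric="minisblack",
                     metadata={"radial_spacing_mm": stack.radial_spacing,
                               "slice_spacing_mm": stack.slice_spacing})


def read_stack(path, radial_spacing: float = 0.0045,
               slice_spacing: float = 0.2) -> PolarStack:
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None]
    return PolarStack(frames.astype(np.float32), radial_spacing, slice_spacing)


def read_png_dir(path, radial_spacing: float = 0.0045,
                 slice_spacing: float = 0.2) -> PolarStack:
    """Read a directory of per-slice PNG frames (sorted by name)."""
    import imageio.v3 as iio
    files = sorted(Path(path).glob("*.png"))
    if not files:
        raise FileNotFoundError(f"no PNG frames in {path}")
    frames = np.stack([np.asarray(iio.imread(f), dtype=np.float32) for f in files])
    if frames.ndim == 4:  # RGB -> gray
        frames = frames[..., :3].mean(axis=-1)
    return PolarStack(frames, radial_spacing, slice_spacing)


def read_dicom(path, radial_spacing: float = 0.0045,
               slice_spacing: float = 0.2) -> PolarStack:
    """Read a multiframe DICOM into the internal polar layout."""
    import pydicom
    ds = pydicom.dcmread(str(path))
    frames = np.asarray(ds.pixel_array, dtype=np.float32)
    if frames.ndim == 2:
        frames = frames[None]
    frames = frames / max(frames.max(), 1.0) * 255.0
    return PolarStack(frames, radial_spacing, slice_spacing)


# ------------------------------------------------------------------- contours
def contours_to_frame(contours: Sequence[LayerContourSet],
                      center=(0.0, 0.0)) -> pd.DataFrame:
    """Tidy table: slice_index, angle_deg, boundary, radius_mm, x_mm, y_mm, valid."""
    rows = []
    for cs in contours:
        deg = np.degrees(angle_grid(cs.lumen.n_angle_bins))
        for name, c in cs.as_dict().items():
            rows.append(pd.DataFrame({
                "slice_index": cs.slice_index,
                "angle_deg": deg,
                "boundary": name,
                "radius_mm": c.radii,
                "x_mm": c.radii * np.cos(np.radians(deg)) + center[0],
                "y_mm": c.radii * np.sin(np.radians(deg)) + center[1],
                "valid": c.valid.astype(int),
            }))
    return pd.concat(rows, ignore_index=True)


def frame_to_contours(df: pd.DataFrame) -> List[LayerContourSet]:
    out = []
    for s, g in df.groupby("slice_index"):
        parts = {}
        for name, gb in g.groupby("boundary"):
            gb = gb.sort_values("angle_deg")
            parts[name] = RadialContour(gb["radius_mm"].to_numpy(),
                                        gb["valid"].to_numpy().astype(bool),
                                        int(s))
        out.append(LayerContourSet(lumen=parts["lumen"], iem=parts["IEM"],
                                   eem=parts["EEM"], adv=parts["ADV"],
                                   slice_index=int(s)))
    return out


def write_contours_csv(path, contours: Sequence[LayerContourSet]) -> None:
    contours_to_frame(contours).to_csv(path, index=False, float_format="%.6f")


def read_contours_csv(path) -> List[LayerContourSet]:
    return frame_to_contours(pd.read_csv(path))


def write_truth_csv(path, truth: GroundTruth) -> None:
    """Ground-truth CSV: slice_index, angle_deg, *_r_mm, shadowed."""
    rows = []
    for s, cs in enumerate(truth.contours):
        deg = np.degrees(angle_grid(cs.lumen.n_angle_bins))
        rows.append(pd.DataFrame({
            "slice_index": s, "angle_deg": deg,
            "lumen_r_mm": cs.lumen.radii, "iem_r_mm": cs.iem.radii,
            "eem_r_mm": cs.eem.radii, "adv_r_mm": cs.adv.radii,
            "shadowed": truth.shadow_mask[s].astype(int),
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False,
                                              float_format="%.6f")


def read_truth_csv(path) -> List[LayerContourSet]:
    df = pd.read_csv(path)
    out = []
    for s, g in df.groupby("slice_index"):
        g = g.sort_values("angle_deg")
        n = len(g)
        full = np.ones(n, dtype=bool)
        out.append(LayerContourSet(
            lumen=RadialContour(g["lumen_r_mm"].to_numpy(), full.copy(), int(s)),
            iem=RadialContour(g["iem_r_mm"].to_numpy(), full.copy(), int(s)),
            eem=RadialContour(g["eem_r_mm"].to_numpy(), full.copy(), int(s)),
            adv=RadialContour(g["adv_r_mm"].to_numpy(), full.copy(), int(s)),
            slice_index=int(s)))
    return out


def surface_from_records(angle_idx: np.ndarray, slice_idx: np.ndarray,
                         radii: np.ndarray, n_angle_bins: int, n_slices: int,
                         boundary: str, radial_spacing: float) -> ContourSurface:
    """Build a ContourSurface from sparse (angle, slice, radius) records.

    Duplicate samples at one (angle, slice) cell are rejected.
    """
    cells = np.ravel_multi_index((np.asarray(angle_idx), np.asarray(slice_idx)),
                                 (n_angle_bins, n_slices))
    if np.unique(cells).size != cells.size:
        raise ValueError("duplicate samples at one (angle, slice) cell")
    R = np.ones((n_angle_bins, n_slices))
    K = np.zeros((n_angle_bins, n_slices), dtype=bool)
    R[angle_idx, slice_idx] = radii
    K[angle_idx, slice_idx] = True
    return ContourSurface(R, K, boundary, radial_spacing)


def write_materials_yaml(path, materials: Dict) -> None:
    from dataclasses import asdict
    payload = {name: asdict(p) for name, p in materials.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
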