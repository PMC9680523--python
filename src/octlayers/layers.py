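"""Wall-layer boundary detection on lumen-flattened frames.

The radial intensity of a coronary OCT A-line rises into the bright intima,
falls into the dark media, rises again into the adventitia and falls into
the periadventitia. On the smoothed first derivative the three wall
boundaries therefore appear as valley (IEM), peak (EEM), valley (ADV).
Canny edge detection proposes candidate edges; each candidate is labeled by
that derivative signature, a manually (or reference-) selected seed slice
pins down the true edges, and acceptance propagates slice to slice under a
radial closeness tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.feature import canny

from .core import PolarStack, WALL_BOUNDARIES

LABELS = ("valley1", "peak", "valley2", "other")
_LABEL_OF = {"IEM": "valley1", "EEM": "peak", "ADV": "valley2"}


@dataclass
class CannyConfig:
    """Canny double thresholds (gradient units on the 0-1 image) + Gaussian radius."""

    low_threshold: float = 0.03
    high_threshold: float = 0.06
    gaussian_radius: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.low_threshold < self.high_threshold):
            raise ValueError("need 0 < low_threshold < high_threshold")
        if self.gaussian_radius <= 0:
            raise ValueError("gaussian_radius must be positive")


@dataclass
class SliceCandidates:
    """Candidates of one slice: per angle bin, depths (radial bins) and labels."""

    depths: List[np.ndarray]
    labels: List[np.ndarray]

    @property
    def n_angle_bins(self) -> int:
        return len(self.depths)

    def is_empty(self) -> bool:
        return all(d.size == 0 for d in self.depths)


@dataclass
class EdgeCandidateSet:
    """Candidate edge depths for every slice of a flattened stack."""

    slices: List[SliceCandidates]
    flagged_empty: List[int] = field(default_factory=list)

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass
class SeedSelection:
    """Chosen candidate depth per angle bin on the seed slice, per boundary.

    ``depths[boundary]`` is a float array with NaN at bins without a pick.
    """

    slice_index: int
    depths: Dict[str, np.ndarray]


def radial_derivatives(frame: np.ndarray, gaussian_radius: float
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian-smoothed first and second radial derivatives of a flattened frame.

    Smoothing runs along the radial (depth) axis with sigma =
    ``gaussian_radius`` pixels, followed by central differences.
    """
    frame = np.asarray(frame, dtype=float)
    if gaussian_radius <= 0:
        raise ValueError("gaussian_radius must be positive")
    if gaussian_radius * 3 >= frame.shape[-1]:
        raise ValueError("gaussian_radius too large for the frame depth")
    sm = gaussian_filter1d(frame, sigma=gaussian_radius, axis=-1)
    d1 = np.gradient(sm, axis=-1)
    d2 = np.gradient(d1, axis=-1)
    return d1, d2


def wall_band(frame: np.ndarray, gaussian_radius: float,
              floor: float = 20.0) -> Tuple[int, np.ndarray]:
    """Candidate region per A-line: [inner margin, outer signal support].

    The inner margin skips the lumen-entry gradient at depth 0 of the
    flattened frame. The outer bound per A-line is the end of the
    contiguous above-``floor`` run of smoothed intensity that starts at the
    wall, plus a margin of twice the smoothing radius; signal beyond a
    full-suppression shadow (or wrapped around by the circular flattening
    shift) is disconnected from that run and therefore excluded. Edges
    outside this band are discarded.
    """
    sm = gaussian_filter1d(np.asarray(frame, dtype=float), sigma=gaussian_radius,
                           axis=-1)
    inner = int(np.ceil(2 * gaussian_radius)) + 2
    margin = int(np.ceil(2 * gaussian_radius))
    above = sm > floor
    nr = frame.shape[-1]
    outer = np.empty(frame.shape[0], dtype=int)
    for a in range(frame.shape[0]):
        idx = np.where(above[a])[0]
        if idx.size == 0:
            outer[a] = inner
            continue
        start = idx[0]
        below = np.where(~above[a, start:])[0]
        end = start + (below[0] - 1) if below.size else nr - 1
        outer[a] = min(nr - 1, end + margin)
    return inner, outer


def detect_edge_candidates(flat: PolarStack, cfg: CannyConfig) -> EdgeCandidateSet:
    """Run Canny per flattened frame and label candidates by derivative sign.

    The frame (scaled to 0-1) is padded circularly along the angle axis by
    3x the Gaussian radius so no seam artifacts appear, then edged with
    ``skimage.feature.canny``. Edge pixels outside the whole-wall candidate
    band are discarded. Remaining candidates at an A-line are labeled from
    the smoothed first derivative at their depth: negative-going edges are
    valleys, positive-going are peaks; valleys are split into ``valley1``
    (inside the strongest peak) and ``valley2`` (beyond it). Guidewire
    A-lines — dilated by the Canny smoothing width, since the shadow border
    itself reads as a spurious edge — yield no candidates. A slice with no
    candidates at all is flagged.
    """
    pad = int(np.ceil(3 * cfg.gaussian_radius))
    gw_dilate = int(np.ceil(2 * cfg.gaussian_radius))
    slices: List[SliceCandidates] = []
    flagged: List[int] = []
    for s in range(flat.n_slices):
        frame = flat.frames[s].astype(float)
        img = frame / 255.0
        padded = np.concatenate([img[-pad:], img, img[:pad]], axis=0)
        edges = canny(padded, sigma=cfg.gaussian_radius,
                      low_threshold=cfg.low_threshold,
                      high_threshold=cfg.high_threshold)[pad:-pad]
        d1, _ = radial_derivatives(img, cfg.gaussian_radius)
        inner, outer = wall_band(frame, cfg.gaussian_radius)
        gw = (flat.guidewire_mask[s] if flat.guidewire_mask is not None
              else np.zeros(flat.n_angle_bins, dtype=bool))
        if gw.any() and gw_dilate:
            base = gw
            gw = gw.copy()
            for k in range(1, gw_dilate + 1):
                gw |= np.roll(base, k) | np.roll(base, -k)
        depths: List[np.ndarray] = []
        labels: List[np.ndarray] = []
        for a in range(flat.n_angle_bins):
            if gw[a]:
                depths.append(np.empty(0, dtype=int))
                labels.append(np.empty(0, dtype=object))
                continue
            d = np.where(edges[a])[0]
            d = d[(d >= inner) & (d <= outer[a])]
            d = _merge_runs(d, d1[a])
            lab = np.empty(d.size, dtype=object)
            if d.size:
                vals = d1[a, d]
                peaks = d[vals > 0]
                peak_ref = peaks[np.argmax(d1[a, peaks])] if peaks.size else None
                for i, (dep, v) in enumerate(zip(d, vals)):
                    if v > 0:
                        lab[i] = "peak"
                    elif v < 0:
                        if peak_ref is None:
                            lab[i] = "other"
                        else:
                            lab[i] = "valley1" if dep < peak_ref else "valley2"
                    else:
                        lab[i] = "other"
            depths.append(d)
            labels.append(lab)
        sc = SliceCandidates(depths, labels)
        if sc.is_empty():
            flagged.append(s)
        slices.append(sc)
    return EdgeCandidateSet(slices=slices, flagged_empty=flagged)


def _merge_runs(depths: np.ndarray, d1_line: np.ndarray,
                max_gap: int = 2) -> np.ndarray:
    """Collapse contiguous same-sign edge-pixel runs to one candidate each.

    Canny edges a couple of pixels thick along an A-line describe one
    physical boundary; the pixel with the strongest first derivative
    represents the run.
    """
    if depths.size <= 1:
        return depths
    out = []
    start = 0
    for i in range(1, depths.size + 1):
        end_of_run = (i == depths.size
                      or depths[i] - depths[i - 1] > max_gap
                      or np.sign(d1_line[depths[i]]) != np.sign(d1_line[depths[i - 1]]))
        if end_of_run:
            run = depths[start:i]
            out.append(run[np.argmax(np.abs(d1_line[run]))])
            start = i
    return np.asarray(out, dtype=int)


def _nearest_match(depths: np.ndarray, labels: np.ndarray, want: str,
                   ref: float) -> Optional[int]:
    """Nearest candidate with the wanted label; ties go to the smaller depth."""
    cand = depths[labels == want]
    if cand.size == 0:
        return None
    dist = np.abs(cand - ref)
    best = np.min(dist)
    return int(np.min(cand[dist == best]))


def select_seed_edges(candidates: EdgeCandidateSet, seed_slice: int,
                      reference: Dict[str, np.ndarray]) -> SeedSelection:
    """Pick one candidate per angle bin on the seed slice for each boundary.

    ``reference`` maps boundary name to a per-angle reference depth (a
    manual pick in interactive use, or a known contour in batch/testing);
    the nearest candidate with the boundary's derivative label is chosen,
    ties broken toward the smaller depth. A boundary with no candidate on
    the whole slice is an error.
    """
    if not (0 <= seed_slice < candidates.n_slices):
        raise ValueError("seed slice outside the stack")
    sc = candidates.slices[seed_slice]
    n = sc.n_angle_bins
    depths: Dict[str, np.ndarray] = {}
    missing = []
    for b in WALL_BOUNDARIES:
        want = _LABEL_OF[b]
        picked = np.full(n, np.nan)
        for a in range(n):
            ref = reference[b][a]
            if not np.isfinite(ref):
                continue
            m = _nearest_match(sc.depths[a], sc.labels[a], want, ref)
            if m is not None:
                picked[a] = m
        if not np.isfinite(picked).any():
            missing.append(b)
        depths[b] = picked
    if missing:
        raise ValueError(f"no seed candidates found for: {', '.join(missing)}")
    return SeedSelection(slice_index=seed_slice, depths=depths)


def propagate_edges(candidates: EdgeCandidateSet, seeds: SeedSelection,
                    tolerance: float = 10.0
                    ) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Track seed edges across the pullback under a radial closeness tolerance.

    For each boundary and angle bin, the accepted edge on the next slice is
    the candidate with matching derivative label nearest in depth to the
    last accepted depth at that bin, if within ``tolerance`` radial bins;
    otherwise the bin is left as a gap and the reference is carried forward
    unchanged (propagation resumes from the last accepted slice).
    Propagation runs in both directions from the seed slice. Bins where the
    accepted depths violate IEM < EEM < ADV are demoted to gaps entirely.

    Returns per boundary ``(depth_grid, accepted)`` arrays of shape
    (n_slices, n_angle_bins); unaccepted entries are NaN.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    ns = candidates.n_slices
    n = candidates.slices[seeds.slice_index].n_angle_bins
    depth = {b: np.full((ns, n), np.nan) for b in WALL_BOUNDARIES}

    def run(order: Sequence[int]) -> None:
        ref = {b: seeds.depths[b].astype(float).copy() for b in WALL_BOUNDARIES}
        for s in order:
            sc = candidates.slices[s]
            row = {}
            for b in WALL_BOUNDARIES:
                want = _LABEL_OF[b]
                out = np.full(n, np.nan)
                for a in range(n):
                    if not np.isfinite(ref[b][a]):
                        continue
                    m = _nearest_match(sc.depths[a], sc.labels[a], want, ref[b][a])
                    if m is not None and abs(m - ref[b][a]) <= tolerance:
                        out[a] = m
                row[b] = out
            bad = np.zeros(n, dtype=bool)
            for bi, bo in (("IEM", "EEM"), ("EEM", "ADV"), ("IEM", "ADV")):
                both = np.isfinite(row[bi]) & np.isfinite(row[bo])
                bad |= both & ~(row[bi] < row[bo])
            for b in WALL_BOUNDARIES:
                row[b][bad] = np.nan
                depth[b][s] = row[b]
                upd = np.isfinite(row[b])
                ref[b][upd] = row[b][upd]

    # seed slice itself: accept the seed picks (they are chosen candidates)
    run([seeds.slice_index])
    run(range(seeds.slice_index + 1, ns))
    run(range(seeds.slice_index - 1, -1, -1))
    return {b: (depth[b], np.isfinite(depth[b])) for b in WALL_BOUNDARIES}


def tune_canny(flat: PolarStack, reference: Dict[str, np.ndarray],
               seed_slice: int = 0,
               lows: Sequence[float] = (0.02, 0.04, 0.06, 0.08, 0.10),
               radii: Sequence[float] = (1.0, 2.0, 3.0, 5.0),
               tolerance: float = 10.0,
               gap_penalty_bins: float = 10.0) -> CannyConfig:
    """Grid-search Canny thresholds and Gaussian radius against references.

    ``reference`` maps boundary to a (n_slices, n_angle) depth grid (manual
    contours or phantom truth in flattened bins). The objective is the mean
    absolute depth error of accepted bins plus ``gap_penalty_bins`` for
    every reference bin with no accepted edge; the arg-min configuration is
    returned, ties broken lexicographically on (low, high, radius). The
    high threshold follows the common 2x rule.
    """
    grid = [CannyConfig(lo, 2 * lo, r) for lo, r in product(lows, radii)]
    if not grid:
        raise ValueError("empty grid")
    best: Tuple[float, Tuple[float, float, float], CannyConfig] | None = None
    for cfg in grid:
        cand = detect_edge_candidates(flat, cfg)
        seed_ref = {b: reference[b][seed_slice] for b in WALL_BOUNDARIES}
        try:
            seeds = select_seed_edges(cand, seed_slice, seed_ref)
        except ValueError:
            obj = np.inf
        else:
            tracked = propagate_edges(cand, seeds, tolerance)
            errs, gaps, total = [], 0, 0
            for b in WALL_BOUNDARIES:
                dep, acc = tracked[b]
                refb = reference[b]
                have_ref = np.isfinite(refb)
                total += int(have_ref.sum())
                hit = acc & have_ref
                gaps += int((have_ref & ~acc).sum())
                errs.append(np.abs(dep[hit] - refb[hit]))
            err = np.concatenate(errs) if errs else np.empty(0)
            if total == 0:
                obj = np.inf
            else:
                obj = (err.sum() + gap_penalty_bins * gaps) / total
        key = (cfg.low_threshold, cfg.high_threshold, cfg.gaussian_radius)
        if best is None or obj < best[0] or (obj == best[0] and key < best[1]):
            best = (obj, key, cfg)
    assert best is not None
    return best[2]
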