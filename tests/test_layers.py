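"""Edge candidate detection, seed selection, propagation and grid tuning."""

import numpy as np
import pytest

from octlayers.core import WALL_BOUNDARIES
from octlayers.layers import (CannyConfig, EdgeCandidateSet, SeedSelection,
                              SliceCandidates, detect_edge_candidates,
                              propagate_edges, radial_derivatives,
                              select_seed_edges, tune_canny)
from octlayers.lumen import detect_lumen
from octlayers.pipeline import truth_to_flat_depths
from octlayers.preprocess import detect_guidewire, flatten_to_lumen

LBL = {"IEM": "valley1", "EEM": "peak", "ADV": "valley2"}


def _flatten(stack, truth):
    lumen = [cs.lumen for cs in truth.contours]
    return flatten_to_lumen(stack, lumen)


class TestRadialDerivatives:
    def test_linear_ramp_constant_first_derivative(self):
        frame = np.tile(np.arange(100.0), (8, 1))
        d1, d2 = radial_derivatives(frame, 2.0)
        interior = slice(10, 90)
        np.testing.assert_allclose(d1[:, interior], 1.0, atol=1e-6)
        np.testing.assert_allclose(d2[:, interior], 0.0, atol=1e-6)

    def test_symmetric_profile_gives_antisymmetric_first_derivative(self):
        x = np.arange(101.0)
        prof = np.exp(-((x - 50) / 10) ** 2)[None, :]
        d1, _ = radial_derivatives(prof, 2.0)
        np.testing.assert_allclose(d1[0], -d1[0, ::-1], atol=1e-10)

    def test_radius_too_large_rejected(self):
        with pytest.raises(ValueError):
            radial_derivatives(np.zeros((4, 30)), 20.0)


class TestCandidates:
    def test_noise_free_one_candidate_per_boundary_within_2_bins(
            self, noise_free_phantom):
        spec, stack, truth = noise_free_phantom
        flat, off = _flatten(stack, truth)
        cand = detect_edge_candidates(flat, CannyConfig())
        ref = truth_to_flat_depths(truth.contours, off, spec.radial_spacing)
        for s in range(0, spec.n_slices, 2):
            sc = cand.slices[s]
            for a in range(0, spec.n_angle_bins, 15):
                for b in WALL_BOUNDARIES:
                    d = sc.depths[a][sc.labels[a] == LBL[b]]
                    assert d.size == 1
                    assert abs(d[0] - ref[b][s, a]) <= 2.0

    def test_full_suppression_shadow_leaves_no_deep_candidates(
            self, small_phantom):
        """Inside a lipid-shadow arc no peak/valley2 candidate appears
        beyond the suppression depth."""
        spec, stack, truth = small_phantom
        flat, off = _flatten(stack, truth)
        cand = detect_edge_candidates(flat, CannyConfig())
        sec = spec.shadow_sectors[0]
        amask = sec.angle_mask(spec.n_angle_bins)
        margin = 3 * CannyConfig().gaussian_radius
        for s in range(*sec.slice_range):
            depth_bin = (sec.depth_mm / spec.radial_spacing
                         - off.offsets[s] + margin)
            sc = cand.slices[s]
            for a in np.where(amask)[0][5:-5]:
                deep = sc.depths[a] > depth_bin[a]
                bad = deep & np.isin(sc.labels[a], ["peak", "valley2"])
                assert not bad.any()


def _cands(n_angle, spec_per_bin):
    """Build a SliceCandidates from {angle: [(depth, label), ...]}."""
    depths, labels = [], []
    for a in range(n_angle):
        items = spec_per_bin.get(a, [])
        depths.append(np.array([d for d, _ in items], dtype=int))
        labels.append(np.array([l for _, l in items], dtype=object))
    return SliceCandidates(depths, labels)


class TestSeedSelection:
    def test_single_candidate_chosen_regardless_of_reference(self):
        sc = _cands(4, {a: [(50, "valley1"), (80, "peak"), (110, "valley2")]
                        for a in range(4)})
        cset = EdgeCandidateSet([sc])
        ref = {b: np.full(4, 999.0) for b in WALL_BOUNDARIES}
        seeds = select_seed_edges(cset, 0, ref)
        assert np.all(seeds.depths["IEM"] == 50)
        assert np.all(seeds.depths["EEM"] == 80)
        assert np.all(seeds.depths["ADV"] == 110)

    def test_tie_broken_toward_smaller_depth(self):
        sc = _cands(1, {0: [(40, "valley1"), (60, "valley1"),
                            (80, "peak"), (110, "valley2")]})
        seeds = select_seed_edges(EdgeCandidateSet([sc]), 0,
                                  {"IEM": np.array([50.0]),
                                   "EEM": np.array([80.0]),
                                   "ADV": np.array([110.0])})
        assert seeds.depths["IEM"][0] == 40

    def test_nearest_candidate_wins_when_reference_closer_to_first(self):
        sc = _cands(1, {0: [(40, "valley1"), (70, "valley1"),
                            (90, "peak"), (120, "valley2")]})
        seeds = select_seed_edges(EdgeCandidateSet([sc]), 0,
                                  {"IEM": np.array([52.0]),
                                   "EEM": np.array([90.0]),
                                   "ADV": np.array([120.0])})
        assert seeds.depths["IEM"][0] == 40

    def test_boundary_without_candidates_is_reported(self):
        sc = _cands(2, {0: [(50, "valley1"), (80, "peak")]})
        with pytest.raises(ValueError, match="ADV"):
            select_seed_edges(EdgeCandidateSet([sc]), 0,
                              {b: np.zeros(2) + 60 for b in WALL_BOUNDARIES})


class TestPropagation:
    def _simple_set(self, n_slices, n_angle=3, drift=0.0, extra=None):
        slices = []
        for s in range(n_slices):
            base = {a: [(int(50 + drift * s), "valley1"),
                        (int(80 + drift * s), "peak"),
                        (int(110 + drift * s), "valley2")]
                    for a in range(n_angle)}
            if extra and s in extra:
                for a, items in extra[s].items():
                    base[a] = base.get(a, []) + items
            slices.append(_cands(n_angle, base))
        return EdgeCandidateSet(slices)

    def _seeds(self, n_angle=3):
        return SeedSelection(0, {"IEM": np.full(n_angle, 50.0),
                                 "EEM": np.full(n_angle, 80.0),
                                 "ADV": np.full(n_angle, 110.0)})

    def test_spurious_candidate_outside_tolerance_never_accepted(self):
        extra = {2: {0: [(140, "valley1")]}}  # 90 bins from the track
        cset = self._simple_set(5, extra=extra)
        tracked = propagate_edges(cset, self._seeds(), tolerance=10)
        dep, acc = tracked["IEM"]
        assert acc.all()
        assert np.all(dep == 50)

    def test_candidate_free_slice_leaves_gap_and_resumes(self):
        cset = self._simple_set(5)
        cset.slices[2] = _cands(3, {})  # drop-out slice mid-stack
        tracked = propagate_edges(cset, self._seeds(), tolerance=10)
        for b in WALL_BOUNDARIES:
            dep, acc = tracked[b]
            assert not acc[2].any()
            assert acc[[0, 1, 3, 4]].all()

    def test_propagation_is_deterministic(self):
        cset = self._simple_set(6, drift=0.8)
        t1 = propagate_edges(cset, self._seeds(), tolerance=10)
        t2 = propagate_edges(cset, self._seeds(), tolerance=10)
        for b in WALL_BOUNDARIES:
            np.testing.assert_array_equal(t1[b][0], t2[b][0])

    def test_ordering_violation_demotes_whole_bin(self):
        # on slice 1 the "peak" sits beyond the valley2 track: EEM > ADV
        cset = self._simple_set(2)
        cset.slices[1] = _cands(3, {a: [(50, "valley1"), (115, "peak"),
                                        (110, "valley2")] for a in range(3)})
        tracked = propagate_edges(cset, self._seeds(), tolerance=40)
        for b in WALL_BOUNDARIES:
            assert not tracked[b][1][1].any()

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            propagate_edges(self._simple_set(2), self._seeds(), tolerance=0)


def test_noise_free_end_to_end_within_two_bins(noise_free_phantom):
    """Without noise or shadows the tracked boundaries match truth to +/-2
    radial bins at every angle bin of every slice."""
    spec, stack, truth = noise_free_phantom
    stack = stack.copy()
    stack.guidewire_mask = detect_guidewire(stack)
    lumen = detect_lumen(stack)
    flat, off = flatten_to_lumen(stack, lumen)
    cand = detect_edge_candidates(flat, CannyConfig())
    ref = truth_to_flat_depths(truth.contours, off, spec.radial_spacing)
    seeds = select_seed_edges(cand, 0, {b: ref[b][0] for b in WALL_BOUNDARIES})
    tracked = propagate_edges(cand, seeds, tolerance=10)
    for b in WALL_BOUNDARIES:
        dep, acc = tracked[b]
        assert acc.all()
        assert np.all(np.abs(dep - ref[b]) <= 2.0)


def test_speckled_recall_above_90_percent(small_phantom):
    """With speckle on, a correctly-labeled candidate lies within 3 bins of
    the true boundary on at least 90% of non-occluded angle bins."""
    spec, stack, truth = small_phantom
    flat, off = _flatten(stack, truth)
    cand = detect_edge_candidates(flat, CannyConfig())
    ref = truth_to_flat_depths(truth.contours, off, spec.radial_spacing)
    occl = truth.shadow_mask | truth.guidewire_mask
    for b in WALL_BOUNDARIES:
        hits = total = 0
        for s in range(spec.n_slices):
            sc = cand.slices[s]
            for a in np.where(~occl[s])[0]:
                total += 1
                d = sc.depths[a][sc.labels[a] == LBL[b]]
                if d.size and np.abs(d - ref[b][s, a]).min() <= 3.0:
                    hits += 1
        assert hits / total >= 0.90, b


class TestTuneCanny:
    def _setup(self, noise_free_phantom):
        spec, stack, truth = noise_free_phantom
        flat, off = _flatten(stack, truth)
        ref = truth_to_flat_depths(truth.contours, off, spec.radial_spacing)
        return flat, ref

    def test_single_point_grid_returns_that_point(self, noise_free_phantom):
        flat, ref = self._setup(noise_free_phantom)
        cfg = tune_canny(flat, ref, lows=[0.03], radii=[5.0])
        assert (cfg.low_threshold, cfg.gaussian_radius) == (0.03, 5.0)

    def test_empty_grid_rejected(self, noise_free_phantom):
        flat, ref = self._setup(noise_free_phantom)
        with pytest.raises(ValueError):
            tune_canny(flat, ref, lows=[], radii=[])

    def test_returned_config_minimizes_grid_objective(self, noise_free_phantom):
        """Re-evaluating every grid point never beats the returned config."""
        flat, ref = self._setup(noise_free_phantom)
        lows, radii = [0.03, 0.08], [3.0, 5.0]
        best = tune_canny(flat, ref, lows=lows, radii=radii)

        def objective(cfg):
            cand = detect_edge_candidates(flat, cfg)
            try:
                seeds = select_seed_edges(cand, 0,
                                          {b: ref[b][0] for b in WALL_BOUNDARIES})
            except ValueError:
                return np.inf
            tracked = propagate_edges(cand, seeds, 10.0)
            err_sum = gaps = total = 0.0
            for b in WALL_BOUNDARIES:
                dep, acc = tracked[b]
                total += np.isfinite(ref[b]).sum()
                gaps += (~acc).sum()
                err_sum += np.abs(dep[acc] - ref[b][acc]).sum()
            return (err_sum + 10.0 * gaps) / total

        best_obj = objective(best)
        for lo in lows:
            for r in radii:
                assert best_obj <= objective(CannyConfig(lo, 2 * lo, r)) + 1e-9
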