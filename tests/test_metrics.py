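"""Nodal correspondence, thickness tensor statistics and error equations."""

import numpy as np
import pytest

from octlayers.core import LayerContourSet, RadialContour, angle_grid
from octlayers.metrics import (N_NODES, N_PER_QUARTER, ThicknessTensor,
                               build_nodal_set, contour_distance,
                               distance_stats, error_percentile,
                               thickness_error, thickness_stats)


def _contour(radii, n=360):
    r = radii if np.ndim(radii) else np.full(n, float(radii))
    return RadialContour(np.asarray(r, float), np.ones(len(np.atleast_1d(r)) if np.ndim(radii) else n, bool), 0)


def _circles(r_lumen=1.5, r_iem=2.0, r_eem=2.2, r_adv=2.4):
    return LayerContourSet(_contour(r_lumen), _contour(r_iem),
                           _contour(r_eem), _contour(r_adv))


class TestNodalSet:
    def test_concentric_circles_give_constant_layer_thickness(self):
        ns = build_nodal_set(_circles())
        np.testing.assert_allclose(ns.thickness[0], 0.5, atol=1e-3)
        np.testing.assert_allclose(ns.thickness[1], 0.2, atol=1e-3)
        np.testing.assert_allclose(ns.thickness[2], 0.2, atol=1e-3)

    def test_structure_100_points_25_per_quarter(self):
        th = angle_grid(360)
        wavy = 1.5 + 0.2 * np.cos(th) + 0.1 * np.sin(2 * th)
        cs = LayerContourSet(_contour(wavy), _contour(wavy + 0.5),
                             _contour(wavy + 0.75), _contour(wavy + 1.0))
        ns = build_nodal_set(cs)
        assert ns.lumen_points.shape == (N_NODES, 2)
        cx, cy = ns.centroid
        phi = np.mod(np.arctan2(ns.lumen_points[:, 1] - cy,
                                ns.lumen_points[:, 0] - cx), 2 * np.pi)
        quarters = np.floor(phi / (np.pi / 2)).astype(int)
        assert np.bincount(quarters, minlength=4).tolist() == [N_PER_QUARTER] * 4

    def test_ellipse_thickness_matches_minimum_distance_within_2pct(self):
        th = angle_grid(360)

        def ellipse(a, b):
            return a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)

        cs = LayerContourSet(_contour(ellipse(1.5, 1.2)),
                             _contour(ellipse(2.0, 1.7)),
                             _contour(ellipse(2.2, 1.9)),
                             _contour(ellipse(2.4, 2.1)))
        ns = build_nodal_set(cs)
        # dense brute-force minimum distance from each lumen node to the IEM
        tt = np.linspace(0, 2 * np.pi, 20000)
        rr = 2.0 * 1.7 / np.sqrt((1.7 * np.cos(tt)) ** 2 + (2.0 * np.sin(tt)) ** 2)
        P = np.column_stack([rr * np.cos(tt), rr * np.sin(tt)])
        dmin = np.array([np.linalg.norm(P - p, axis=1).min()
                         for p in ns.lumen_points])
        assert np.all(np.abs(ns.thickness[0] - dmin) / dmin <= 0.02)

    def test_layer_thicknesses_add_up_to_the_connecting_path(self):
        th = angle_grid(360)
        wavy = 1.4 + 0.15 * np.cos(th + 0.4) + 0.05 * np.cos(2 * th)
        cs = LayerContourSet(_contour(wavy), _contour(wavy + 0.45),
                             _contour(wavy + 0.7), _contour(wavy + 0.95))
        ns = build_nodal_set(cs)
        assert np.all(ns.thickness >= 0)
        path = (np.linalg.norm(ns.boundary_points["IEM"] - ns.lumen_points, axis=1)
                + np.linalg.norm(ns.boundary_points["EEM"]
                                 - ns.boundary_points["IEM"], axis=1)
                + np.linalg.norm(ns.boundary_points["ADV"]
                                 - ns.boundary_points["EEM"], axis=1))
        np.testing.assert_allclose(ns.total_thickness, path, atol=1e-12)


def _random_tensor(rng, m_per_patient):
    return ThicknessTensor([0.2 + rng.uniform(0.0, 0.8, (3, N_NODES, m))
                            for m in m_per_patient])


def loop_slice_means(T):
    out = []
    for a in T.per_patient:
        sm = np.zeros((3, a.shape[2]))
        for q in range(3):
            for j in range(a.shape[2]):
                sm[q, j] = sum(a[q, i, j] for i in range(N_NODES)) / N_NODES
        out.append(sm)
    return out


class TestThicknessStats:
    def test_uniform_tensor_returns_the_constant_at_every_level(self):
        T = ThicknessTensor([np.full((3, N_NODES, 4), 0.5),
                             np.full((3, N_NODES, 2), 0.5)])
        assert np.allclose(thickness_stats(T, "patient")["patient_mean"], 0.5)
        allv = thickness_stats(T, "all")
        assert np.allclose(allv["all_mean_pooled"], 0.5)
        assert np.allclose(allv["all_mean_equal_patient"], 0.5)

    def test_two_slices_with_means_04_and_06_average_to_05(self):
        a = np.empty((3, N_NODES, 2))
        a[:, :, 0], a[:, :, 1] = 0.4, 0.6
        T = ThicknessTensor([a])
        assert np.allclose(thickness_stats(T, "patient")["patient_mean"], 0.5)

    def test_matches_brute_force_loop_oracle(self):
        rng = np.random.default_rng(0)
        T = _random_tensor(rng, [5, 3, 4])
        sm_oracle = loop_slice_means(T)
        sm = thickness_stats(T, "slice")["slice_mean"]
        for got, exp in zip(sm, sm_oracle):
            np.testing.assert_allclose(got, exp, rtol=1e-10)
        # patient level: mean over slices of slice means
        pat = thickness_stats(T, "patient")["patient_mean"]
        for k, exp in enumerate(sm_oracle):
            np.testing.assert_allclose(pat[:, k], exp.mean(axis=1), rtol=1e-10)
        # pooled: every (i, j, k) sample weighted equally
        allv = thickness_stats(T, "all")
        total = np.zeros(3)
        count = 0
        for a in T.per_patient:
            total += a.sum(axis=(1, 2))
            count += a.shape[1] * a.shape[2]
        np.testing.assert_allclose(allv["all_mean_pooled"], total / count,
                                   rtol=1e-10)
        np.testing.assert_allclose(allv["all_mean_equal_patient"],
                                   pat.mean(axis=1), rtol=1e-10)

    def test_empty_tensor_rejected(self):
        with pytest.raises(ValueError):
            thickness_stats(ThicknessTensor([]), "all")


class TestThicknessError:
    def test_uniform_10pct_difference_at_every_level(self):
        Ta = ThicknessTensor([np.full((3, N_NODES, 3), 1.1)])
        Tm = ThicknessTensor([np.full((3, N_NODES, 3), 1.0)])
        res = thickness_error(Ta, Tm, "all")
        np.testing.assert_allclose(res["all_error"], 10.0, atol=1e-10)
        np.testing.assert_allclose(res["patient_error"], 10.0, atol=1e-10)

    def test_identical_tensors_give_zero_error(self):
        rng = np.random.default_rng(1)
        T = _random_tensor(rng, [4])
        res = thickness_error(T, T, "all")
        np.testing.assert_allclose(res["all_error"], 0.0, atol=1e-12)

    def test_matches_brute_force_equation_oracle(self):
        rng = np.random.default_rng(2)
        Ta = _random_tensor(rng, [4, 3])
        Tm = _random_tensor(rng, [4, 3])
        res = thickness_error(Ta, Tm, "all")
        # independent nested-loop evaluation of the slice/patient/overall
        # signed relative errors
        per_patient = []
        for a, m in zip(Ta.per_patient, Tm.per_patient):
            errs = np.zeros((3, a.shape[2]))
            for q in range(3):
                for j in range(a.shape[2]):
                    num = sum(a[q, i, j] - m[q, i, j]
                              for i in range(N_NODES)) / N_NODES
                    den = sum(m[q, i, j] for i in range(N_NODES)) / N_NODES
                    errs[q, j] = 100.0 * num / den
            per_patient.append(errs)
        pat = np.stack([e.mean(axis=1) for e in per_patient], axis=1)
        np.testing.assert_allclose(res["patient_error"], pat, rtol=1e-10)
        np.testing.assert_allclose(res["all_error"], pat.mean(axis=1),
                                   rtol=1e-10)

    def test_negative_error_means_automatic_thinner(self):
        Ta = ThicknessTensor([np.full((3, N_NODES, 2), 0.9)])
        Tm = ThicknessTensor([np.full((3, N_NODES, 2), 1.0)])
        assert np.all(thickness_error(Ta, Tm, "all")["all_error"] < 0)

    def test_zero_manual_slice_excluded_and_counted(self):
        a = np.full((3, N_NODES, 2), 1.0)
        m = np.full((3, N_NODES, 2), 1.0)
        m[:, :, 1] = 0.0
        res = thickness_error(ThicknessTensor([a]), ThicknessTensor([m]), "all")
        assert res["n_excluded"] == 3
        np.testing.assert_allclose(res["all_error"], 0.0, atol=1e-12)


class TestContourDistance:
    def test_identical_contours_zero(self):
        r = 2.0 + 0.1 * np.cos(angle_grid(360))
        d = contour_distance(r, r)
        np.testing.assert_allclose(d, 0.0, atol=1e-15)

    def test_uniform_offset_recovered_with_sign(self):
        r = 2.0 + 0.1 * np.cos(angle_grid(360))
        stats = distance_stats([r - 0.05], [r])
        assert abs(stats["mean"] + 0.05) < 1e-12

    def test_matches_per_angle_loop(self):
        rng = np.random.default_rng(3)
        a = 2.0 + 0.1 * rng.standard_normal(360)
        m = 2.0 + 0.1 * rng.standard_normal(360)
        d = contour_distance(a, m)
        for i in range(0, 360, 37):
            assert d[i] == a[i] - m[i]

    def test_grid_mismatch_resampled_periodically(self):
        th180 = angle_grid(180)
        a = 2.0 + 0.1 * np.cos(th180)
        m = 2.0 + 0.1 * np.cos(angle_grid(360))
        d = contour_distance(a, m)
        assert d.size == 360
        assert np.abs(d).max() < 1e-3


class TestErrorPercentile:
    def test_constant_errors_return_the_constant(self):
        assert error_percentile(np.full(12, 7.0), 90) == 7.0

    def test_1_to_100_matches_sort_and_interpolate_oracle(self):
        errs = np.arange(1.0, 101.0)
        got = error_percentile(errs, 90)
        # linear-interpolation convention on the order statistics
        sorted_abs = np.sort(np.abs(errs))
        pos = 0.90 * (len(errs) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        exp = sorted_abs[lo] + (pos - lo) * (sorted_abs[hi] - sorted_abs[lo])
        assert got == pytest.approx(exp, rel=1e-12)

    def test_sign_flip_invariant(self):
        rng = np.random.default_rng(4)
        e = rng.standard_normal(50) * 10
        assert error_percentile(e, 90) == error_percentile(-e, 90)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            error_percentile(np.array([]), 90)
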