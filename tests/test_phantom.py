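"""ROI detection, vial statistics, the statistical battery, and calibration."""

import numpy as np
import pytest

import o17relax as o
from o17relax.phantom import _layout_centers_voxel


def make_stats(concs, medians):
    return [
        o.VialStats(vial_id=i, concentration=c, median_rate=m,
                    iqr_rate=0.0, n_voxels=10, n_repeats=1)
        for i, (c, m) in enumerate(zip(concs, medians))
    ]


def uniform_rate_map(shape, rate, voxel_size=(1.67, 1.67, 5.0)):
    r = np.full(shape, float(rate))
    return o.ParametricMap(
        time_map=1000.0 / r, rate_map=r, amplitude_map=np.full(shape, 1000.0),
        converged_mask=np.ones(shape, bool), rss_map=np.zeros(shape),
        voxel_size_mm=voxel_size,
    )


class TestRoiDetection:
    def test_thirteen_vials_found_with_accurate_centers(self, layout_pair,
                                                        noisy_phantom_series):
        layout = layout_pair[0]
        rois = o.detect_vial_rois(noisy_phantom_series, layout)
        assert len(rois) == 13
        centers = _layout_centers_voxel(layout, noisy_phantom_series)
        for roi in rois:
            vx, vy = centers[roi.vial_id]
            assert np.hypot(roi.center_voxel[0] - vx, roi.center_voxel[1] - vy) < 1.0

    def test_target_area_gives_42_voxels_at_scanner_resolution(self,
                                                               noisy_phantom_series):
        # 118 mm^2 / (1.67 mm)^2 = 42.31 -> 42 voxels per ROI-slice
        rois = o.detect_vial_rois(noisy_phantom_series, target_area_mm2=118.0)
        for roi in rois:
            assert len(roi.rows) == 42

    def test_roi_area_within_one_voxel_of_target(self, noisy_phantom_series):
        voxel_area = noisy_phantom_series.protocol.in_plane_voxel_area_mm2
        for roi in o.detect_vial_rois(noisy_phantom_series, target_area_mm2=118.0):
            assert abs(roi.area_mm2 - 118.0) <= voxel_area

    def test_noise_only_image_raises_detection_error(self, tse_protocol):
        rng = np.random.default_rng(0)
        p = o.tse_t2_protocol(matrix_shape=(32, 32, 1))
        series = o.ImageSeries(data=rng.rayleigh(5.0, (32, 32, 1, 8)), protocol=p,
                               frame_axis_meaning="echo")
        with pytest.raises(o.DetectionError):
            o.detect_vial_rois(series)

    def test_missing_vials_warn_with_partial_result(self, layout_pair, tse_protocol):
        # render only the three control vials but match against the full layout
        small = o.make_phantom_layout([])
        truth = o.phantom_ground_truth(small, tse_protocol)
        series = o.simulate_multiecho_series(truth, tse_protocol)
        with pytest.warns(UserWarning, match="13"):
            rois = o.detect_vial_rois(series, layout_pair[0])
        assert len(rois) == 3


class TestVialStats:
    def test_uniform_rate_yields_median_and_zero_iqr(self, layout_pair, tse_protocol):
        layout = layout_pair[0]
        truth = o.phantom_ground_truth(layout, tse_protocol)
        series = o.simulate_multiecho_series(truth, tse_protocol)
        rois = o.detect_vial_rois(series, layout)
        pm = uniform_rate_map(series.shape, 2.0)
        stats = o.summarize_vials(pm, rois, layout)
        assert all(s.median_rate == pytest.approx(2.0) for s in stats)
        assert all(s.iqr_rate == pytest.approx(0.0, abs=1e-12) for s in stats)

    def test_quartiles_use_linear_interpolation(self):
        # pooled {1,2,3,4,5}: median 3, q1 = 2, q3 = 4 -> IQR 2
        sample = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        q1, q2, q3 = np.percentile(sample, [25, 50, 75], method="linear")
        assert (q2, q3 - q1) == (3.0, 2.0)
        shape = (5, 1, 1)
        pm = uniform_rate_map(shape, 1.0)
        pm.rate_map[:, 0, 0] = sample
        pm.time_map[:, 0, 0] = 1000.0 / sample
        roi = o.VialROI(center_voxel=(2.0, 0.0), radius_voxels=3.0,
                        slice_indices=(0,), area_mm2=118.0, vial_id=0,
                        rows=np.arange(5), cols=np.zeros(5, int))
        layout = o.make_phantom_layout([])
        stats = o.summarize_vials(pm, [roi], layout)
        assert stats[0].median_rate == 3.0
        assert stats[0].iqr_rate == 2.0

    def test_unmatched_roi_raises_pairing_error(self):
        pm = uniform_rate_map((4, 4, 1), 2.0)
        roi = o.VialROI(center_voxel=(1.0, 1.0), radius_voxels=1.0,
                        slice_indices=(0,), area_mm2=1.0, vial_id=None,
                        rows=np.array([1]), cols=np.array([1]))
        with pytest.raises(o.PairingError):
            o.summarize_vials(pm, [roi], o.make_phantom_layout([]))

    def test_pooled_repeats_recover_truth(self, layout_pair, tse_protocol):
        """Thirty SNR-50 repeats: medians within 2% in the linear-fit regime.

        Vials near natural abundance have T2 ~ 3 s, so the 160-ms echo
        train carries little decay information there; censoring of
        non-physical (non-decaying) voxel fits then biases those medians
        up by a few percent, which is tolerated separately.
        """
        layout = layout_pair[0]
        truth = o.phantom_ground_truth(layout, tse_protocol)
        sigma = o.sigma_for_first_echo_snr(truth, tse_protocol, 50.0)
        maps, first = [], None
        for rep in range(30):
            nm = o.NoiseModel(kind="rician", sigma=sigma, seed=40 + rep)
            series = o.simulate_multiecho_series(truth, tse_protocol, nm)
            first = first or series
            maps.append(o.fit_monoexp(series))
        rois = o.detect_vial_rois(first, layout)
        conc = dict(layout.vial_assignments)
        for s in o.summarize_vials(maps, rois, layout):
            expected = 0.405 * conc[s.vial_id] + 0.3215
            tol = 0.02 if conc[s.vial_id] >= 0.245 else 0.05
            assert s.median_rate == pytest.approx(expected, rel=tol)
            assert s.n_repeats == 30


class TestStatisticalBattery:
    def test_monotone_stats_give_rho_one(self):
        stats = make_stats([0.1, 0.5, 1.0, 2.0, 4.0], [1, 2, 3, 4, 5])
        rho, _ = o.spearman_vs_concentration(stats)
        assert rho == pytest.approx(1.0)

    def test_antitone_stats_give_rho_minus_one(self):
        stats = make_stats([0.1, 0.5, 1.0, 2.0, 4.0], [5, 4, 3, 2, 1])
        rho, _ = o.spearman_vs_concentration(stats)
        assert rho == pytest.approx(-1.0)

    def test_rho_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(12)
        c = np.arange(1.0, 11.0)
        m = rng.permutation(10).astype(float)
        stats = make_stats(c, m)
        rho, _ = o.spearman_vs_concentration(stats)
        # no ties: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        d = np.argsort(np.argsort(c)) - np.argsort(np.argsort(m))
        oracle = 1 - 6 * (d**2).sum() / (10 * 99)
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_is_undefined_correlation(self):
        with pytest.raises(o.ValidationError):
            o.spearman_vs_concentration(make_stats([1, 2, 3, 4], [2, 2, 2, 2]))

    def test_shapiro_null_calibration_and_power(self):
        """Under the null ~95% of p-values exceed 0.05 (binomial error
        allows a few either way); a log-normal sample is firmly rejected."""
        rng = np.random.default_rng(0)
        above = sum(o.normality_test(rng.normal(size=500))[1] > 0.05
                    for _ in range(100))
        assert above >= 90  # 95 expected, sd ~2.2
        w, p = o.normality_test(np.exp(rng.normal(size=500) * 1.5))
        assert p < 1e-3

    def test_shapiro_rejects_tiny_samples(self):
        with pytest.raises(o.ValidationError):
            o.normality_test([1.0, 2.0])


class TestGamesHowell:
    def test_identical_large_samples_give_p_near_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 500)
        table = o.games_howell_pairwise([(1.0, x), (2.0, x + rng.normal(0, 1e-6, 500))])
        assert table.p_adj.iloc[0] > 0.95

    def test_separated_groups_strongly_rejected(self):
        # means 2.0 vs 2.6 s^-1, sigma 0.1, n = 30 per group
        rng = np.random.default_rng(5)
        a = rng.normal(2.0, 0.1, 30)
        b = rng.normal(2.6, 0.1, 30)
        table = o.games_howell_pairwise([(3.1, a), (5.5, b)])
        assert table.p_adj.iloc[0] < 1e-3

    def test_zero_variance_conventions(self):
        same = [(1.0, [2.0, 2.0]), (2.0, [2.0, 2.0])]
        diff = [(1.0, [2.0, 2.0]), (2.0, [3.0, 3.0])]
        assert o.games_howell_pairwise(same).p_adj.iloc[0] == 1.0
        assert o.games_howell_pairwise(diff).p_adj.iloc[0] == 0.0

    def test_matches_pingouin_reference_on_five_groups(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(8)
        groups = [(float(i), rng.normal(i * 0.3, 0.5 + 0.1 * i, 12 + 2 * i))
                  for i in range(5)]
        table = o.games_howell_pairwise(groups)
        df = pd.DataFrame({
            "y": np.concatenate([x for _, x in groups]),
            "g": np.concatenate([[c] * len(x) for c, x in groups]),
        })
        ref = pingouin.pairwise_gameshowell(data=df, dv="y", between="g")
        merged = table.merge(ref, left_on=["group_a", "group_b"],
                             right_on=["A", "B"])
        assert len(merged) == 10
        np.testing.assert_allclose(merged.p_adj, merged.pval, atol=0.01)
        np.testing.assert_allclose(np.abs(merged.mean_diff), np.abs(merged["diff"]),
                                   rtol=1e-9)

    def test_null_phantom_false_positive_rate_below_five_percent(self, tse_protocol):
        # all 13 vials at natural abundance: any rejection is a false positive
        layout = o.make_phantom_layout([0.037] * 10)
        truth = o.phantom_ground_truth(layout, tse_protocol)
        sigma = o.sigma_for_first_echo_snr(truth, tse_protocol, 50.0)
        rates = []
        for seed in range(6):
            nm = o.NoiseModel(kind="rician", sigma=sigma, seed=200 + seed)
            series = o.simulate_multiecho_series(truth, tse_protocol, nm)
            pm = o.fit_monoexp(series)
            rois = o.detect_vial_rois(series, layout)
            groups = []
            for roi in rois:
                vals = pm.rate_map[roi.rows, roi.cols, 0]
                groups.append((roi.concentration, vals[np.isfinite(vals)]))
            table = o.games_howell_pairwise(groups)
            rates.append((table.p_adj < 0.05).mean())
        assert np.mean(rates) <= 0.05


class TestCalibration:
    def test_exact_points_recover_printed_constants(self):
        in_range = [c for c in o.CANONICAL_CONCENTRATIONS if 0.245 <= c <= 5.5]
        assert len(in_range) == 11
        stats = make_stats(in_range, [0.405 * c + 0.3215 for c in in_range])
        model = o.fit_calibration(stats)
        assert model.slope == pytest.approx(0.405, rel=1e-12)
        assert model.intercept == pytest.approx(0.3215, rel=1e-12)
        assert model.n_points == 11

    def test_two_points_give_interpolating_line(self):
        stats = make_stats([1.0, 2.0], [1.0, 3.0])
        model = o.fit_calibration(stats, fit_range=(0.5, 2.5))
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(-1.0)

    def test_out_of_range_vials_excluded(self):
        concs = [0.037, 1.0, 2.0, 3.0, 6.5]
        stats = make_stats(concs, [0.405 * c + 0.3215 for c in concs])
        stats[-1].median_rate = 99.0  # corrupt the 6.5% vial; must not matter
        model = o.fit_calibration(stats)
        assert model.slope == pytest.approx(0.405, rel=1e-9)
        assert model.n_points == 3

    def test_insufficient_in_range_vials_rejected(self):
        stats = make_stats([0.037, 6.5], [0.3, 3.0])
        with pytest.raises(o.InsufficientDataError):
            o.fit_calibration(stats)

    def test_ols_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        c = rng.uniform(0.3, 5.0, 10)
        r = 0.4 * c + 0.3 + rng.normal(0, 0.05, 10)
        stats = make_stats(c, r)
        model = o.fit_calibration(stats, fit_range=(0.0, 6.0))
        x = np.column_stack([c, np.ones(10)])
        beta = np.linalg.solve(x.T @ x, x.T @ r)
        assert model.slope == pytest.approx(beta[0], abs=1e-10)
        assert model.intercept == pytest.approx(beta[1], abs=1e-10)


class TestConcentrationInversion:
    def model(self):
        return o.CalibrationModel(slope=0.405, intercept=0.3215,
                                  fit_range=(0.245, 5.5), r_spearman=1.0, n_points=11)

    def test_printed_rate_inverts_to_55_percent(self):
        c, ok = o.estimate_concentration(2.549, self.model())
        assert c == pytest.approx(5.5, rel=1e-9)
        assert ok

    def test_intercept_rate_flagged_out_of_range(self):
        c, ok = o.estimate_concentration(0.3215, self.model())
        assert c == pytest.approx(0.0, abs=1e-12)
        assert not ok

    def test_forward_inverse_identity_in_range(self):
        rng = np.random.default_rng(10)
        concs = rng.uniform(0.245, 5.5, 100)
        r2 = 0.405 * concs + 0.3215
        est, ok = o.estimate_concentration(r2, self.model())
        np.testing.assert_allclose(est, concs, rtol=1e-12)
        assert ok.all()

    def test_zero_slope_cannot_invert(self):
        model = o.CalibrationModel(slope=0.0, intercept=0.3, fit_range=(0.245, 5.5),
                                   r_spearman=0.0, n_points=5)
        with pytest.raises(o.ValidationError):
            o.estimate_concentration(1.0, model)
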