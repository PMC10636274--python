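"""EIC extraction, smoothing, noise/baseline estimation, peak matching and
integration bounds."""

import numpy as np
import pytest

from conftest import gaussian_eic, make_gln_target, make_method
from midquant.chromatography import (
    EIC,
    IsotopicCluster,
    estimate_baseline,
    estimate_noise,
    extract_cluster,
    find_bounds,
    match_peak,
    prepare_cluster,
    smooth,
    warp_rt,
)
from midquant.errors import EmptyEICError, PeakNotFoundError
from midquant.method import MzTolerance


def make_cluster(composite: EIC, method=None, noise=None, baseline=None):
    """Single-channel cluster around a prepared composite trace."""
    method = method or make_method()
    cluster = IsotopicCluster(
        target=make_gln_target(),
        channel_eics=[composite],
        composite=composite,
    )
    prepare_cluster(cluster, method)
    if noise is not None:
        cluster.noise_level = noise
    if baseline is not None:
        cluster.baseline = np.full(composite.intensity.size, baseline,
                                   dtype=float)
    return cluster


class TestExtractEic:
    def test_recovers_generated_trace(self, tmp_path, gln_method):
        from midquant.io_raw import read_run
        from midquant.synthetic import TruthSpec, write_synthetic_run

        truth = TruthSpec("Gln [M+H]+", np.array([1, 0, 0, 0, 0, 0.0]),
                          apex_rt=60.0, sigma=4.0, apex_intensity=1e6)
        path = tmp_path / "run.mzML"
        write_synthetic_run([truth], gln_method, path, seed=0)
        run = read_run(path)
        cluster = extract_cluster(run, gln_method.targets[0], gln_method)
        # channel 0 should carry nearly all intensity of the unlabeled peak
        apex = np.argmax(cluster.composite.intensity)
        assert cluster.composite.rt[apex] == pytest.approx(60.0, abs=0.5)
        frac = (cluster.channel_eics[0].intensity[apex]
                / cluster.composite.intensity[apex])
        assert frac == pytest.approx(0.9477, abs=0.01)  # 0.9893**5

    def test_far_mz_gives_all_zero_full_length(self, tmp_path, gln_method):
        from midquant.io_raw import read_run
        from midquant.synthetic import TruthSpec, write_synthetic_run
        from midquant.chromatography import extract_eic

        truth = TruthSpec("Gln [M+H]+", np.array([1, 0, 0, 0, 0, 0.0]),
                          apex_rt=60.0, sigma=4.0, apex_intensity=1e6)
        path = tmp_path / "run.mzML"
        write_synthetic_run([truth], gln_method, path, seed=0)
        run = read_run(path)
        eic = extract_eic(run, 999.9, gln_method.mz_tolerance)
        assert eic.rt.size == len(run.scans)
        assert np.all(eic.intensity == 0)

    def test_no_ms2_scans_raises(self, tmp_path, gln_method):
        from midquant.io_raw import read_run
        from midquant.synthetic import TruthSpec, write_synthetic_run
        from midquant.chromatography import extract_eic

        truth = TruthSpec("Gln [M+H]+", np.array([1, 0, 0, 0, 0, 0.0]),
                          apex_rt=60.0, sigma=4.0, apex_intensity=1e6)
        path = tmp_path / "run.mzML"
        write_synthetic_run([truth], gln_method, path, seed=0)
        run = read_run(path)
        with pytest.raises(EmptyEICError):
            extract_eic(run, 147.0, gln_method.mz_tolerance, ms_level=2,
                        precursor=147.0)

    def test_ppm_window_scales_with_mz(self):
        tol = MzTolerance(10, "ppm")
        assert tol.half_width(500.0) == pytest.approx(0.005)
        assert MzTolerance(0.3, "Th").half_width(500.0) == 0.3


class TestWarpRt:
    def test_exact_anchors_give_identity(self):
        warp = warp_rt([(100.0, 100.0), (200.0, 200.0)])
        assert warp(150.0) == pytest.approx(150.0)

    def test_single_anchor_constant_offset(self):
        warp = warp_rt([(100.0, 105.0)])
        assert warp(50.0) == pytest.approx(55.0)
        assert warp(300.0) == pytest.approx(305.0)

    def test_two_anchors_interpolate_linearly(self):
        warp = warp_rt([(100.0, 102.0), (200.0, 206.0)])
        assert warp(100.0) == pytest.approx(102.0)
        assert warp(150.0) == pytest.approx(154.0)  # offset 2 + (6-2)/2
        assert warp(200.0) == pytest.approx(206.0)
        # flat extrapolation beyond outermost anchors
        assert warp(300.0) == pytest.approx(306.0)

    def test_no_anchors_identity_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            warp = warp_rt([])
        assert warp(42.0) == 42.0
        assert any("identity" in r.message for r in caplog.records)


class TestSmoothing:
    def test_polynomial_signals_reproduced_exactly(self):
        t = np.arange(0, 50, 0.5)
        for coeffs in [(2.0,), (1.0, 3.0), (0.5, -2.0, 7.0), (0.1, 0.5, -1, 4)]:
            y = np.polyval(coeffs, t)
            y = y - y.min()  # keep non-negative so clamping is inert
            eic = EIC(rt=t, intensity=y, target_mz=100.0)
            out = smooth(eic, window=7, order=3)
            np.testing.assert_allclose(out.intensity, y, atol=1e-9)

    def test_interior_matches_published_sg_7_3_coefficients(self):
        # classic 7-point cubic Savitzky-Golay weights: (-2,3,6,7,6,3,-2)/21
        rng = np.random.default_rng(7)
        y = rng.uniform(10, 100, 50)
        eic = EIC(rt=np.arange(50.0), intensity=y, target_mz=100.0)
        out = smooth(eic, window=7, order=3)
        weights = np.array([-2, 3, 6, 7, 6, 3, -2]) / 21.0
        expected = np.convolve(y, weights[::-1], mode="valid")
        np.testing.assert_allclose(out.intensity[3:-3],
                                   np.clip(expected, 0, None), atol=1e-9)

    def test_short_eic_returned_unchanged_with_warning(self):
        eic = EIC(rt=np.arange(5.0), intensity=np.ones(5), target_mz=100.0)
        with pytest.warns(UserWarning, match="shorter"):
            out = smooth(eic, window=7, order=3)
        np.testing.assert_array_equal(out.intensity, eic.intensity)

    def test_negative_outputs_clamped(self):
        y = np.zeros(21)
        y[10] = 100.0  # impulse: SG filter rings negative nearby
        eic = EIC(rt=np.arange(21.0), intensity=y, target_mz=100.0)
        out = smooth(eic, window=7, order=3)
        assert np.all(out.intensity >= 0)


class TestNoiseEstimate:
    def test_all_zero_is_zero(self):
        eic = EIC(rt=np.arange(10.0), intensity=np.zeros(10), target_mz=100.0)
        assert estimate_noise(eic) == 0.0

    def test_gaussian_noise_scale_recovered(self):
        rng = np.random.default_rng(42)
        y = np.abs(1000 + rng.normal(0, 100, 10_000))
        eic = EIC(rt=np.arange(10_000.0), intensity=y, target_mz=100.0)
        assert estimate_noise(eic) == pytest.approx(100.0, rel=0.05)

    def test_smooth_peak_contributes_little(self):
        eic = gaussian_eic(apex=1e6, sigma=4.0)
        assert estimate_noise(eic) < 0.01 * 1e6


class TestBaselineEstimate:
    def test_flat_signal_is_its_own_baseline(self):
        eic = EIC(rt=np.arange(50.0), intensity=np.full(50, 50.0),
                  target_mz=100.0)
        np.testing.assert_allclose(estimate_baseline(eic), 50.0)

    def test_zero_baseline_gaussian(self):
        eic = gaussian_eic()
        assert np.max(estimate_baseline(eic)) < 1e-3 * 1e6

    def test_linear_drift_recovered_at_ends(self):
        a, b = 500.0, 10.0
        eic = gaussian_eic(baseline=a, drift=b)
        baseline = estimate_baseline(eic)
        true = a + b * (eic.rt - eic.rt[0])
        assert baseline[0] == pytest.approx(true[0], rel=0.10)
        assert baseline[-1] == pytest.approx(true[-1], rel=0.10)


class TestMatchPeak:
    def test_single_candidate_returned(self):
        cluster = make_cluster(gaussian_eic(apex_rt=60.0))
        apex = match_peak(cluster, expected_rt=58.0, rt_window=20.0)
        assert cluster.composite.rt[apex] == pytest.approx(60.0, abs=0.5)

    def test_closer_of_two_equal_peaks_wins(self):
        t = np.arange(0, 120, 0.5)
        y = (1e6 * np.exp(-((t - 62) ** 2) / (2 * 3**2))
             + 1e6 * np.exp(-((t - 80) ** 2) / (2 * 3**2)))
        cluster = make_cluster(EIC(rt=t, intensity=y, target_mz=150.0))
        apex = match_peak(cluster, expected_rt=60.0, rt_window=30.0)
        assert cluster.composite.rt[apex] == pytest.approx(62.0, abs=0.5)

    def test_rt_term_beats_height_at_hand_computed_scores(self):
        # candidates: (drt=5 s, rel height 1.0) vs (drt=0, rel height 0.5)
        # with sigma = 15: scores 0.946 vs 0.500 -> the taller, farther one
        t = np.arange(0, 120, 0.5)
        y = (1e6 * np.exp(-((t - 65) ** 2) / (2 * 2.5**2))
             + 5e5 * np.exp(-((t - 60) ** 2) / (2 * 2.5**2)))
        cluster = make_cluster(EIC(rt=t, intensity=y, target_mz=150.0))
        apex = match_peak(cluster, expected_rt=60.0, rt_window=30.0)
        assert cluster.composite.rt[apex] == pytest.approx(65.0, abs=0.5)
        # sanity-check the hand arithmetic of the scoring formula
        assert np.exp(-(5.0**2) / (2 * 15.0**2)) == pytest.approx(0.946, abs=1e-3)

    def test_invariant_to_uniform_intensity_scaling(self):
        t = np.arange(0, 120, 0.5)
        y = (8e5 * np.exp(-((t - 55) ** 2) / (2 * 3**2))
             + 1e6 * np.exp(-((t - 70) ** 2) / (2 * 3**2)))
        a = match_peak(make_cluster(EIC(rt=t, intensity=y, target_mz=150.0)),
                       expected_rt=60.0, rt_window=25.0)
        b = match_peak(
            make_cluster(EIC(rt=t, intensity=y * 1e3, target_mz=150.0)),
            expected_rt=60.0, rt_window=25.0)
        assert a == b

    def test_nothing_above_threshold_raises(self):
        eic = gaussian_eic(apex=1.0, noise_sd=0)
        cluster = make_cluster(eic, noise=1e6)  # absurd noise floor
        with pytest.raises(PeakNotFoundError):
            match_peak(cluster, expected_rt=60.0, rt_window=20.0)

    def test_characteristic_sibling_disambiguates(self):
        t = np.arange(0, 120, 0.5)
        y = (1e6 * np.exp(-((t - 50) ** 2) / (2 * 3**2))
             + 1e6 * np.exp(-((t - 70) ** 2) / (2 * 3**2)))
        cluster = make_cluster(EIC(rt=t, intensity=y, target_mz=150.0))
        apex = match_peak(cluster, expected_rt=60.0, rt_window=30.0,
                          characteristic_apex_rts=[70.5])
        assert cluster.composite.rt[apex] == pytest.approx(70.0, abs=0.5)


class TestFindBounds:
    def test_symmetric_gaussian_gives_symmetric_bounds(self):
        cluster = make_cluster(gaussian_eic(), noise=0.001 * 1e6, baseline=0.0)
        apex = match_peak(cluster, 60.0, 20.0)
        bounds = find_bounds(cluster, apex, k=3.0)
        left_w = bounds.apex_index - bounds.left_index
        right_w = bounds.right_index - bounds.apex_index
        assert abs(left_w - right_w) <= 1

    def test_gaussian_threshold_crossing_position(self):
        # sigma=2 s on a 0.5 s grid, noise 1% of apex, k=3: the smoothed
        # curve crosses 3*noise at |t - apex| = sigma * sqrt(2 ln(1/0.03))
        sigma = 2.0
        cluster = make_cluster(gaussian_eic(sigma=sigma), noise=0.01 * 1e6,
                               baseline=0.0)
        apex = match_peak(cluster, 60.0, 20.0)
        bounds = find_bounds(cluster, apex, k=3.0, asymmetry_cap=10.0)
        expected_half_width = sigma * np.sqrt(2 * np.log(1 / 0.03))
        for idx in (bounds.left_index, bounds.right_index):
            assert abs(abs(cluster.composite.rt[idx] - 60.0)
                       - expected_half_width) < 1.0

    def test_asymmetric_tail_clipped_to_cap(self):
        from midquant.synthetic import _peak_shape

        t = np.arange(0, 200, 0.5)
        y = 1e6 * _peak_shape(t, 60.0, 3.0, tau=30.0)  # heavy right tail
        cluster = make_cluster(EIC(rt=t, intensity=y, target_mz=150.0),
                               noise=0.002 * 1e6, baseline=0.0)
        apex = match_peak(cluster, 60.0, 30.0)
        bounds = find_bounds(cluster, apex, k=3.0, asymmetry_cap=2.0)
        left_w = bounds.apex_index - bounds.left_index
        right_w = bounds.right_index - bounds.apex_index
        assert right_w == 2 * left_w

    def test_monotone_in_k(self):
        cluster = make_cluster(gaussian_eic(noise_sd=5e3, seed=3),
                               baseline=0.0)
        apex = match_peak(cluster, 60.0, 20.0)
        widths = []
        for k in (1.0, 2.0, 3.0, 5.0, 8.0):
            b = find_bounds(cluster, apex, k=k, asymmetry_cap=100.0)
            widths.append(b.right_index - b.left_index)
        assert all(b <= a for a, b in zip(widths, widths[1:]))

    def test_shoulder_peak_not_merged(self):
        t = np.arange(0, 120, 0.5)
        # valley between the two peaks dips below 5% of the apex height,
        # so the walk must stop there instead of merging the neighbor
        y = (1e6 * np.exp(-((t - 60) ** 2) / (2 * 3**2))
             + 8e5 * np.exp(-((t - 80) ** 2) / (2 * 3**2)))
        cluster = make_cluster(EIC(rt=t, intensity=y, target_mz=150.0),
                               noise=100.0, baseline=0.0)
        apex = match_peak(cluster, 60.0, 5.0)
        bounds = find_bounds(cluster, apex, k=3.0, asymmetry_cap=100.0)
        assert cluster.composite.rt[bounds.right_index] < 75.0

    def test_noiseless_gaussian_area_capture(self):
        """With k<=3 and a 0.1%-apex noise floor, the bounds capture >= 99%
        of the analytic Gaussian area."""
        from midquant.quantify import integrate_channel

        eic = gaussian_eic(sigma=4.0, dt=0.5)
        cluster = make_cluster(eic, noise=0.001 * 1e6, baseline=0.0)
        apex = match_peak(cluster, 60.0, 20.0)
        bounds = find_bounds(cluster, apex, k=3.0, asymmetry_cap=10.0)
        area = integrate_channel(eic, bounds, baseline=None)
        total = float(eic.intensity.sum())
        assert area >= 0.99 * total


def test_cluster_channels_share_one_grid_structurally(tmp_path, gln_method):
    """Bounds live on the cluster, not the channels, and all channel EICs
    are forced onto one RT grid."""
    from midquant.io_raw import read_run
    from midquant.synthetic import TruthSpec, write_synthetic_run

    truth = TruthSpec("Gln [M+H]+", np.array([0.5, 0, 0, 0, 0, 0.5]),
                      apex_rt=60.0, sigma=4.0, apex_intensity=1e6)
    path = tmp_path / "run.mzML"
    write_synthetic_run([truth], gln_method, path, seed=0)
    cluster = extract_cluster(read_run(path), gln_method.targets[0], gln_method)
    grids = {tuple(e.rt) for e in cluster.channel_eics}
    assert len(grids) == 1
    assert not hasattr(cluster.channel_eics[0], "bounds")
    assert hasattr(cluster, "bounds")
    np.testing.assert_allclose(
        cluster.composite.intensity,
        np.sum([e.intensity for e in cluster.channel_eics], axis=0))
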