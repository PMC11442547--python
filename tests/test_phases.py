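"""Baseline subtraction, sMIP, ROI curves, landmarks and phase maps."""

import numpy as np
import pytest

from collimap.io import BrainMask, PerfusionSeries, PHASE_NAMES
from collimap.phases import (
    PhaseLandmarks,
    SignalTimeCurve,
    compose_phase_maps,
    detect_landmarks,
    extract_roi_curve,
    partition_phases,
    subtract_baseline,
    temporal_mip,
)


class TestSubtractBaseline:
    def test_drop_arithmetic(self):
        data = np.full((6, 1, 2, 2), 100.0)
        data[5, 0, 0, 0] = 60.0
        out = subtract_baseline(PerfusionSeries(data=data), sign="drop")
        assert out.data[5, 0, 0, 0] == 40.0

    def test_first_frame_zero(self, small_series):
        out = subtract_baseline(small_series)
        assert np.all(out.data[0] == 0.0)

    def test_rising_signal_clipped_to_zero_under_drop(self):
        data = np.zeros((4, 1, 2, 2))
        data[0] = 10.0
        data[1:] = 50.0  # signal above baseline everywhere
        out = subtract_baseline(PerfusionSeries(data=data), sign="drop")
        assert np.all(out.data == 0.0)

    def test_rise_mode_mirrors_drop(self):
        data = np.zeros((3, 1, 2, 2))
        data[0] = 10.0
        data[1] = 25.0
        out = subtract_baseline(PerfusionSeries(data=data), sign="rise")
        assert out.data[1, 0, 0, 0] == 15.0


class TestTemporalMip:
    def test_recovers_peak(self, rng):
        data = rng.uniform(0, 5, size=(10, 2, 3, 3))
        data[4, 1, 2, 2] = 8.0
        series = PerfusionSeries(data=data)
        out = temporal_mip(series, (0, 9))
        assert out[1, 2, 2] == 8.0
        np.testing.assert_array_equal(out, data.max(axis=0))

    def test_single_index_window(self, small_series):
        out = temporal_mip(small_series, (3, 3))
        np.testing.assert_array_equal(out, small_series.data[3])

    def test_monotone_under_window_growth(self, small_series):
        small = temporal_mip(small_series, (1, 2))
        large = temporal_mip(small_series, (0, 4))
        assert np.all(large >= small)

    def test_empty_window_rejected(self, small_series):
        with pytest.raises(ValueError, match="empty"):
            temporal_mip(small_series, (3, 2))


class TestExtractRoiCurve:
    def test_single_voxel_roi(self, small_series):
        m = np.zeros(small_series.data.shape[1:], dtype=bool)
        m[1, 2, 3] = True
        curve = extract_roi_curve(small_series, BrainMask(mask=m))
        np.testing.assert_allclose(curve.values, small_series.data[:, 1, 2, 3])
        assert len(curve) == small_series.t_count

    def test_two_voxel_mean(self):
        data = np.zeros((3, 1, 1, 2))
        data[:, 0, 0, 0] = [0, 2, 4]
        data[:, 0, 0, 1] = [0, 4, 8]
        m = np.ones((1, 1, 2), dtype=bool)
        curve = extract_roi_curve(PerfusionSeries(data=data), BrainMask(mask=m))
        np.testing.assert_allclose(curve.values, [0, 3, 6])


class TestDetectLandmarks:
    @staticmethod
    def _curves():
        """Triangular arterial curve peaking at 5; venous peak 12, flat 15-18."""
        T = 40
        mca = np.zeros(T)
        mca[:11] = [0, 0, 1, 2, 6, 10, 8, 6, 4, 2, 1]
        sss = np.zeros(T)
        sss[6:13] = [1, 2, 4, 6, 8, 9, 10]
        sss[13] = 8.0
        sss[14] = 6.0
        sss[15:19] = 5.0  # plateau 15..18
        sss[19:] = np.linspace(4.0, 0.5, 21)
        return SignalTimeCurve(values=mca), SignalTimeCurve(values=sss)

    def test_brute_force_expected_landmarks(self):
        mca, sss = self._curves()
        lm = detect_landmarks(mca, sss, arrival_frac=0.1, plateau_tol=0.05)
        # brute-force oracle on the constructed curves:
        # argmax(mca)=5, argmax(sss)=12, arrival: first mca >= 1.0 -> idx 2,
        # plateau steps |diff|<=0.5 start at 15 and run through 17 -> end 18
        assert lm == PhaseLandmarks(2, 5, 12, 15, 18)

    def test_all_zero_curves_rejected(self):
        flat = SignalTimeCurve(values=np.zeros(20))
        with pytest.raises(ValueError, match="no bolus"):
            detect_landmarks(flat, flat)

    def test_venous_before_arterial_rejected(self):
        mca, sss = self._curves()
        with pytest.raises(ValueError, match="venous peak"):
            detect_landmarks(sss, mca)

    def test_manual_override(self):
        mca, sss = self._curves()
        lm = detect_landmarks(mca, sss, overrides={"t_plateau_start": 16})
        assert lm.t_plateau_start == 16

    def test_phantom_gamma_peak_matches_discrete_argmax(self):
        from collimap.phantom import GammaVariate, gamma_variate_curve
        gv = GammaVariate(t0=6.4, alpha=2.0, beta=1.6)
        times = np.arange(40) * 1.6
        curve = gamma_variate_curve(gv, times)
        assert gv.t_peak == pytest.approx(9.6)
        assert np.argmax(curve) == np.argmin(np.abs(times - gv.t_peak))


class TestPartitionPhases:
    def test_stated_convention(self):
        lm = PhaseLandmarks(3, 5, 12, 15, 18)
        w = partition_phases(lm, 40)
        assert w["Art"] == (3, 5)
        assert w["Cap"] == (6, 12)
        assert w["EVen"] == (13, 15)
        assert w["LVen"] == (16, 18)
        assert w["Del"] == (19, 39)

    def test_windows_partition_the_tail(self):
        lm = PhaseLandmarks(3, 5, 12, 15, 18)
        w = partition_phases(lm, 40)
        covered = []
        for _, (lo, hi) in w.items():
            covered.extend(range(lo, hi + 1))
        assert covered == list(range(3, 40))  # disjoint and contiguous

    def test_empty_late_venous_rejected(self):
        with pytest.raises(ValueError, match="ordering|LVen"):
            partition_phases(PhaseLandmarks(3, 5, 12, 15, 15), 40)


class TestComposePhaseMaps:
    def test_peak_lands_in_its_window(self):
        T = 40
        data = np.full((T, 1, 2, 2), 100.0)
        data[4, 0, 0, 0] = 92.0   # drop of 8 inside Art window
        data[20, 0, 0, 0] = 98.5  # small drop elsewhere
        series = PerfusionSeries(data=data)
        sub = subtract_baseline(series)
        w = partition_phases(PhaseLandmarks(3, 5, 12, 15, 18), T)
        maps = compose_phase_maps(sub, w)
        art = maps.phase("Art")
        assert art[0, 0, 0] == 8.0
        for name in PHASE_NAMES[1:]:
            assert maps.phase(name)[0, 0, 0] <= 2.0

    def test_all_zero_series_gives_zero_maps(self):
        data = np.full((40, 1, 2, 2), 50.0)
        sub = subtract_baseline(PerfusionSeries(data=data))
        w = partition_phases(PhaseLandmarks(3, 5, 12, 15, 18), 40)
        maps = compose_phase_maps(sub, w)
        assert np.all(maps.maps == 0.0)

    def test_phase_maxima_cover_global_max(self, noiseless_phantom):
        sub = subtract_baseline(noiseless_phantom.series)
        maps = compose_phase_maps(sub, noiseless_phantom.windows)
        global_max = sub.data[noiseless_phantom.windows["Art"][0]:].max(axis=0)
        assert np.all(maps.maps.max(axis=0) >= global_max - 1e-12)

    def test_commutes_with_voxel_permutation(self, rng):
        data = rng.uniform(0, 10, size=(40, 2, 3, 3))
        data[0] = 20.0  # baseline above everything: subtraction stays positive
        series = PerfusionSeries(data=data)
        sub = subtract_baseline(series)
        w = partition_phases(PhaseLandmarks(3, 5, 12, 15, 18), 40)
        maps = compose_phase_maps(sub, w)
        perm = rng.permutation(2 * 3 * 3)
        data_p = data.reshape(40, -1)[:, perm].reshape(40, 2, 3, 3)
        maps_p = compose_phase_maps(
            subtract_baseline(PerfusionSeries(data=data_p)), w)
        np.testing.assert_array_equal(
            maps.maps.reshape(5, -1)[:, perm], maps_p.maps.reshape(5, -1))

    def test_mean_statistic_alternative(self, small_series):
        sub = subtract_baseline(small_series)
        w = partition_phases(PhaseLandmarks(0, 1, 2, 3, 4), small_series.t_count)
        maps = compose_phase_maps(sub, w, statistic="mean")
        lo, hi = w["Del"]
        np.testing.assert_allclose(maps.phase("Del"),
                                   sub.data[lo:hi + 1].mean(axis=0))


class TestPhantomClosure:
    """End-to-end self-consistency of the generator and the procedure."""

    def test_noiseless_landmarks_detected_exactly(self, noiseless_phantom):
        ph = noiseless_phantom
        sub = subtract_baseline(ph.series)
        lm = detect_landmarks(extract_roi_curve(sub, ph.mca_roi),
                              extract_roi_curve(sub, ph.sss_roi))
        assert lm == ph.landmarks

    def test_noiseless_maps_equal_analytic_maps(self, noiseless_phantom):
        ph = noiseless_phantom
        sub = subtract_baseline(ph.series)
        maps = compose_phase_maps(sub, ph.windows)
        np.testing.assert_array_equal(maps.maps, ph.maps.maps)

    def test_windows_partition_from_arrival(self, noiseless_phantom):
        ph = noiseless_phantom
        T = ph.series.t_count
        covered = []
        for _, (lo, hi) in ph.windows.items():
            covered.extend(range(lo, hi + 1))
        assert covered == list(range(ph.landmarks.t_arrival, T))

    def test_noisy_peak_landmarks_within_one_index(self):
        """Peak recovery within +/-1 index for sigma = 2% of peak drop."""
        from collimap.phantom import PhantomSpec, make_phantom

        base = PhantomSpec(grid=(40, 8, 32, 32))
        sigma = 0.02 * base.peak_signal_drop
        hits = 0
        n_trials = 100
        for s in range(n_trials):
            ph = make_phantom(PhantomSpec(grid=(40, 8, 32, 32),
                                          noise_sigma=sigma, seed=s))
            sub = subtract_baseline(ph.series)
            lm = detect_landmarks(extract_roi_curve(sub, ph.mca_roi),
                                  extract_roi_curve(sub, ph.sss_roi))
            if (abs(lm.t_arterial_peak - ph.landmarks.t_arterial_peak) <= 1
                    and abs(lm.t_venous_peak - ph.landmarks.t_venous_peak) <= 1):
                hits += 1
        assert hits >= 95
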