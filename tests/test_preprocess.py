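"""Optical density, trimming, motion handling, filtering and the
modified Beer-Lambert inversion."""

import numpy as np
import pytest

import fnirsnet as fn
from fnirsnet.preprocess import (ArtifactMask, OpticalDensitySeries,
                                 hemoglobin_to_od)

FS = 20.0


def od_series(x, n_ch=1):
    """Wrap a 1-D trace as a (n_ch, 2, T) OD series."""
    data = np.broadcast_to(x, (n_ch, 2, len(x))).copy()
    return OpticalDensitySeries("t", data, FS)


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        raw = fn.RawIntensitySeries("s", np.full((2, 2, 100), 5.0), FS)
        od = fn.intensity_to_od(raw)
        np.testing.assert_allclose(od.data, 0.0, atol=1e-15)

    def test_doubled_sample_gives_minus_log_two(self):
        data = np.ones((1, 2, 1000))
        data[0, :, 500] = 2.0
        raw = fn.RawIntensitySeries("s", data, FS)
        od = fn.intensity_to_od(raw)
        base = np.mean(data[0, 0])
        assert od.data[0, 0, 500] == pytest.approx(-np.log(2.0 / base))
        assert od.data[0, 0, 500] == pytest.approx(-0.6931, abs=1e-3)

    def test_mean_od_is_small_but_nonzero_for_fluctuating_traces(self):
        # OD(t) = -ln(I/mean I); by Jensen's inequality the temporal mean of
        # OD is >= 0 and small for small fluctuations
        rng = np.random.default_rng(0)
        data = np.exp(0.02 * rng.standard_normal((5, 2, 4000)))
        od = fn.intensity_to_od(fn.RawIntensitySeries("s", data, FS))
        means = od.data.mean(axis=2)
        assert np.all(means >= 0)
        assert np.all(means < 1e-3)


class TestTrim:
    def test_five_minutes_trims_to_3600_samples(self):
        od = od_series(np.zeros(6000))
        out = fn.trim_edges(od, 60.0)
        assert out.n_samples == 3600

    def test_short_record_rejected(self):
        od = od_series(np.zeros(int(100 * FS)))
        with pytest.raises(fn.ValidationError, match="too short"):
            fn.trim_edges(od, 60.0)

    def test_zero_trim_is_identity(self):
        x = np.sin(np.arange(500) / 50.0)
        od = od_series(x)
        out = fn.trim_edges(od, 0.0)
        np.testing.assert_array_equal(out.data, od.data)


class TestMotionDetection:
    def test_clean_sinusoid_yields_empty_mask(self):
        t = np.arange(4000) / FS
        od = od_series(0.01 * np.sin(2 * np.pi * 0.05 * t))
        mask = fn.detect_motion(od)
        assert mask.is_empty

    def test_injected_step_flagged_once(self):
        rng = np.random.default_rng(3)
        t = np.arange(4000) / FS
        x = 0.005 * np.sin(2 * np.pi * 0.05 * t) \
            + 0.0005 * rng.standard_normal(4000)
        x[2500:] += 10 * x.std()
        od = od_series(x)
        mask = fn.detect_motion(od)
        ivs = mask.intervals[0]
        assert len(ivs) == 1
        a, b = ivs[0]
        assert a <= 2500 <= b

    def test_infinite_thresholds_disable_detection(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(2000)
        od = od_series(x)
        mask = fn.detect_motion(od, sd_thresh=np.inf, amp_thresh=np.inf)
        assert mask.is_empty

    def test_window_longer_than_record_rejected(self):
        od = od_series(np.zeros(10))
        with pytest.raises(fn.ValidationError, match="window"):
            fn.detect_motion(od, window_s=10.0)

    def test_mask_intervals_validated(self):
        with pytest.raises(fn.ValidationError, match="out of bounds"):
            ArtifactMask({0: [(5, 20)]}, n_samples=10)
        with pytest.raises(fn.ValidationError, match="overlap"):
            ArtifactMask({0: [(0, 5), (3, 8)]}, n_samples=10)


class TestSplineCorrection:
    def test_empty_mask_is_identity(self):
        rng = np.random.default_rng(1)
        od = od_series(rng.standard_normal(1000))
        out = fn.spline_correct(od, ArtifactMask({0: []}, 1000))
        np.testing.assert_array_equal(out.data, od.data)

    def test_step_artifact_peak_to_peak_reduced(self):
        rng = np.random.default_rng(0)
        t = np.arange(4000) / FS
        x = 0.005 * np.sin(2 * np.pi * 0.05 * t) \
            + 0.0005 * rng.standard_normal(4000)
        x[2000:] += 0.6
        od = od_series(x)
        mask = fn.detect_motion(od)
        out = fn.spline_correct(od, mask)
        a, b = mask.intervals[0][0]
        before = np.ptp(od.data[0, 0, a:b])
        after = np.ptp(out.data[0, 0, a:b])
        assert after <= 0.2 * before

    def test_unflagged_samples_untouched(self):
        rng = np.random.default_rng(2)
        od = od_series(rng.standard_normal(1000))
        out = fn.spline_correct(od, ArtifactMask({0: [(400, 500)]}, 1000))
        np.testing.assert_array_equal(out.data[0, 0, :400], od.data[0, 0, :400])
        np.testing.assert_array_equal(out.data[0, 0, 500:], od.data[0, 0, 500:])

    def test_whole_record_mask_stays_level_continuous(self):
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.standard_normal(2000)) * 0.05
        od = od_series(x)
        intervals = [(i, i + 200) for i in range(0, 2000, 200)]
        out = fn.spline_correct(od, ArtifactMask({0: intervals}, 2000))
        jumps = np.abs(np.diff(out.data[0, 0]))
        assert jumps.max() < 0.4  # no step larger than the amplitude threshold


class TestBandpass:
    @staticmethod
    def attenuation_db(freq):
        t = np.arange(int(600 * FS)) / FS
        od = od_series(np.sin(2 * np.pi * freq * t))
        out = fn.bandpass(od)
        core = slice(2000, -2000)
        ratio = out.data[0, 0, core].std() / od.data[0, 0, core].std()
        return -20 * np.log10(ratio)

    def test_passband_tone_preserved(self):
        assert self.attenuation_db(0.05) < 3.0

    def test_respiration_band_suppressed(self):
        assert self.attenuation_db(0.4) > 20.0

    def test_cardiac_band_suppressed(self):
        assert self.attenuation_db(1.2) > 20.0

    def test_zero_phase_time_reversal_symmetry(self):
        rng = np.random.default_rng(5)
        od = od_series(rng.standard_normal(4000))
        fwd = fn.bandpass(od).data
        rev = fn.bandpass(od_series(od.data[0, 0, ::-1])).data[:, :, ::-1]
        np.testing.assert_allclose(fwd, rev, atol=1e-9)

    def test_invalid_band_rejected(self):
        od = od_series(np.zeros(100))
        with pytest.raises(fn.ValidationError, match="band"):
            fn.bandpass(od, 0.1, 0.01)


class TestBeerLambert:
    def test_zero_od_gives_zero_concentration(self):
        od = OpticalDensitySeries("s", np.zeros((3, 2, 50)), FS)
        hemo = fn.od_to_hemoglobin(od)
        np.testing.assert_array_equal(hemo.data, 0.0)

    def test_forward_inverse_round_trip(self):
        rng = np.random.default_rng(6)
        conc = rng.standard_normal((5, 2, 300))
        hemo = fn.HemoSeries("s", conc, FS)
        od = hemoglobin_to_od(hemo)
        back = fn.od_to_hemoglobin(od)
        np.testing.assert_allclose(back.data, conc, atol=1e-9)

    def test_singular_extinction_rejected(self):
        with pytest.raises(fn.ValidationError, match="singular"):
            fn.MbllCoefficients(extinction=np.array([[1.0, 2.0], [2.0, 4.0]]))


class TestFullChain:
    def test_clean_subject_output_shape(self, small_cohort):
        res = fn.run_preprocess(small_cohort.raws[0])
        assert not res.excluded
        assert res.hemo.data.shape == (53, 2, 3600)
        assert res.hemo.hbo.shape == (53, 3600)

    def test_determinism(self, small_cohort):
        a = fn.run_preprocess(small_cohort.raws[0])
        b = fn.run_preprocess(small_cohort.raws[0])
        np.testing.assert_array_equal(a.hemo.data, b.hemo.data)

    def test_high_motion_subject_excluded(self, atlas):
        cfg = fn.SynthConfig(spike_rate_per_min=40.0, seed=3)
        from fnirsnet.simulate import _truth_full, simulate_subject

        truth = _truth_full(cfg, atlas, "HC")
        raw = simulate_subject(truth, cfg, seed=11, subject_id="shaky")
        res = fn.run_preprocess(raw)
        assert res.excluded
        assert res.exclusion_reason == "head movement"

    def test_recovers_band_limited_truth_on_clean_channels(self, atlas):
        # forward-simulate then invert: trace-level correlation with the
        # noiseless band-limited HbO should be high on artifact-free channels
        from fnirsnet.simulate import _truth_full, simulate_subject
        from fnirsnet.preprocess import bandpass, intensity_to_od, \
            od_to_hemoglobin, trim_edges

        cfg = fn.SynthConfig(spike_rate_per_min=0.0, seed=5)
        truth = _truth_full(cfg, atlas, "HC")
        raw = simulate_subject(truth, cfg, seed=5, subject_id="clean")
        res = fn.run_preprocess(raw)
        # reference: drift/physio-free inversion band-passed the same way
        cfg0 = fn.SynthConfig(spike_rate_per_min=0.0, mayer_amp_um=0.0,
                              resp_amp_um=0.0, cardiac_amp_um=0.0,
                              drift_amp_od=0.0, seed=5)
        raw0 = simulate_subject(truth, cfg0, seed=5, subject_id="ref")
        ref = od_to_hemoglobin(bandpass(trim_edges(intensity_to_od(raw0)))).hbo
        got = res.hemo.hbo
        cors = [np.corrcoef(got[c], ref[c])[0, 1] for c in range(53)]
        assert np.mean(cors) >= 0.95
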