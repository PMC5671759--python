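"""HRV metric unit, identity and oracle tests."""

import numpy as np
import pytest

from adneuro.errors import (
    DegenerateInputError,
    DetectionError,
    InsufficientDataError,
    QualityError,
)
from adneuro.hrv import (
    HRV_METRIC_NAMES,
    FrequencyBands,
    RRSeries,
    detect_rpeaks,
    hrv_all,
    lomb_grid,
    lomb_spectrum,
    poincare,
    sample_entropy,
    screen_ectopics,
    time_domain,
)
from adneuro.synthetic import SyntheticCohortSpec, HRVParams, gen_rr
from oracles import sampen_bruteforce


def _ecg_pulse_train(rate=500.0, dur=30.0, hr_hz=1.0):
    """Spiky synthetic ECG: narrow triangular R waves on a flat line."""
    n = int(rate * dur)
    x = np.zeros(n)
    width = int(0.02 * rate)
    for beat in np.arange(0.5, dur, 1.0 / hr_hz):
        c = int(beat * rate)
        if c + width >= n:
            break
        tri = 1.0 - np.abs(np.arange(-width, width + 1)) / width
        x[c - width:c + width + 1] += tri
    return x


class TestRRSeries:
    def test_interval_beat_time_consistency(self):
        rr = RRSeries.from_intervals([800.0, 900.0, 850.0])
        assert rr.beat_times[-1] == pytest.approx(2.55)
        assert np.allclose(np.diff(rr.beat_times) * 1000, rr.intervals)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(DegenerateInputError):
            RRSeries.from_intervals([800.0, -10.0])


class TestDetectRpeaks:
    def test_one_hz_pulse_train_recovers_1000ms(self):
        rr = detect_rpeaks(_ecg_pulse_train(), 500.0)
        assert np.all(np.abs(rr.intervals - 1000.0) <= 2.0)

    def test_clean_sinusoid_yields_detection_error(self):
        t = np.arange(0, 30, 1 / 500)
        with pytest.raises(DetectionError):
            detect_rpeaks(np.sin(2 * np.pi * 1.0 * t), 500.0)

    def test_amplitude_invariance(self):
        x = _ecg_pulse_train()
        rr1 = detect_rpeaks(x, 500.0)
        rr2 = detect_rpeaks(2.0 * x, 500.0)
        assert np.allclose(rr1.intervals, rr2.intervals)


class TestScreenEctopics:
    def test_clean_series_untouched(self, rng):
        rr = RRSeries.from_intervals(850 + 5 * rng.standard_normal(100))
        out, flags = screen_ectopics(rr)
        assert flags.sum() == 0
        assert out is rr

    def test_single_halved_interval_flagged(self, rng):
        iv = 850 + 5 * rng.standard_normal(100)
        iv[40] /= 2.0
        _, flags = screen_ectopics(RRSeries.from_intervals(iv))
        assert flags[40] and flags.sum() == 1

    def test_infinite_tolerance_flags_nothing(self, rng):
        iv = 850 * np.abs(1 + rng.standard_normal(50))
        _, flags = screen_ectopics(RRSeries.from_intervals(iv + 100),
                                   tol=np.inf)
        assert flags.sum() == 0

    def test_too_many_ectopics_rejects_series(self, rng):
        iv = np.where(np.arange(100) % 3 == 0, 400.0, 850.0)
        with pytest.raises(QualityError):
            screen_ectopics(RRSeries.from_intervals(iv))


class TestTimeDomain:
    def test_constant_1000ms(self):
        td = time_domain(RRSeries.from_intervals([1000.0] * 60))
        assert td["t_meanHR"] == pytest.approx(60.0)
        assert td["t_sdHR"] == 0.0
        assert td["t_RMSSD"] == 0.0
        assert td["t_NN50"] == 0

    def test_alternating_800_860(self):
        td = time_domain(RRSeries.from_intervals([800.0, 860, 800, 860]))
        assert td["t_RMSSD"] == pytest.approx(60.0)
        assert td["t_NN50"] == 3

    def test_unit_conversion_750ms(self):
        td = time_domain(RRSeries.from_intervals([750.0] * 10))
        assert td["t_meanHR"] == pytest.approx(80.0)

    def test_single_interval_insufficient(self):
        with pytest.raises(InsufficientDataError):
            time_domain(RRSeries.from_intervals([800.0]))


class TestLombSpectrum:
    def _modulated(self, freq, amp=40.0, dur=120.0, seed=0):
        spec = SyntheticCohortSpec(
            hrv=HRVParams(lf_amp_ms=amp if freq < 0.15 else 0.0,
                          lf_freq_hz=freq if freq < 0.15 else 0.10,
                          hf_amp_ms=amp if freq >= 0.15 else 0.0,
                          hf_freq_hz=freq if freq >= 0.15 else 0.25,
                          jitter_sd_ms=2.0),
            seed=seed)
        rr, _ = gen_rr(spec, rng=np.random.default_rng(seed), duration_s=dur)
        return rr

    def test_normalized_powers_sum_to_one(self, rng):
        rr = RRSeries.from_intervals(850 + 30 * rng.standard_normal(200))
        f = lomb_spectrum(rr)
        assert f["f_nLF_lomb"] + f["f_nHF_lomb"] == pytest.approx(1.0)
        assert f["f_pLF"] + f["f_pHF"] == pytest.approx(100.0)
        assert f["f_LFHF_lomb"] == pytest.approx(
            f["f_aLF_lomb"] / f["f_aHF_lomb"])

    def test_lf_modulation_recovered(self):
        rr = self._modulated(0.10)
        f = lomb_spectrum(rr)
        df = 1.0 / (4.0 * rr.span_s)
        assert abs(f["f_peakLF_lomb"] - 0.10) <= df
        assert f["f_nLF_lomb"] >= 0.9

    def test_hf_modulation_recovered(self):
        rr = self._modulated(0.25)
        f = lomb_spectrum(rr)
        df = 1.0 / (4.0 * rr.span_s)
        assert abs(f["f_peakHF_lomb"] - 0.25) <= df
        assert f["f_LFHF_lomb"] < 1.0

    def test_time_offset_invariance(self, rng):
        iv = 850 + 30 * rng.standard_normal(150)
        rr0 = RRSeries.from_intervals(iv)
        rr1 = RRSeries.from_intervals(iv, t0=9876.0)
        f0, f1 = lomb_spectrum(rr0), lomb_spectrum(rr1)
        for k in f0:
            assert f0[k] == pytest.approx(f1[k], rel=1e-9), k

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateInputError):
            lomb_spectrum(RRSeries.from_intervals([800.0] * 100))


class TestPoincare:
    def test_constant_series_zero(self):
        p = poincare(RRSeries.from_intervals([900.0] * 50))
        assert p["p_SD1"] == 0.0 and p["p_SD2"] == 0.0
        assert np.isnan(p["p_SD1vsSD2"])

    def test_sd1_rmssd_identity(self, rng):
        iv = 800 + 50 * rng.standard_normal(300)
        rr = RRSeries.from_intervals(np.abs(iv) + 100)
        p = poincare(rr)
        td = time_domain(rr)
        assert p["p_SD1"] == pytest.approx(td["t_RMSSD"] / np.sqrt(2),
                                           rel=1e-9)

    def test_alternating_series_short_term_dominates(self):
        iv = 850 + 40 * np.tile([1.0, -1.0], 50)
        p = poincare(RRSeries.from_intervals(iv))
        assert p["p_SD1"] > p["p_SD2"]


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy(np.full(50, 800.0), m=2) == 0.0

    @pytest.mark.parametrize("m", [1, 2])
    def test_periodic_series_zero(self, m):
        x = np.tile([700.0, 900.0], 100)
        assert sample_entropy(x, m=m) == 0.0

    @pytest.mark.parametrize("n", [50, 200, 500])
    def test_matches_bruteforce_oracle_on_noise(self, rng, n):
        x = rng.standard_normal(n)
        for m in (1, 2):
            r = 0.2 * x.std(ddof=1)
            expected = sampen_bruteforce(x, m, r)
            got = sample_entropy(x, m=m)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_short_series_insufficient(self):
        with pytest.raises(InsufficientDataError):
            sample_entropy(np.array([1.0, 2.0]), m=2)


class TestHrvAll:
    def test_all_seventeen_finite_on_generator_defaults(self):
        spec = SyntheticCohortSpec(seed=11)
        rr, _ = gen_rr(spec, rng=np.random.default_rng(11), duration_s=120)
        out = hrv_all(rr)
        assert set(out) == set(HRV_METRIC_NAMES)
        assert all(np.isfinite(v) for v in out.values())

    def test_leave_one_out_stability(self):
        spec = SyntheticCohortSpec(seed=4)
        rr, _ = gen_rr(spec, rng=np.random.default_rng(4), duration_s=120)
        full = hrv_all(rr)
        loo = hrv_all(RRSeries(rr.beat_times[:-1], rr.intervals[:-1]))
        for k in ("t_meanHR", "p_SD1", "f_peakLF_lomb", "f_peakHF_lomb"):
            assert abs(full[k] - loo[k]) < 0.05 * max(abs(full[k]), 1.0), k
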