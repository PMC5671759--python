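"""EEG metric unit and property tests."""

import numpy as np
import pytest
from scipy import stats as sst

from adneuro import eeg
from adneuro.eeg import (
    DEFAULT_BANDS,
    EEGRecording,
    band_filter,
    band_zscore,
    extract_eeg_metrics,
    gfp,
    interest_index,
    interpolate_bad_channels,
    kurtosis,
    pleasantness_index,
    reject_epochs,
)
from adneuro.errors import (
    ConfigurationError,
    DegenerateInputError,
    InsufficientDataError,
)
from adneuro.synthetic import gen_eeg


def _recording(data, rate=128.0, channels=None, ad=(0.0, None)):
    channels = channels or [f"ch{i}" for i in range(data.shape[0])]
    return EEGRecording(np.asarray(data, float), rate, channels)


class TestKurtosis:
    def test_two_point_symmetric_is_one(self):
        assert kurtosis(np.tile([1.0, -1.0], 50)) == pytest.approx(1.0)

    def test_matches_population_moment_oracle_on_normal_sample(self, rng):
        x = rng.standard_normal(20000)
        # independent oracle: scipy's population kurtosis (fisher=False)
        assert kurtosis(x) == pytest.approx(
            sst.kurtosis(x, fisher=False, bias=True), rel=1e-12)
        se = np.sqrt(24.0 / x.size)
        assert abs(kurtosis(x) - 3.0) < 3 * se

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            kurtosis(np.ones(100))
        with pytest.raises(InsufficientDataError):
            kurtosis(np.array([1.0, 2.0]))


class TestRejectEpochs:
    def test_homogeneous_noise_rejects_almost_nothing(self, rng):
        rec = _recording(rng.standard_normal((4, 128 * 60)))
        es = reject_epochs(rec, z_thresh=5.0)
        assert es.rejected.sum() <= 2  # near-zero false-positive rate

    def test_spike_train_epoch_is_rejected(self, rng):
        data = rng.standard_normal((3, 128 * 20))
        # plant a sparse high-amplitude spike train in epoch 7, channel 1
        sl = slice(7 * 128, 8 * 128)
        data[1, sl][::16] += 40.0
        es = reject_epochs(_recording(data), z_thresh=5.0)
        assert es.rejected[7]
        assert es.rejected.sum() == 1

    def test_infinite_threshold_keeps_all(self, rng):
        rec = _recording(rng.standard_normal((2, 128 * 5)))
        assert reject_epochs(rec, z_thresh=np.inf).rejected.sum() == 0


class TestInterpolation:
    def test_channel_equal_to_neighbour_mean_is_reconstructed(self, rng):
        labels = ["Fp1", "Fp2", "F3", "F4", "Fz"]
        data = rng.standard_normal((5, 256))
        rec = EEGRecording(data, 128.0, labels)
        # overwrite Fz with the mean of its 4 nearest (all others)
        target = interpolate_bad_channels(rec, {"Fz"}, k=4)
        good = [l for l in labels if l != "Fz"]
        # reconstruction is a convex combination of the neighbours
        recon = target.pick(["Fz"])[0]
        lo = rec.pick(good).min(axis=0) - 1e-12
        hi = rec.pick(good).max(axis=0) + 1e-12
        assert np.all(recon >= lo) and np.all(recon <= hi)
        assert recon.var() <= max(rec.pick([g])[0].var() for g in good) + 1e-12

    def test_empty_bad_set_is_identity(self, rng):
        rec = EEGRecording(rng.standard_normal((2, 64)), 64.0, ["C3", "C4"])
        out = interpolate_bad_channels(rec, set())
        assert out is rec

    def test_all_bad_raises(self, rng):
        rec = EEGRecording(rng.standard_normal((2, 64)), 64.0, ["C3", "C4"])
        with pytest.raises(DegenerateInputError):
            interpolate_bad_channels(rec, {"C3", "C4"})


class TestBandFilter:
    @pytest.mark.parametrize("freq,min_gain,max_gain", [
        (5.0, 0.95, 1.05),    # theta centre passes
        (30.0, 0.0, 0.01),    # far out-of-band is crushed
    ])
    def test_sinusoid_response(self, freq, min_gain, max_gain):
        rate, dur = 256.0, 20.0
        t = np.arange(int(rate * dur)) / rate
        x = np.sin(2 * np.pi * freq * t)[None, :]
        rec = _recording(x, rate=rate)
        out = band_filter(rec, DEFAULT_BANDS["theta"]).data[0]
        mid = slice(int(2 * rate), int(18 * rate))  # skip filter edges
        gain = out[mid].std() / x[0, mid].std()
        assert min_gain <= gain <= max_gain

    def test_zero_in_zero_out(self):
        rec = _recording(np.zeros((2, 512)), rate=256.0)
        assert np.allclose(band_filter(rec, DEFAULT_BANDS["alpha"]).data, 0)

    def test_band_above_nyquist_rejected(self):
        rec = _recording(np.zeros((2, 512)), rate=64.0)
        with pytest.raises(ConfigurationError):
            band_filter(rec, DEFAULT_BANDS["gamma"])


class TestGFP:
    def test_identical_channels_zero(self):
        assert np.allclose(gfp(np.ones((3, 50)) * 7.0), 0.0)

    def test_two_antisymmetric_channels(self, rng):
        a = rng.standard_normal(100)
        assert np.allclose(gfp(np.vstack([a, -a])), np.abs(a))

    def test_homogeneity_and_offset_invariance(self, rng):
        x = rng.standard_normal((4, 80))
        assert np.allclose(gfp(3.5 * x), 3.5 * gfp(x))
        assert np.allclose(gfp(x + 100.0), gfp(x))

    def test_single_electrode_rejected(self):
        with pytest.raises(ConfigurationError):
            gfp(np.zeros((1, 10)))


class TestBandZscore:
    def test_self_comparison_is_zero(self, rng):
        x = rng.standard_normal(500)
        assert band_zscore(x, x) == pytest.approx(0.0)

    def test_two_sigma_shift_gives_two(self, rng):
        base = rng.standard_normal(1000)
        ad = base + 2.0 * base.std(ddof=1)
        assert band_zscore(ad, base) == pytest.approx(2.0)

    def test_flat_baseline_raises(self):
        with pytest.raises(DegenerateInputError):
            band_zscore(np.ones(10), np.ones(10))


class TestPleasantnessIndex:
    def _sym_recording(self, rng, asym_swap=False):
        from adneuro.synthetic import SyntheticCohortSpec, EEGParams
        spec = SyntheticCohortSpec(
            ad_duration_s=8.0, baseline_duration_s=12.0,
            eeg=EEGParams(channels=["Fp1", "Fp2", "F3", "F4", "F7", "F8"]),
            seed=5)
        rec, _ = gen_eeg(spec, rng=rng, asymmetry=0.5)
        return rec

    def test_mirror_symmetric_recording_gives_zero(self):
        rate, n = 128.0, 128 * 30
        t = np.arange(n)
        rng = np.random.default_rng(0)
        shared = rng.standard_normal(n)
        data = np.vstack([shared, shared, shared * 0.5, shared * 0.5])
        rec = EEGRecording(data, rate, ["F3", "F4", "F7", "F8"],
                           events=[(0.0, "baseline_start"), (10.0, "baseline_end"),
                                   (10.0, "ad_start"), (30.0, "ad_end")])
        pi = pleasantness_index(rec, DEFAULT_BANDS["theta"],
                                pairs=[("F3", "F4"), ("F7", "F8")])
        assert pi == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetric_under_left_right_swap(self, rng):
        rec = self._sym_recording(rng)
        band = DEFAULT_BANDS["theta"]
        pairs = [("Fp1", "Fp2"), ("F3", "F4"), ("F7", "F8")]
        swapped = [(r, l) for l, r in pairs]
        pi = pleasantness_index(rec, band, pairs)
        pi_sw = pleasantness_index(rec, band, swapped)
        assert pi_sw == pytest.approx(-pi, rel=1e-9)

    def test_missing_pair_electrode_raises(self, rng):
        rec = self._sym_recording(rng)
        with pytest.raises(ConfigurationError):
            pleasantness_index(rec, DEFAULT_BANDS["theta"],
                               pairs=[("F3", "T8")])


class TestInterestIndex:
    def test_no_suprathreshold_peak(self):
        x = np.zeros(1000)
        pn_t, pn_b, ii = interest_index(x, 100.0, [(0.0, 5.0)])
        assert (pn_t, pn_b, ii) == (0, 0, 0.0)

    def _bumpy_series(self, peak_times, rate=100.0, dur=20.0):
        t = np.arange(int(rate * dur)) / rate
        x = np.zeros_like(t)
        for pt in peak_times:
            x += 10.0 * np.exp(-0.5 * ((t - pt) / 0.05) ** 2)
        return x + 0.01 * np.sin(2 * np.pi * 7 * t)

    def test_half_of_planted_peaks_inside_brand_windows(self):
        inside = [2.0, 4.0, 6.0, 8.0]
        outside = [11.0, 13.0, 15.0, 17.0]
        x = self._bumpy_series(inside + outside)
        pn_t, pn_b, ii = interest_index(x, 100.0, [(1.0, 9.0)])
        assert pn_t == 8 and pn_b == 4
        assert ii == pytest.approx(0.5)

    def test_all_peaks_inside_gives_one(self):
        x = self._bumpy_series([2.0, 5.0, 8.0])
        _, _, ii = interest_index(x, 100.0, [(0.0, 10.0)])
        assert ii == pytest.approx(1.0)

    def test_matches_brute_force_peak_scan(self, rng):
        x = rng.standard_normal(3000)
        rate = 100.0
        pn_t, pn_b, _ = interest_index(x, rate, [(5.0, 12.0)], c=2.0,
                                       min_distance_s=0.25)
        # brute force: local maxima above mean + 2 SD, greedy 0.25 s spacing
        thr = x.mean() + 2.0 * x.std(ddof=1)
        cand = [i for i in range(1, x.size - 1)
                if x[i] > thr and x[i] >= x[i - 1] and x[i] > x[i + 1]]
        cand.sort(key=lambda i: -x[i])
        chosen: list[int] = []
        for i in cand:
            if all(abs(i - j) >= 25 for j in chosen):
                chosen.append(i)
        assert pn_t == len(chosen)


class TestFullExtraction:
    def test_rejection_stage_transparent_when_nothing_rejected(self, small_spec, rng):
        rec, _ = gen_eeg(small_spec, rng=rng, brand_windows=[(2.0, 4.0)])
        with_stage = extract_eeg_metrics(rec, z_thresh=50.0)
        without = extract_eeg_metrics(rec, z_thresh=np.inf)
        for k in with_stage:
            assert with_stage[k] == without[k], k

    def test_metric_row_complete(self, small_spec, rng):
        rec, _ = gen_eeg(small_spec, rng=rng, brand_windows=[(2.0, 4.0)])
        row = extract_eeg_metrics(rec)
        expected = {"z_delta", "z_theta", "z_alpha", "z_beta", "z_beta_ext",
                    "z_gamma", "PI_theta", "PI_alpha", "II_theta", "II_beta"}
        assert set(row) == expected
        assert all(np.isfinite(v) for v in row.values())
        assert 0.0 <= row["II_theta"] <= 1.0
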