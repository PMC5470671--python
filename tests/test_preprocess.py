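import numpy as np
import pytest

from motornet import (
    SimulationConfig,
    TrialEpochs,
    average_and_baseline,
    bandpass_epochs,
    flip_hemispheres,
    generate_cohort,
    morlet_power,
    project_to_sources,
    reject_artifacts,
    simulate_eeg_trials,
)
from motornet.preprocess import EmptyDataError, morlet_kernel
from motornet.sources import MONTAGE_32
from motornet.synthdata import make_lead_field

from conftest import FREQS4

FS = 500.0


def make_epochs(data, fs=FS, window=(-1500.0, 2000.0), names=None):
    names = names or MONTAGE_32[: data.shape[0]]
    return TrialEpochs(data=data, sample_rate=fs, channel_names=names,
                       epoch_window=window)


def sinusoid_epochs(freq, fs=FS, n_ch=4, n_trials=2, amp=1.0):
    t = np.arange(int(3.5 * fs) + 1) / fs - 1.5
    sig = amp * np.sin(2 * np.pi * freq * t)
    data = np.tile(sig, (n_ch, n_trials, 1)).transpose(0, 2, 1)
    return make_epochs(data)


def fft_amplitude(x, fs, freq):
    spec = np.abs(np.fft.rfft(x)) / x.size * 2
    f = np.fft.rfftfreq(x.size, 1 / fs)
    return spec[np.argmin(np.abs(f - freq))]


class TestBandpass:
    def test_stopband_attenuation_exceeds_20db(self):
        raw = sinusoid_epochs(2.0)
        out = bandpass_epochs(raw, 4.0, 48.0)
        a_in = fft_amplitude(raw.data[0, :, 0], FS, 2.0)
        a_out = fft_amplitude(out.data[0, :, 0], FS, 2.0)
        assert 20 * np.log10(a_in / a_out) > 20

    def test_passband_amplitude_preserved(self):
        raw = sinusoid_epochs(20.0)
        out = bandpass_epochs(raw, 4.0, 48.0)
        a_out = fft_amplitude(out.data[0, :, 0], FS, 20.0)
        assert abs(a_out - 1.0) < 0.05

    def test_zero_in_zero_out(self):
        raw = make_epochs(np.zeros((4, int(3.5 * FS) + 1, 2)))
        assert np.allclose(bandpass_epochs(raw).data, 0.0)

    def test_bad_edges_raise(self):
        raw = sinusoid_epochs(10.0)
        with pytest.raises(ValueError):
            bandpass_epochs(raw, 4.0, 300.0)
        with pytest.raises(ValueError):
            bandpass_epochs(raw, 48.0, 4.0)


class TestArtifactRejection:
    def test_counting(self):
        rng = np.random.default_rng(0)
        data = 50.0 * rng.standard_normal((4, 100, 80))
        data[2, 10, [3, 40, 77]] = 600.0
        epochs = make_epochs(data, window=(0.0, 99.0 / FS * 1000.0))
        kept, rejected = reject_artifacts(epochs, 500.0)
        assert kept.n_trials == 77
        assert list(rejected) == [3, 40, 77]

    def test_strict_inequality_at_boundary(self):
        data = np.full((2, 50, 5), 499.9)
        epochs = make_epochs(data, window=(0.0, 49.0 / FS * 1000.0))
        kept, rejected = reject_artifacts(epochs, 500.0)
        assert kept.n_trials == 5 and rejected.size == 0
        data2 = data.copy()
        data2[0, 0, 0] = 500.0  # exactly at threshold: kept (strict >)
        kept2, _ = reject_artifacts(make_epochs(data2, window=(0.0, 49.0 / FS * 1000.0)))
        assert kept2.n_trials == 5

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        data = 140.0 * rng.standard_normal((6, 200, 40))
        epochs = make_epochs(data, window=(0.0, 199.0 / FS * 1000.0))
        kept, rejected = reject_artifacts(epochs, 500.0)
        survivors = [r for r in range(40) if np.abs(data[:, :, r]).max() <= 500.0]
        assert kept.n_trials == len(survivors)
        assert np.array_equal(kept.data, data[:, :, survivors])

    def test_all_rejected_raises(self):
        data = np.full((2, 50, 3), 1000.0)
        with pytest.raises(EmptyDataError):
            reject_artifacts(make_epochs(data, window=(0.0, 49.0 / FS * 1000.0)))


class TestFlip:
    def test_left_lesion_is_identity(self):
        rng = np.random.default_rng(2)
        epochs = make_epochs(rng.standard_normal((32, 100, 3)),
                             window=(0.0, 99.0 / FS * 1000.0))
        assert np.array_equal(flip_hemispheres(epochs, "left").data, epochs.data)

    def test_flip_twice_restores(self):
        rng = np.random.default_rng(3)
        epochs = make_epochs(rng.standard_normal((32, 100, 3)),
                             window=(0.0, 99.0 / FS * 1000.0))
        twice = flip_hemispheres(flip_hemispheres(epochs, "right"), "right")
        assert np.array_equal(twice.data, epochs.data)

    def test_flip_mirrors_lateralized_topography(self):
        # a left-lateralized source mixed through the geometric lead field,
        # flipped, must match mixing through the mirrored source directly
        coords = np.array([[-40.0, -12.0, 52.0]])
        L = make_lead_field(32, coords, mode="geometric")
        Lm = make_lead_field(32, coords * np.array([-1.0, 1.0, 1.0]),
                             mode="geometric")
        sig = np.sin(2 * np.pi * 10 * np.arange(100) / FS)
        data = L @ sig[None, :]
        epochs = make_epochs(data[:, :, None], window=(0.0, 99.0 / FS * 1000.0))
        flipped = flip_hemispheres(epochs, "right")
        expected = Lm @ sig[None, :]
        assert np.allclose(flipped.data[:, :, 0], expected, atol=1e-12)

    def test_unpaired_channel_raises(self):
        epochs = make_epochs(np.zeros((2, 50, 1)), names=["C3", "Cz"],
                             window=(0.0, 49.0 / FS * 1000.0))
        with pytest.raises(ValueError):
            flip_hemispheres(epochs, "right")


class TestSourceProjection:
    def test_noiseless_mixture_recovered(self):
        rng = np.random.default_rng(4)
        L = make_lead_field(32, seed=0)
        s = rng.standard_normal((5, 200, 3))
        epochs = make_epochs(np.einsum("cs,str->ctr", L, s),
                             window=(0.0, 199.0 / FS * 1000.0))
        rec = project_to_sources(epochs, L)
        assert np.allclose(rec, s, atol=1e-6)

    def test_zero_in_zero_out(self):
        L = make_lead_field(32, seed=0)
        epochs = make_epochs(np.zeros((32, 50, 2)), window=(0.0, 49.0 / FS * 1000.0))
        assert np.allclose(project_to_sources(epochs, L), 0.0)

    def test_matches_lstsq_oracle(self):
        rng = np.random.default_rng(5)
        L = make_lead_field(16, seed=1)
        data = rng.standard_normal((16, 30, 2))
        epochs = make_epochs(data, names=MONTAGE_32[:16],
                             window=(0.0, 29.0 / FS * 1000.0))
        rec = project_to_sources(epochs, L)
        for t in range(30):
            for r in range(2):
                x, *_ = np.linalg.lstsq(L, data[:, t, r], rcond=None)
                assert np.allclose(rec[:, t, r], x, atol=1e-10)

    def test_rank_deficient_warns(self):
        L = np.ones((8, 3))
        epochs = make_epochs(np.zeros((8, 20, 1)), names=MONTAGE_32[:8],
                             window=(0.0, 19.0 / FS * 1000.0))
        with pytest.warns(UserWarning, match="rank deficient"):
            project_to_sources(epochs, L)


class TestMorlet:
    def test_peak_at_signal_frequency(self):
        t = np.arange(int(2 * FS)) / FS
        sig = np.sin(2 * np.pi * 10.0 * t)
        freqs = np.arange(4.0, 30.0, 2.0)
        power = morlet_power(sig[None, :, None], FS, freqs)
        interior = slice(int(0.5 * FS), int(1.5 * FS))
        argmax = np.argmax(power[0, :, interior, 0], axis=0)
        assert np.all(freqs[argmax] == 10.0)

    def test_magnitude_linear_in_amplitude(self):
        t = np.arange(int(2 * FS)) / FS
        sig = np.sin(2 * np.pi * 20.0 * t)
        p1 = morlet_power(sig[None, :, None], FS, np.array([20.0]))
        p2 = morlet_power(2 * sig[None, :, None], FS, np.array([20.0]))
        assert np.allclose(p2, 2 * p1, atol=1e-10)

    def test_matches_direct_convolution_oracle(self):
        # brute-force oracle: explicit complex kernel, O(N*M) convolution
        rng = np.random.default_rng(6)
        sig = rng.standard_normal(400)
        freq = 12.0
        k = morlet_kernel(freq, FS, 7.0)
        n, m = sig.size, k.size
        direct = np.zeros(n, dtype=complex)
        # 'same' alignment of a full convolution
        full = np.zeros(n + m - 1, dtype=complex)
        for i in range(n):
            full[i:i + m] += sig[i] * k
        start = (m - 1) // 2
        direct = np.abs(full[start:start + n])
        power = morlet_power(sig[None, :, None], FS, np.array([freq]))
        assert np.allclose(power[0, 0, :, 0], direct, atol=1e-8)

    def test_frequency_above_nyquist_raises(self):
        with pytest.raises(ValueError):
            morlet_power(np.zeros((1, 100, 1)), FS, np.array([300.0]))


class TestBaseline:
    def times(self, n=71):
        return np.linspace(-1500.0, 2000.0, n)

    def test_constant_power_gives_zero_percent(self):
        times = self.times()
        power = np.full((2, 3, times.size, 4), 7.0)
        spec = average_and_baseline(power, times, np.array([6.0, 11.0, 22.0]),
                                    ["a", "b"])
        assert np.allclose(spec.power, 0.0)

    def test_doubling_gives_plus_100(self):
        times = self.times()
        power = np.full((1, 1, times.size, 1), 3.0)
        power[:, :, times >= 0.0, :] = 6.0
        spec = average_and_baseline(power, times, np.array([10.0]), ["a"])
        assert np.allclose(spec.power[0, 0, spec.times_ms >= 0.0], 100.0)

    def test_matches_manual_small_array_oracle(self):
        # 2 sources x 3 freqs x T x 4 trials with hand-computed answer
        rng = np.random.default_rng(7)
        times = self.times(351)
        power = rng.uniform(1.0, 5.0, size=(2, 3, times.size, 4))
        spec = average_and_baseline(power, times, np.array([5.0, 10.0, 20.0]),
                                    ["a", "b"])
        mean = power.mean(axis=3)
        bmask = (times >= -850.0) & (times <= -800.0)
        base = mean[:, :, bmask].mean(axis=2)
        cmask = (times >= -500.0) & (times <= 800.0)
        expected = 100.0 * (mean[:, :, cmask] - base[:, :, None]) / base[:, :, None]
        assert np.allclose(spec.power, expected, atol=1e-12)
        assert spec.times_ms[0] >= -500.0 and spec.times_ms[-1] <= 800.0

    def test_subtractive_mode(self):
        times = self.times()
        power = np.full((1, 1, times.size, 1), 3.0)
        power[:, :, times >= 0.0, :] = 5.0
        spec = average_and_baseline(power, times, np.array([10.0]), ["a"],
                                    mode="subtract")
        assert np.allclose(spec.power[0, 0, spec.times_ms >= 0.0], 2.0)

    def test_zero_baseline_raises(self):
        times = self.times()
        power = np.zeros((1, 1, times.size, 1))
        with pytest.raises(ZeroDivisionError):
            average_and_baseline(power, times, np.array([10.0]), ["a"])

    def test_bad_baseline_window_raises(self):
        times = self.times()
        power = np.ones((1, 1, times.size, 1))
        with pytest.raises(ValueError):
            average_and_baseline(power, times, np.array([10.0]), ["a"],
                                 baseline_window=(-200.0, 0.0))


class TestRoundTrip:
    def test_full_chain_tracks_generating_envelope(self, model_space):
        # noiseless synthetic source -> band-pass -> projection -> Morlet ->
        # baseline: band power must correlate > 0.9 with the generating
        # percent-power envelope.  Envelope dynamics are kept slower than
        # the theta wavelet's temporal resolution (7 cycles at 6 Hz smooth
        # over ~190 ms), which is the regime the transform can resolve.
        from motornet.dcm import default_intrinsic
        cfg = SimulationConfig(frequencies=FREQS4, sample_rate=500.0,
                               n_trials=6, seed=9, noise_sd=0.0)
        _, truth = generate_cohort(1, 1, cfg, model=model_space[0])
        slow = default_intrinsic(FREQS4, decay=2.5)
        truth.coupling[0].intrinsic = slow
        for e in truth.coupling[0].A:
            truth.coupling[0].A[e] *= 0.3  # keep the slow system stable
        epochs = simulate_eeg_trials(truth, cfg, subject=0)
        epochs = bandpass_epochs(epochs, 4.0, 48.0)
        series = project_to_sources(epochs, truth.lead_field)
        power = morlet_power(series, cfg.sample_rate, FREQS4)
        spec = average_and_baseline(power, epochs.times_ms, FREQS4,
                                    list(truth.coupling[0].source_labels))
        from motornet import simulate_induced_power
        pred = simulate_induced_power(truth.model, truth.coupling[0],
                                      times_ms=spec.times_ms)
        for s in range(5):
            for f in range(FREQS4.size):
                r = np.corrcoef(spec.power[s, f], pred.power[s, f])[0, 1]
                assert r > 0.9, (s, f, r)

    def test_no_stage_changes_trial_count_except_rejection(self, model_space):
        cfg = SimulationConfig(frequencies=FREQS4, sample_rate=250.0,
                               n_trials=5, seed=10, noise_sd=0.5)
        _, truth = generate_cohort(1, 1, cfg, model=model_space[0])
        epochs = simulate_eeg_trials(truth, cfg, subject=0)
        assert bandpass_epochs(epochs).n_trials == 5
        assert flip_hemispheres(epochs, "right").n_trials == 5
        series = project_to_sources(epochs, truth.lead_field)
        assert series.shape[2] == 5
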