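"""Filters, envelopes, channel repair, normalization and onset detection."""

import numpy as np
import pytest
from scipy import signal as sps

from hdemg.errors import ParameterError, SegmentationError, UnrecoverableChannelError
from hdemg.preprocess import (
    EnvelopeSet,
    auto_detect_faulty,
    bandpass,
    bandpass_sos,
    detect_onsets,
    envelope,
    moving_average,
    normalization_factors,
    notch,
    notch_ba,
    repair_channels,
)
from hdemg.session import ContractionProtocol
from hdemg.synth import NoiseModel, make_spatial_template, synthesize_session

FS = 2048.0


def _steady_amplitude(y, fs):
    """Peak amplitude of the central third of a trace (transients discarded)."""
    n = len(y)
    return np.abs(y[n // 3 : 2 * n // 3]).max()


class TestBandpass:
    def test_dc_is_rejected(self):
        x = np.ones((1, int(4 * FS)))
        y = bandpass(x, FS)
        assert _steady_amplitude(y[0], FS) < 1e-6

    @pytest.mark.parametrize(
        "freq, lo, hi",
        [(100.0, 0.95, 1.0), (5.0, 0.0, 0.05)],
    )
    def test_magnitude_response_at_probe_frequencies(self, freq, lo, hi):
        # oracle: the designed filter's frequency response, squared for the
        # zero-phase forward-backward application
        sos = bandpass_sos(FS)
        w, h = sps.sosfreqz(sos, worN=[freq], fs=FS)
        gain = np.abs(h[0]) ** 2
        assert lo <= gain <= hi
        # time-domain confirmation on a pure sinusoid
        t = np.arange(int(8 * FS)) / FS
        y = bandpass(np.sin(2 * np.pi * freq * t)[None, :], FS)
        assert lo - 1e-9 <= _steady_amplitude(y[0], FS) <= hi + 0.01

    def test_rejects_cutoff_above_nyquist(self):
        with pytest.raises(ParameterError):
            bandpass(np.zeros((1, 100)), 800.0, high=450.0)

    def test_filter_is_stable(self):
        sos = bandpass_sos(FS)
        imp = np.zeros(int(4 * FS))
        imp[0] = 1.0
        resp = sps.sosfilt(sos, imp)
        assert np.abs(resp[-100:]).max() < 1e-8 * np.abs(resp).max()


class TestNotch:
    def test_50hz_rejection_at_least_30db(self):
        b, a = notch_ba(FS)
        _, h = sps.freqz(b, a, worN=[50.0], fs=FS)
        assert 20 * np.log10(np.abs(h[0]) ** 2 + 1e-300) <= -30.0
        t = np.arange(int(10 * FS)) / FS
        y = notch(np.sin(2 * np.pi * 50.0 * t)[None, :], FS)
        assert _steady_amplitude(y[0], FS) < 10 ** (-30 / 20)

    def test_passband_untouched_at_100hz(self):
        b, a = notch_ba(FS)
        _, h = sps.freqz(b, a, worN=[100.0], fs=FS)
        assert np.abs(h[0]) ** 2 == pytest.approx(1.0, abs=0.01)

    def test_zero_input_zero_output(self):
        assert not notch(np.zeros((2, 4096)), FS).any()


class TestEnvelope:
    def test_zero_signal_zero_envelope(self):
        env = envelope(np.zeros((2, 4096)), FS)
        assert not env.envelopes.any()
        assert env.envelopes.shape == (2, 4096)

    def test_alternating_carrier_recovers_magnitude(self):
        # +/- c square carrier at 128 Hz rectifies to a constant c
        c = 3.0
        t = np.arange(int(6 * FS)) / FS
        x = c * np.sign(np.sin(2 * np.pi * 128.0 * t))
        env = envelope(x[None, :], FS)
        mid = env.envelopes[0, int(2 * FS) : int(4 * FS)]
        assert mid.mean() == pytest.approx(c, rel=0.02)

    def test_gaussian_carrier_mean_is_folded_normal(self, rng):
        # long-run simulation of the rectified-Gaussian mean sigma*sqrt(2/pi)
        sigma = 2.5
        x = sigma * rng.standard_normal(int(10 * FS))
        env = envelope(x[None, :], FS)
        mid = env.envelopes[0, int(2 * FS) : int(8 * FS)]
        assert mid.mean() == pytest.approx(sigma * np.sqrt(2 / np.pi), rel=0.05)

    def test_envelope_nonnegative(self, rng):
        x = rng.standard_normal((3, 4096))
        env = envelope(x, FS)
        assert np.all(env.envelopes >= 0)


class TestRepair:
    def test_constant_neighbors_give_constant(self, grid):
        data = np.ones((64, 100))
        data[grid.channel_of(3, 3) - 1] = 99.0
        fixed, _ = repair_channels(data, grid, [grid.channel_of(3, 3)])
        assert np.allclose(fixed[grid.channel_of(3, 3) - 1], 1.0)

    def test_longitudinal_extreme_uses_five_neighbors(self, grid, rng):
        data = rng.normal(size=(64, 50))
        ch = grid.channel_of(0, 0)
        fixed, _ = repair_channels(data, grid, [ch])
        neigh = [grid.channel_of(r, c) for r, c in grid.neighbors(0, 0)]
        assert len(neigh) == 5
        assert np.allclose(fixed[ch - 1], data[[n - 1 for n in neigh]].mean(axis=0))

    def test_adjacent_faulty_channels_order_independent(self, grid, rng):
        data = rng.normal(size=(64, 50))
        a, b = grid.channel_of(2, 3), grid.channel_of(2, 4)
        fixed_ab, _ = repair_channels(data, grid, [a, b])
        fixed_ba, _ = repair_channels(data, grid, [b, a])
        assert np.array_equal(fixed_ab, fixed_ba)
        # neither repaired channel used the other (faulty) one
        good_a = [grid.channel_of(r, c) for r, c in grid.neighbors(2, 3)
                  if grid.channel_of(r, c) != b]
        assert np.allclose(fixed_ab[a - 1], data[[g - 1 for g in good_a]].mean(axis=0))

    def test_repair_is_idempotent(self, grid, rng):
        data = rng.normal(size=(64, 50))
        faulty = [1, 17, 40]
        once, _ = repair_channels(data, grid, faulty)
        twice, _ = repair_channels(once, grid, faulty)
        assert np.array_equal(once, twice)

    def test_all_neighbors_faulty_is_unrecoverable(self, grid):
        center = grid.channel_of(3, 3)
        ring = [grid.channel_of(r, c) for r, c in grid.neighbors(3, 3)]
        with pytest.raises(UnrecoverableChannelError):
            repair_channels(np.ones((64, 10)), grid, [center] + ring)

    def test_auto_mode_flags_dead_and_saturated(self, grid, anth):
        protocol = ContractionProtocol(n_repetitions=2, fs=1024.0)
        tpl = make_spatial_template(grid, (2.0, 3.0), 1.0, 20.0)
        noise = NoiseModel(baseline_sd=1.0, seed=9,
                           faulty_channels={5: "dead", 50: "saturated-noise"})
        s = synthesize_session(tpl, protocol, noise, {"anthropometrics": anth, "grid": grid})
        assert sorted(auto_detect_faulty(s.signals)) == [5, 50]


class TestNormalization:
    def test_constant_envelope_gives_its_value(self):
        env = EnvelopeSet(np.full((2, 4096), 2.0), FS)
        nf = normalization_factors([env])
        assert np.allclose(nf.factors, 2.0)

    def test_single_spike_is_attenuated_by_moving_average(self):
        x = np.ones((1, int(4 * FS)))
        x[0, int(2 * FS)] = 100.0
        env = EnvelopeSet(x, FS)
        nf = normalization_factors([env])
        assert nf.factors[0] == pytest.approx(1 + 99 / 2048, rel=1e-6)

    def test_normalized_dataset_max_at_most_one(self, rng):
        env = EnvelopeSet(np.abs(rng.normal(size=(4, 8192))) + 0.1, FS)
        nf = normalization_factors([env])
        smoothed = moving_average(env.envelopes, FS, 1.0)
        assert np.all(smoothed / nf.factors[:, None] <= 1.0 + 1e-12)

    def test_factors_must_be_positive(self):
        env = EnvelopeSet(np.zeros((2, 2048)), FS)
        with pytest.raises(ParameterError):
            normalization_factors([env])


class TestOnsets:
    def _session(self, grid, anth, seed, n_rep=3, snr=20.0):
        protocol = ContractionProtocol(n_repetitions=n_rep, fs=1024.0)
        tpl = make_spatial_template(grid, (2.3, 3.7), 1.2, snr * 1.0)
        noise = NoiseModel(baseline_sd=1.0, powerline_amplitude=1.0, seed=seed)
        s = synthesize_session(tpl, protocol, noise, {"anthropometrics": anth, "grid": grid})
        return s, protocol

    def test_planted_onsets_recovered_within_100ms(self, grid, anth):
        for seed in range(5):
            s, protocol = self._session(grid, anth, seed)
            env = envelope(bandpass(s.signals, s.fs), s.fs)
            seg = detect_onsets(env, protocol)
            detected = seg.onset_times(s.fs)
            planted = protocol.onset_times()
            assert len(detected) == protocol.n_repetitions
            assert np.all(np.abs(detected - planted) <= 0.1)
            assert np.all(np.diff(seg.onsets) > 0)

    def test_steady_window_is_contraction_shrunk_by_margin(self, grid, anth):
        s, protocol = self._session(grid, anth, 1)
        env = envelope(bandpass(s.signals, s.fs), s.fs)
        seg = detect_onsets(env, protocol)
        n_margin = int(1.0 * s.fs)  # (3 s - 1 s) / 2
        for (c0, c1), (s0, s1) in zip(seg.contraction_windows, seg.steady_windows):
            assert s0 == c0 + n_margin
            assert s1 == c1 - n_margin

    def test_quiet_recording_raises_segmentation_error(self, grid, anth):
        protocol = ContractionProtocol(n_repetitions=3, fs=1024.0)
        env = EnvelopeSet(np.abs(np.random.default_rng(0).normal(0, 0.1, (64, protocol.n_samples))), 1024.0)
        with pytest.raises(SegmentationError) as exc:
            detect_onsets(env, protocol)
        assert exc.value.n_found == 0

    def test_missing_burst_reports_count(self, grid, anth):
        s, _ = self._session(grid, anth, 2, n_rep=2)
        protocol_claimed = ContractionProtocol(n_repetitions=4, fs=1024.0)
        env = envelope(bandpass(s.signals, s.fs), s.fs)
        with pytest.raises(SegmentationError) as exc:
            detect_onsets(env, protocol_claimed)
        assert exc.value.n_found == 2
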