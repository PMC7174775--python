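"""Signal conditioning: filters, envelopes, channel repair, segmentation.

The chain mirrors standard offline HD-sEMG practice: a fourth-order
Butterworth band-pass (20-450 Hz), a second-order IIR notch at the 50 Hz
powerline frequency (Q = 50), full-wave rectification followed by a
third-order 2 Hz Butterworth low-pass to obtain amplitude envelopes,
8-neighborhood interpolation of faulty channels, onset detection at 10
standard deviations above the baseline, and per-channel normalization by the
maximum of a 1-s moving-averaged envelope across the participant's complete
dataset.  All filtering is zero-phase (forward-backward), which is
appropriate offline and keeps onset estimates free of group delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import ParameterError, SegmentationError, UnrecoverableChannelError
from .grid import ElectrodeGrid
from .session import ContractionProtocol


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def bandpass_sos(fs: float, low: float = 20.0, high: float = 450.0, order: int = 4):
    """Design the Butterworth band-pass (second-order sections)."""
    if not 0 < low < high:
        raise ParameterError("need 0 < low < high")
    if high >= fs / 2:
        raise ParameterError(f"high cutoff {high} Hz must be below Nyquist {fs / 2} Hz")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(
    signals: np.ndarray, fs: float, low: float = 20.0, high: float = 450.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied per channel."""
    sos = bandpass_sos(fs, low, high, order)
    return sps.sosfiltfilt(sos, np.asarray(signals, dtype=np.float64), axis=-1)


def notch_ba(fs: float, f0: float = 50.0, q: float = 50.0):
    """Design the second-order IIR notch (numerator/denominator)."""
    if not 0 < f0 < fs / 2:
        raise ParameterError("notch frequency must lie in (0, fs/2)")
    return sps.iirnotch(f0, q, fs=fs)


def notch(signals: np.ndarray, fs: float, f0: float = 50.0, q: float = 50.0) -> np.ndarray:
    """Zero-phase narrow-band rejection at f0 (powerline)."""
    b, a = notch_ba(fs, f0, q)
    return sps.filtfilt(b, a, np.asarray(signals, dtype=np.float64), axis=-1)


@dataclass
class EnvelopeSet:
    """Non-negative amplitude envelopes, same shape as the source signals."""

    envelopes: np.ndarray
    fs: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.envelopes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.envelopes.shape[-1]


def envelope(signals: np.ndarray, fs: float, lp: float = 2.0, order: int = 3) -> EnvelopeSet:
    """Full-wave rectification followed by a zero-phase Butterworth low-pass.

    Tiny negative excursions from low-pass ringing are clamped to zero:
    envelopes are amplitudes.
    """
    if not 0 < lp < fs / 2:
        raise ParameterError("low-pass cutoff must lie in (0, fs/2)")
    sos = sps.butter(order, lp, btype="lowpass", fs=fs, output="sos")
    env = sps.sosfiltfilt(sos, np.abs(np.asarray(signals, dtype=np.float64)), axis=-1)
    np.clip(env, 0.0, None, out=env)
    return EnvelopeSet(env, fs, provenance={"lp_hz": lp, "order": order, "zero_phase": True})


# ---------------------------------------------------------------------------
# Faulty-channel repair
# ---------------------------------------------------------------------------

def auto_detect_faulty(
    signals: np.ndarray, high_factor: float = 5.0, low_factor: float = 0.05
) -> list[int]:
    """Flag channels whose rest-level amplitude is an outlier vs. the median channel.

    An explicit stand-in for the visual time/frequency-domain inspection used
    in practice.  The statistic is each channel's lower-quartile rectified
    amplitude — with an on/off contraction protocol the lower quartile falls
    in the rest periods, so a genuinely active electrode is not mistaken for
    a saturated one.  A channel is flagged when its rest level exceeds
    ``high_factor`` times, or falls below ``low_factor`` times, the median
    channel's.  Returns 1-based channel indices; a manually supplied faulty
    list always takes precedence over this rule.
    """
    rest_level = np.quantile(np.abs(np.asarray(signals, dtype=np.float64)), 0.25, axis=-1)
    med = np.median(rest_level)
    if med <= 0:
        return []
    bad = (rest_level > high_factor * med) | (rest_level < low_factor * med)
    return [int(i) + 1 for i in np.flatnonzero(bad)]


def repair_channels(
    data: np.ndarray,
    grid: ElectrodeGrid,
    faulty: Sequence[int] | str = "auto",
) -> tuple[np.ndarray, list[int]]:
    """Replace faulty channels by the mean of their non-faulty 8-neighbors.

    Rows wrap circumferentially; cells at the longitudinal extremes use their
    (five) available neighbors.  ``faulty`` is a list of 1-based channel
    indices, or ``"auto"`` to apply the RMS outlier rule.  Each faulty channel
    is rebuilt only from non-faulty neighbors, so the result is independent of
    repair order and idempotent for a fixed faulty list.

    Returns the repaired copy and the faulty list actually used.
    """
    data = np.array(data, dtype=np.float64, copy=True)
    if isinstance(faulty, str):
        if faulty != "auto":
            raise ParameterError(f"faulty must be a channel list or 'auto', got {faulty!r}")
        faulty_list = auto_detect_faulty(data)
    else:
        faulty_list = [int(c) for c in faulty]
    bad = set(faulty_list)
    for ch in bad:
        if not 1 <= ch <= grid.n_channels:
            raise ParameterError(f"faulty channel {ch} outside 1..{grid.n_channels}")
    replacements = {}
    for ch in sorted(bad):
        row, col = grid.position_of(ch)
        good = [grid.channel_of(r, c) for r, c in grid.neighbors(row, col)]
        good = [g for g in good if g not in bad]
        if not good:
            raise UnrecoverableChannelError(
                f"channel {ch} has no non-faulty neighbors to interpolate from"
            )
        replacements[ch] = np.mean([data[g - 1] for g in good], axis=0)
    for ch, rep in replacements.items():
        data[ch - 1] = rep
    return data, faulty_list


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def moving_average(env: np.ndarray, fs: float, window_s: float = 1.0) -> np.ndarray:
    """Centered moving average along the last axis (edges use nearest values)."""
    size = max(1, int(round(window_s * fs)))
    return uniform_filter1d(np.asarray(env, dtype=np.float64), size=size, axis=-1, mode="nearest")


@dataclass
class NormalizationFactors:
    """Per-channel normalization values (microvolts).

    The factor of a channel is the maximum, across the participant's complete
    dataset, of the 1-s moving-averaged envelope — the moving average guards
    the maximum against single-sample artifacts.
    """

    factors: np.ndarray
    window_s: float = 1.0

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=np.float64)
        if np.any(self.factors <= 0):
            bad = np.flatnonzero(self.factors <= 0) + 1
            raise ParameterError(f"non-positive normalization factor for channels {bad.tolist()}")


def normalization_factors(
    envelope_sets: Iterable[EnvelopeSet], window_s: float = 1.0
) -> NormalizationFactors:
    """Max of the moving-averaged envelope over a participant's complete dataset."""
    factors = None
    for env in envelope_sets:
        smoothed = moving_average(env.envelopes, env.fs, window_s)
        m = smoothed.max(axis=-1)
        factors = m if factors is None else np.maximum(factors, m)
    if factors is None:
        raise ParameterError("normalization_factors requires at least one envelope set")
    return NormalizationFactors(factors, window_s)


# ---------------------------------------------------------------------------
# Onset detection / segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    """Detected contraction onsets and derived analysis windows (samples)."""

    onsets: list[int]
    contraction_windows: list[tuple[int, int]]
    steady_windows: list[tuple[int, int]]
    threshold_used: float
    baseline_stats: tuple[float, float]

    def onset_times(self, fs: float) -> np.ndarray:
        return np.asarray(self.onsets, dtype=np.float64) / fs


def summary_trace(env: EnvelopeSet, quantile: float = 0.25, window_s: float = 1.0) -> np.ndarray:
    """Aggregate envelope used for onset detection.

    Each channel is normalized by its own within-recording factor (max of the
    moving-averaged envelope); the trace is the mean over channels whose
    factor exceeds the given quantile of all factors — robust to dead
    channels, which otherwise dilute or distort the aggregate.
    """
    smoothed = moving_average(env.envelopes, env.fs, window_s)
    factors = smoothed.max(axis=-1)
    cutoff = np.quantile(factors, quantile)
    keep = factors > cutoff
    if not np.any(keep):
        keep = factors >= cutoff
    safe = np.where(factors > 0, factors, 1.0)
    normalized = env.envelopes / safe[:, None]
    return normalized[keep].mean(axis=0)


def detect_onsets(
    env: EnvelopeSet,
    protocol: ContractionProtocol,
    k: float = 10.0,
    steady_s: float = 1.0,
    settle_s: float = 0.5,
    channel: int | None = None,
) -> SegmentationResult:
    """Segment a recording into contraction and steady-state windows.

    An onset is the first sample at which the summary envelope exceeds
    ``baseline_mean + k * baseline_sd``; the baseline is estimated over the
    lead-in rest interval after discarding the first ``settle_s`` seconds
    (filter settling).  Each contraction window spans ``contraction_s`` from
    its onset; the steady window is the contraction window shrunk by an equal
    margin on each side to ``steady_s`` (the middle second, by default).
    After each detected contraction the trace must fall back below the
    threshold before the next onset is searched.

    ``channel`` switches to single-channel mode (1-based index) instead of
    the channel-aggregate summary trace.
    """
    fs = env.fs
    if channel is not None:
        smoothed = moving_average(env.envelopes[channel - 1], fs, 1.0)
        factor = smoothed.max()
        trace = env.envelopes[channel - 1] / (factor if factor > 0 else 1.0)
    else:
        trace = summary_trace(env)
    n = trace.shape[0]

    b0 = int(round(settle_s * fs))
    b1 = int(round(protocol.lead_in * fs))
    if b1 - b0 < 2:
        raise SegmentationError("lead-in rest too short to estimate a baseline", n_found=0)
    base = trace[b0:b1]
    mu, sd = float(base.mean()), float(base.std(ddof=1))
    threshold = mu + k * sd

    n_contr = int(round(protocol.contraction_s * fs))
    margin = (protocol.contraction_s - steady_s) / 2
    if margin < 0:
        raise ParameterError("steady_s exceeds contraction_s")
    n_margin = int(round(margin * fs))
    n_steady = int(round(steady_s * fs))

    onsets: list[int] = []
    pos = b0
    while len(onsets) < protocol.n_repetitions:
        above = np.flatnonzero(trace[pos:] > threshold)
        if above.size == 0:
            raise SegmentationError(
                f"found {len(onsets)} activity bursts, expected {protocol.n_repetitions}",
                n_found=len(onsets),
            )
        onset = pos + int(above[0])
        if onset + n_contr > n:
            raise SegmentationError(
                f"burst {len(onsets) + 1} runs past the end of the recording",
                n_found=len(onsets),
            )
        onsets.append(onset)
        # require the trace to drop below threshold before searching again
        tail = onset + n_contr
        below = np.flatnonzero(trace[tail:] < threshold)
        pos = tail + (int(below[0]) if below.size else trace[tail:].shape[0])

    contraction_windows = [(o, o + n_contr) for o in onsets]
    steady_windows = [(o + n_margin, o + n_margin + n_steady) for o in onsets]
    return SegmentationResult(
        onsets=onsets,
        contraction_windows=contraction_windows,
        steady_windows=steady_windows,
        threshold_used=threshold,
        baseline_stats=(mu, sd),
    )
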