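"""Synthetic HD-sEMG cohorts with known ground truth.

The generator emulates the statistical structure the analysis chain assumes:
each gesture activates a spatially localized region of the 8x8 electrode grid
(a Gaussian bump on the forearm cylinder); a trapezoidal on/off envelope
amplitude-modulates band-limited (20-450 Hz) Gaussian carrier noise,
independent per channel; baseline instrument noise, a 50 Hz powerline
sinusoid and optional faulty channels are added on top.  Because the carrier
is zero-mean Gaussian, rectification followed by a 2 Hz low-pass recovers the
modulation envelope scaled by the rectified-Gaussian mean factor
sqrt(2/pi) ~= 0.7979.

Cohort profiles plant group-level ground truth: the number of distinct base
activation patterns (recoverable as PCA dimensionality), the normalized
activation level reached during comfortable gestures (realized by scaling a
maximal-effort reference recording into the normalization dataset), and the
absolute envelope scale in microvolts.  Gestures beyond the distinct-pattern
count blend neighbouring base patterns, producing the correlated gesture
structure characteristic of reduced motor-pattern repertoires.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .grid import Anthropometrics, ElectrodeGrid, grid_from_anthropometrics
from .session import GESTURES, ContractionProtocol, RecordingSession

#: Mean of |X| for X ~ N(0, 1): the factor linking carrier SD to envelope level.
RECTIFIED_GAUSSIAN_MEAN = math.sqrt(2.0 / math.pi)


# ---------------------------------------------------------------------------
# Spatial templates
# ---------------------------------------------------------------------------

@dataclass
class SpatialTemplate:
    """A non-negative 8x8 activation pattern with a known center.

    ``amplitudes`` are on the carrier-SD scale in microvolts at full
    contraction.  ``center`` is real-valued in grid coordinates (row wraps
    around the forearm).
    """

    amplitudes: np.ndarray
    center: tuple[float, float]
    spread: float
    gesture_id: str = ""

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if np.any(self.amplitudes < 0):
            raise ParameterError("template amplitudes must be non-negative")

    def centroid(self, n_rows: int = 8) -> tuple[float, float]:
        """Unthresholded amplitude-weighted centroid (circular in rows)."""
        w = self.amplitudes
        total = w.sum()
        if total <= 0:
            raise ParameterError("null template has no centroid")
        rows = np.arange(w.shape[0], dtype=np.float64)
        cols = np.arange(w.shape[1], dtype=np.float64)
        col_c = float((w.sum(axis=0) * cols).sum() / total)
        rw = w.sum(axis=1)
        ang = 2 * np.pi * rows / n_rows
        x = float((rw * np.cos(ang)).sum())
        y = float((rw * np.sin(ang)).sum())
        if math.hypot(x, y) < 1e-12 * total:
            row_c = float((rw * rows).sum() / total)
        else:
            row_c = (math.atan2(y, x) * n_rows / (2 * np.pi)) % n_rows
            row_c = ((row_c + 0.5) % n_rows) - 0.5
        return row_c, col_c


def make_spatial_template(
    grid: ElectrodeGrid,
    center: tuple[float, float],
    spread: float,
    peak: float,
    wrap_circumferential: bool = True,
    gesture_id: str = "",
) -> SpatialTemplate:
    """Isotropic Gaussian activation bump in grid units, max value = ``peak``.

    Rows wrap around the forearm cylinder when ``wrap_circumferential`` is
    set (wrapped Gaussian).  Columns do not wrap; to keep the unthresholded
    centroid exactly on ``center`` for centres on the half-integer lattice,
    column weights are truncated to the largest support symmetric about the
    centre that fits the grid.
    """
    if spread <= 0:
        raise ParameterError("spread must be > 0")
    if peak < 0:
        raise ParameterError("peak must be >= 0")
    cr, cc = float(center[0]), float(center[1])
    if wrap_circumferential:
        cr = cr % grid.n_rows  # rows live on the forearm cylinder
    elif not -0.5 <= cr <= grid.n_rows - 0.5:
        raise ParameterError(f"center {center} outside grid extent")
    if not -0.5 <= cc <= grid.n_cols - 0.5:
        raise ParameterError(f"center {center} outside grid extent")
    rows = np.arange(grid.n_rows, dtype=np.float64)
    cols = np.arange(grid.n_cols, dtype=np.float64)
    with np.errstate(under="ignore"):
        if wrap_circumferential:
            row_w = np.zeros(grid.n_rows)
            for k in (-1, 0, 1):
                row_w += np.exp(-((rows - cr + k * grid.n_rows) ** 2) / (2 * spread**2))
        else:
            row_w = np.exp(-((rows - cr) ** 2) / (2 * spread**2))
        col_w = np.exp(-((cols - cc) ** 2) / (2 * spread**2))
    # symmetric column support: cells beyond the mirrorable radius are zeroed
    radius = min(cc - (-0.5), (grid.n_cols - 0.5) - cc)
    col_w[np.abs(cols - cc) > radius + 1e-9] = 0.0
    amp = np.outer(row_w, col_w)
    m = amp.max()
    if m > 0 and peak > 0:
        amp = amp * (peak / m)
    else:
        amp = np.zeros_like(amp)
    return SpatialTemplate(amplitudes=amp, center=(cr, cc), spread=spread, gesture_id=gesture_id)


# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Interference and fault structure added to the clean modulated carrier.

    ``faulty_channels`` maps 1-based channel index -> mode (``"dead"``:
    baseline noise scaled by 0.01; ``"saturated-noise"``: baseline noise
    scaled by 50 — the two failure signatures visual inspection flags).
    """

    carrier_band: tuple[float, float] = (20.0, 450.0)
    baseline_sd: float = 2.0
    powerline_amplitude: float = 1.0
    powerline_hz: float = 50.0
    faulty_channels: dict[int, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.carrier_band
        if not 0 < lo < hi:
            raise ParameterError("carrier band must satisfy 0 < low < high")
        if self.baseline_sd < 0:
            raise ParameterError("baseline_sd must be >= 0")
        if self.powerline_amplitude < 0:
            raise ParameterError("powerline_amplitude must be >= 0")
        for ch, mode in self.faulty_channels.items():
            if mode not in ("dead", "saturated-noise"):
                raise ParameterError(f"unknown faulty mode {mode!r} for channel {ch}")


def trapezoid_envelope(protocol: ContractionProtocol, n_samples: int | None = None) -> np.ndarray:
    """Instructed activation profile: 0 at rest, trapezoid (ramp up, plateau,
    ramp down) for each contraction."""
    n = protocol.n_samples if n_samples is None else n_samples
    t = np.arange(n) / protocol.fs
    env = np.zeros(n)
    ramp = protocol.ramp_s
    for onset in protocol.onset_times():
        end = onset + protocol.contraction_s
        seg = (t >= onset) & (t < end)
        if ramp > 0:
            up = np.clip((t - onset) / ramp, 0.0, 1.0)
            down = np.clip((end - t) / ramp, 0.0, 1.0)
            env[seg] = np.minimum(up, down)[seg]
        else:
            env[seg] = 1.0
    return env


def _bandlimited_noise(rng: np.random.Generator, n_ch: int, n: int, band, fs: float) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to ``band`` (per channel)."""
    lo, hi = band
    hi = min(hi, 0.999 * fs / 2)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = rng.standard_normal((n_ch, n))
    x = sps.sosfiltfilt(sos, x, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def synthesize_session(
    template: SpatialTemplate | list[SpatialTemplate],
    protocol: ContractionProtocol,
    noise: NoiseModel,
    participant_meta: dict,
    rep_gains: np.ndarray | None = None,
) -> RecordingSession:
    """Generate one recording: modulated carrier + baseline + powerline + faults.

    Per channel c: ``signal = envelope(t) * gain_rep * template[c] * carrier``
    plus baseline noise and the powerline sinusoid.  ``template`` may be a
    single pattern or one pattern per repetition (repetition-to-repetition
    pattern variability); ``rep_gains`` scales each repetition's amplitude.
    Fully reproducible from ``noise.seed``.
    """
    anth: Anthropometrics = participant_meta["anthropometrics"]
    grid = participant_meta.get("grid") or grid_from_anthropometrics(
        anth.forearm_length_cm, anth.circumference_cm, anth.handedness
    )
    templates = template if isinstance(template, list) else [template] * protocol.n_repetitions
    if len(templates) != protocol.n_repetitions:
        raise ParameterError("need one template per repetition")
    if rep_gains is None:
        rep_gains = np.ones(protocol.n_repetitions)
    rep_gains = np.asarray(rep_gains, dtype=np.float64)
    if rep_gains.shape != (protocol.n_repetitions,):
        raise ParameterError("rep_gains must have one entry per repetition")

    n_ch = grid.n_channels
    n = protocol.n_samples
    fs = protocol.fs
    rng = np.random.default_rng(noise.seed)

    # per-channel amplitude profile over time
    profile = np.zeros((n_ch, n))
    t = np.arange(n) / fs
    ramp = protocol.ramp_s
    for rep, onset in enumerate(protocol.onset_times()):
        end = onset + protocol.contraction_s
        i0, i1 = int(round(onset * fs)), min(int(round(end * fs)), n)
        seg_t = t[i0:i1]
        if ramp > 0:
            env = np.minimum(np.clip((seg_t - onset) / ramp, 0, 1), np.clip((end - seg_t) / ramp, 0, 1))
        else:
            env = np.ones(i1 - i0)
        ch_amp = grid.channel_values(templates[rep].amplitudes) * rep_gains[rep]
        profile[:, i0:i1] += np.outer(ch_amp, env)

    if np.any(profile > 0):
        carrier = _bandlimited_noise(rng, n_ch, n, noise.carrier_band, fs)
        sig = profile * carrier
    else:
        sig = np.zeros((n_ch, n))

    if noise.baseline_sd > 0:
        sig += noise.baseline_sd * _bandlimited_noise(rng, n_ch, n, noise.carrier_band, fs)
    if noise.powerline_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        sig += noise.powerline_amplitude * np.sin(
            2 * np.pi * noise.powerline_hz * t[None, :] + phases[:, None]
        )
    for ch, mode in noise.faulty_channels.items():
        scale = 0.01 if mode == "dead" else 50.0
        sig[ch - 1] = scale * noise.baseline_sd * rng.standard_normal(n)

    return RecordingSession(
        signals=sig.astype(np.float32),
        fs=fs,
        gesture_label=participant_meta.get("gesture_label", "synthetic"),
        participant_id=participant_meta.get("participant_id", "SP0"),
        protocol=protocol,
        anthropometrics=anth,
        group=participant_meta.get("group", "unknown"),
        extra={"seed": noise.seed},
    )


# ---------------------------------------------------------------------------
# Cohort profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortProfile:
    """Group-level generating conditions for a synthetic cohort.

    ``normalized_activation_level`` is the fraction of the per-channel
    maximum reached during comfortable gestures; ``absolute_scale`` is the
    target gesture envelope amplitude in microvolts; ``mix_jitter`` is the
    SD of repetition-to-repetition perturbations of the gesture's
    base-pattern mixing weights (co-activation variability).
    """

    group: str
    n_templates_distinct: int
    template_spread: float
    normalized_activation_level: float
    absolute_scale: float
    rep_amplitude_jitter: float = 0.10
    mix_jitter: float = 0.05
    mvc_background: float = 0.2
    forearm_length_cm: tuple[float, float] = (24.8, 1.8)
    circumference_cm: tuple[float, float] = (25.9, 1.8)

    def __post_init__(self):
        if not 0 < self.normalized_activation_level <= 1:
            raise ParameterError("normalized_activation_level must be in (0, 1]")
        if not 1 <= self.n_templates_distinct <= 7:
            raise ParameterError("n_templates_distinct must be between 1 and 7")
        if self.template_spread <= 0:
            raise ParameterError("template_spread must be > 0")
        if self.absolute_scale <= 0:
            raise ParameterError("absolute_scale must be > 0")


#: Healthy group defaults: broad repertoire (5 distinct patterns), comfortable
#: contractions at 26% of maximum, 89 uV envelope scale.
HEALTHY_PROFILE = CohortProfile(
    group="healthy",
    n_templates_distinct=5,
    template_spread=1.4,
    normalized_activation_level=0.26,
    absolute_scale=89.0,
    mix_jitter=0.05,
    forearm_length_cm=(24.8, 1.8),
    circumference_cm=(25.9, 1.8),
)

#: DMD group defaults: reduced repertoire (3 distinct patterns), near-maximal
#: comfortable contractions (63%), 35 uV envelope scale, smaller activation
#: areas and larger co-activation variability.
DMD_PROFILE = CohortProfile(
    group="dmd",
    n_templates_distinct=3,
    template_spread=1.0,
    normalized_activation_level=0.63,
    absolute_scale=35.0,
    mix_jitter=0.12,
    forearm_length_cm=(24.2, 2.9),
    circumference_cm=(25.5, 3.9),
)


def gesture_mixing_weights(n_gestures: int, n_distinct: int) -> np.ndarray:
    """Base-pattern mixing weight vectors, one row per gesture.

    The first ``n_distinct`` gestures map to pure base patterns; each further
    gesture blends a neighbouring pair of bases (0.7/0.3, dropping to
    0.55/0.45 on the second wrap) so correlated gestures never add rank.
    """
    w = np.zeros((n_gestures, n_distinct))
    for g in range(n_gestures):
        if g < n_distinct:
            w[g, g] = 1.0
        else:
            j = g - n_distinct
            a, b = j % n_distinct, (j + 1) % n_distinct
            wa = 0.7 if j < n_distinct else 0.55
            w[g, a], w[g, b] = wa, 1.0 - wa
    return w


@dataclass
class ParticipantData:
    """One synthetic participant: sessions plus the planted ground truth."""

    participant_id: str
    group: str
    anthropometrics: Anthropometrics
    grid: ElectrodeGrid
    sessions: dict[str, RecordingSession]
    mvc_session: RecordingSession
    ground_truth: dict


def _base_centers(rng: np.random.Generator, n_distinct: int, grid: ElectrodeGrid):
    """Spread base-pattern centres around the cylinder, jittered per participant.

    Centres sit on two longitudinal rings (a proximal and a distal column),
    with rows evenly spaced around the circumference within each ring and the
    rings offset by half a spacing — this keeps every pair of patterns,
    including wrap-around row neighbours, well separated on the cylinder.
    """
    ring_cols = (2.0, 5.0)
    members: list[list[int]] = [[], []]
    for k in range(n_distinct):
        members[k % 2].append(k)
    centers: list[tuple[float, float]] = [(0.0, 0.0)] * n_distinct
    for ring, ks in enumerate(members):
        if not ks:
            continue
        spacing = grid.n_rows / len(ks)
        for j, k in enumerate(ks):
            row = (spacing * j + ring * spacing / 2 + rng.uniform(-0.4, 0.4)) % grid.n_rows
            col = ring_cols[ring] + rng.uniform(-0.3, 0.3)
            centers[k] = (float(row), float(col))
    return centers


def make_participant(
    profile: CohortProfile,
    participant_id: str,
    seed_seq: np.random.SeedSequence,
    gestures: tuple[str, ...] = GESTURES,
    protocol: ContractionProtocol | None = None,
    noise: NoiseModel | None = None,
) -> ParticipantData:
    """Generate one participant's full dataset (7 gestures + a maximal-effort
    reference recording used for normalization)."""
    protocol = protocol or ContractionProtocol()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed_seq)
    child_seeds = seed_seq.spawn(len(gestures) + 1)

    length = max(15.0, rng.normal(*profile.forearm_length_cm))
    circ = max(15.0, rng.normal(*profile.circumference_cm))
    anth = Anthropometrics(length, circ)
    grid = grid_from_anthropometrics(length, circ)

    d = profile.n_templates_distinct
    centers = _base_centers(rng, d, grid)
    # profile scale is the target *envelope* amplitude; the carrier SD that
    # produces it is larger by 1/sqrt(2/pi)
    carrier_scale = profile.absolute_scale / RECTIFIED_GAUSSIAN_MEAN
    bases = [
        make_spatial_template(grid, c, profile.template_spread, 1.0, gesture_id=f"base{k}")
        for k, c in enumerate(centers)
    ]
    base_mats = np.stack([b.amplitudes for b in bases])
    weights = gesture_mixing_weights(len(gestures), d)

    def mixture_template(w: np.ndarray, label: str) -> SpatialTemplate:
        amp = np.tensordot(w, base_mats, axes=(0, 0))
        m = amp.max()
        if m > 0:
            amp = amp / m
        dom = int(np.argmax(w))
        return SpatialTemplate(amp, center=centers[dom], spread=profile.template_spread,
                               gesture_id=label)

    sessions: dict[str, RecordingSession] = {}
    gesture_truth = {}
    for gi, gesture in enumerate(gestures):
        g_rng = np.random.default_rng(child_seeds[gi])
        rep_templates = []
        for _ in range(protocol.n_repetitions):
            w = weights[gi] + g_rng.normal(0, profile.mix_jitter, size=d)
            w = np.clip(w, 0, None)
            if w.sum() == 0:
                w = weights[gi].copy()
            rep_templates.append(mixture_template(w, gesture))
        gains = carrier_scale * np.clip(
            g_rng.normal(1.0, profile.rep_amplitude_jitter, size=protocol.n_repetitions),
            0.2, None,
        )
        g_noise = replace(noise, seed=int(child_seeds[gi].generate_state(1)[0] % (2**31)))
        sessions[gesture] = synthesize_session(
            rep_templates, protocol, g_noise,
            {
                "anthropometrics": anth, "grid": grid, "gesture_label": gesture,
                "participant_id": participant_id, "group": profile.group,
            },
            rep_gains=gains,
        )
        gesture_truth[gesture] = {
            "weights": weights[gi].tolist(),
            "rep_gains_uv": gains.tolist(),
            "dominant_center": centers[int(np.argmax(weights[gi]))],
        }

    # maximal-effort reference: cycles the base patterns at full amplitude,
    # no repetition jitter (a single instructed-maximum recording).  Maximal
    # dynamic effort co-contracts the whole forearm, so every electrode sees
    # at least ``mvc_background`` of its local maximum — without it, electrodes
    # far from every base pattern would be normalized by their noise floor.
    mvc_protocol = replace(protocol, n_repetitions=max(d, 3))
    mvc_templates = [
        SpatialTemplate(
            np.maximum(base_mats[r % d], profile.mvc_background),
            centers[r % d], profile.template_spread, "mvc",
        )
        for r in range(mvc_protocol.n_repetitions)
    ]
    mvc_gain = carrier_scale / profile.normalized_activation_level
    mvc_noise = replace(noise, seed=int(child_seeds[-1].generate_state(1)[0] % (2**31)))
    mvc_session = synthesize_session(
        mvc_templates, mvc_protocol, mvc_noise,
        {
            "anthropometrics": anth, "grid": grid, "gesture_label": "mvc",
            "participant_id": participant_id, "group": profile.group,
        },
        rep_gains=np.full(mvc_protocol.n_repetitions, mvc_gain),
    )

    truth = {
        "participant_id": participant_id,
        "group": profile.group,
        "planted_rank": d,
        "base_centers": centers,
        "template_spread": profile.template_spread,
        "normalized_activation_level": profile.normalized_activation_level,
        "absolute_scale_uv": profile.absolute_scale,
        "onset_times_s": protocol.onset_times().tolist(),
        "gestures": gesture_truth,
        "seed_entropy": list(map(int, np.atleast_1d(seed_seq.entropy))),
    }
    return ParticipantData(
        participant_id=participant_id,
        group=profile.group,
        anthropometrics=anth,
        grid=grid,
        sessions=sessions,
        mvc_session=mvc_session,
        ground_truth=truth,
    )


def make_cohort(
    profile: CohortProfile,
    n_participants: int,
    gestures: tuple[str, ...] = GESTURES,
    seed: int = 0,
    protocol: ContractionProtocol | None = None,
    noise: NoiseModel | None = None,
) -> list[ParticipantData]:
    """Generate a cohort of participants sharing one generating profile.

    Identical (profile, n_participants, seed) arguments reproduce the cohort
    exactly.
    """
    if n_participants < 0:
        raise ParameterError("n_participants must be >= 0")
    group_key = zlib.crc32(profile.group.encode()) % (2**31)
    root = np.random.SeedSequence([int(seed), group_key])
    children = root.spawn(n_participants)
    prefix = "HP" if profile.group == "healthy" else "DP" if profile.group == "dmd" else "SP"
    return [
        make_participant(profile, f"{prefix}{i + 1}", children[i], gestures, protocol, noise)
        for i in range(n_participants)
    ]
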