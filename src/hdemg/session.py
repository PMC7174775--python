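"""Core acquisition types: contraction protocol and recording session."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .grid import Anthropometrics

#: The seven hand/wrist gestures of the study protocol, in listing order.
GESTURES = (
    "hand_open",
    "hand_close",
    "thumb_flexion",
    "thumb_extension",
    "wrist_flexion",
    "wrist_extension",
    "index_extension",
)


@dataclass(frozen=True)
class ContractionProtocol:
    """Timing of the instructed contraction/rest cycle.

    Each repetition is ``contraction_s`` of activity followed by ``rest_s`` of
    rest; the recording opens with a lead-in rest of ``lead_in_s`` (defaults
    to ``rest_s``) used for baseline estimation.  ``ramp_s`` is the rise/fall
    time of the trapezoidal activation envelope used by the synthesizer.
    """

    n_repetitions: int = 10
    contraction_s: float = 3.0
    rest_s: float = 3.0
    fs: float = 2048.0
    ramp_s: float = 0.25
    lead_in_s: float | None = None

    def __post_init__(self):
        if self.n_repetitions < 1:
            raise ParameterError("n_repetitions must be >= 1")
        if self.contraction_s <= 0:
            raise ParameterError("contraction_s must be > 0")
        if self.rest_s < 0:
            raise ParameterError("rest_s must be >= 0")
        if self.fs <= 2 * 450:
            raise ParameterError("fs must exceed twice the 450 Hz EMG band edge")
        if not (0 <= self.ramp_s <= self.contraction_s / 2):
            raise ParameterError("ramp_s must lie in [0, contraction_s/2]")

    @property
    def lead_in(self) -> float:
        return self.rest_s if self.lead_in_s is None else self.lead_in_s

    @property
    def duration_s(self) -> float:
        """Total recording duration: lead-in plus n cycles of on/off."""
        return self.lead_in + self.n_repetitions * (self.contraction_s + self.rest_s)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def onset_times(self) -> np.ndarray:
        """Instructed contraction onset times in seconds."""
        period = self.contraction_s + self.rest_s
        return self.lead_in + period * np.arange(self.n_repetitions)


@dataclass
class RecordingSession:
    """One gesture recording: a channels x samples matrix plus its metadata.

    Signals are stored as float32 microvolts so that the on-disk bundle
    round-trips bit-exactly.
    """

    signals: np.ndarray
    fs: float
    gesture_label: str
    participant_id: str
    protocol: ContractionProtocol
    anthropometrics: Anthropometrics
    group: str = "unknown"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signals = np.ascontiguousarray(self.signals, dtype=np.float32)
        if self.signals.ndim != 2:
            raise ParameterError("signals must be a 2-D channels x samples matrix")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        for name in ("gesture_label", "participant_id"):
            if not getattr(self, name):
                raise ParameterError(f"missing metadata field: {name}")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]
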