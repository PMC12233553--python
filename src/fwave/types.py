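"""Shared domain types for F-wave study analysis.

An F-wave study records, per supramaximal stimulation of a motor nerve, a
post-stimulus voltage trace containing the direct compound muscle action
potential (M-wave) and, intermittently, the late antidromic response
(F-wave).  A *session* is one patient visit: 5-8 stimulations per nerve for
a subset of the four routinely studied nerves, plus demographics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Nerve",
    "UPPER_LIMB_NERVES",
    "LOWER_LIMB_NERVES",
    "SEGMENT_CUT_MS",
    "Waveform",
    "Annotations",
    "Session",
    "SurvivalRecord",
]


class Nerve(str, Enum):
    """The four nerve-muscle pairs of a routine F-wave study."""

    ULNAR = "ulnar"
    MEDIAN = "median"
    FIBULAR = "fibular"
    TIBIAL = "tibial"


NERVE_ORDER = (Nerve.ULNAR, Nerve.MEDIAN, Nerve.FIBULAR, Nerve.TIBIAL)

UPPER_LIMB_NERVES = frozenset({Nerve.ULNAR, Nerve.MEDIAN})
LOWER_LIMB_NERVES = frozenset({Nerve.FIBULAR, Nerve.TIBIAL})

#: M-wave / F-wave segment boundary (ms post stimulus): the M-wave of an
#: upper-limb nerve has ended by 20 ms, of a lower-limb nerve by 35 ms.
SEGMENT_CUT_MS = {
    Nerve.ULNAR: 20.0,
    Nerve.MEDIAN: 20.0,
    Nerve.FIBULAR: 35.0,
    Nerve.TIBIAL: 35.0,
}


@dataclass
class Waveform:
    """One post-stimulus voltage trace with acquisition metadata.

    ``samples`` are signed mV; time zero is the stimulation instant and the
    first sample sits at ``start_ms`` (0 for raw recordings, 2.5 after the
    standard artefact trim).
    """

    samples: np.ndarray
    sampling_rate: float  # Hz
    nerve: Nerve
    patient_id: str = ""
    session_id: str = ""
    stim_index: int = 0
    stim_amplitude: float = 0.0  # mA
    stim_duration: float = 0.0  # ms
    start_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")
        self.nerve = Nerve(self.nerve)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sampling_rate * 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        return self.start_ms + np.arange(self.n_samples) / self.sampling_rate * 1000.0

    def replace_samples(self, samples: np.ndarray, *, sampling_rate: Optional[float] = None,
                        start_ms: Optional[float] = None) -> "Waveform":
        return Waveform(
            samples=samples,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            nerve=self.nerve,
            patient_id=self.patient_id,
            session_id=self.session_id,
            stim_index=self.stim_index,
            stim_amplitude=self.stim_amplitude,
            stim_duration=self.stim_duration,
            start_ms=self.start_ms if start_ms is None else start_ms,
        )


#: clinical mark names, in temporal order within each potential
MARK_NAMES = (
    "m_onset",
    "m_neg_peak",
    "m_pos_peak",
    "m_offset",
    "f_onset",
    "f_neg_peak",
    "f_pos_peak",
    "f_offset",
)


@dataclass
class Annotations:
    """Ground-truth clinical marks for one waveform.

    Each mark is a ``(latency_ms, amplitude_mv)`` pair; the four F-wave marks
    are ``None`` when no F-wave occurred on that stimulation.
    """

    m_onset: tuple[float, float]
    m_neg_peak: tuple[float, float]
    m_pos_peak: tuple[float, float]
    m_offset: tuple[float, float]
    f_onset: Optional[tuple[float, float]] = None
    f_neg_peak: Optional[tuple[float, float]] = None
    f_pos_peak: Optional[tuple[float, float]] = None
    f_offset: Optional[tuple[float, float]] = None

    @property
    def f_present(self) -> bool:
        return self.f_onset is not None

    def as_dict(self) -> dict[str, Optional[tuple[float, float]]]:
        return {name: getattr(self, name) for name in MARK_NAMES}


@dataclass
class Session:
    """One patient visit: stimulations grouped by nerve, plus demographics."""

    patient_id: str
    session_id: str
    label: str  # diagnosis group, e.g. "als" / "control"
    age: float  # years
    sex: str  # "female" / "male"
    bmi: float  # kg/m^2
    source: str  # recording machine vendor
    waveforms: dict[Nerve, list[Waveform]] = field(default_factory=dict)
    annotations: dict[Nerve, list[Annotations]] = field(default_factory=dict)

    @property
    def nerves(self) -> list[Nerve]:
        return [n for n in NERVE_ORDER if n in self.waveforms]


@dataclass
class SurvivalRecord:
    """Right-censored survival observation for one ALS patient."""

    duration: float  # months, onset -> death or onset -> censor date
    event: bool
    sex: str
    onset_site: str  # bulbar / upper_limb / lower_limb / other
    family_history: str  # none / als / als_ftd / ftd / parkinsonism
    diagnostic_delay: float  # months
    age_at_onset: float  # years
    bmi: float
    model_score: float  # log-odds of ALS from the classifier

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
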