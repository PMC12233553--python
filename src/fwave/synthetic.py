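"""Synthetic F-wave study generator.

Emulates the statistical structure a wavelet-based F-wave analysis relies
on, without claiming physiological detail:

* a biphasic M-wave atom at a short, stereotyped latency, followed — on a
  random subset of stimulations — by a small, polyphasic F-wave atom whose
  latency varies across stimulations (chronodispersion);
* disease presets that shift persistence, chronodispersion and amplitudes
  in the directions reported clinically for ALS and its common mimics;
* cohorts with skewed demographics matched to published percentile triples
  and realistic per-session nerve subsets;
* right-censored survival times from a Weibull proportional-hazards model.

Waveform atoms are built from raised-cosine (Hann) lobes: smooth, with a
peak exactly at the lobe centre and *compact support*, so ground-truth
annotations are exact and the M- and F-segments partition the trace with
no leakage across the nerve-specific cut point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .types import (
    Annotations,
    LOWER_LIMB_NERVES,
    NERVE_ORDER,
    Nerve,
    SEGMENT_CUT_MS,
    Session,
    SurvivalRecord,
    UPPER_LIMB_NERVES,
    Waveform,
)

__all__ = [
    "WaveformParams",
    "PhenotypePreset",
    "CohortSpec",
    "SurvivalGenSpec",
    "PRESETS",
    "NERVE_PHYSIOLOGY",
    "generate_waveform",
    "generate_session",
    "generate_cohort",
    "generate_survival_records",
    "percentile_sampler",
]

VALID_RATES_HZ = (10_000.0, 20_000.0, 40_000.0)

#: fraction of M-wave amplitude carried by its positive (second) lobe
M_POS_FRACTION = 0.4
#: total F-wave duration (ms) over which its alternating lobes are spread
F_WAVE_DURATION_MS = 12.0
#: geometric taper between successive F-wave lobes
F_LOBE_TAPER = 0.75


# ----------------------------------------------------------------------
# parameter records
# ----------------------------------------------------------------------

@dataclass
class WaveformParams:
    """Generative parameters for a single post-stimulus trace."""

    nerve: Nerve
    m_onset_latency: float  # ms
    m_amplitude: float  # mV, negative-peak magnitude (>0)
    m_duration: float  # ms
    f_present: bool
    f_onset_latency: float  # ms
    f_amplitude: float  # mV, magnitude of the leading negative lobe
    f_n_phases: int = 3
    noise_sd: float = 0.02  # mV
    sampling_rate: float = 10_000.0  # Hz
    record_duration: float = 310.0  # ms
    stim_amplitude: float = 40.0  # mA
    stim_duration: float = 0.2  # ms

    def validate(self) -> None:
        self.nerve = Nerve(self.nerve)
        if self.sampling_rate not in VALID_RATES_HZ:
            raise ValueError(f"sampling_rate must be one of {VALID_RATES_HZ} Hz, got {self.sampling_rate}")
        if self.record_duration < 310.0:
            raise ValueError(f"record_duration must be >= 310 ms, got {self.record_duration}")
        if self.m_amplitude <= 0:
            raise ValueError(f"m_amplitude must be positive, got {self.m_amplitude}")
        if self.m_duration <= 0:
            raise ValueError(f"m_duration must be positive, got {self.m_duration}")
        if self.m_onset_latency < 0:
            raise ValueError(f"m_onset_latency must be >= 0, got {self.m_onset_latency}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.f_n_phases < 1:
            raise ValueError(f"f_n_phases must be >= 1, got {self.f_n_phases}")
        if self.f_present:
            if self.f_onset_latency <= self.m_onset_latency:
                raise ValueError(
                    "f_onset_latency must exceed m_onset_latency "
                    f"({self.f_onset_latency} <= {self.m_onset_latency})"
                )
            if self.f_amplitude <= 0:
                raise ValueError(f"f_amplitude must be positive, got {self.f_amplitude}")
            if self.f_amplitude > 0.2 * self.m_amplitude + 1e-12:
                raise ValueError(
                    f"f_amplitude must be <= 0.2 * m_amplitude "
                    f"({self.f_amplitude} > 0.2 * {self.m_amplitude})"
                )


@dataclass
class PhenotypePreset:
    """Diagnosis-group effect profile applied on top of control physiology.

    ``affected_nerves`` restricts the effects (radiculopathies are limb
    specific); unaffected nerves keep control parameters.
    """

    label: str
    f_persistence: float = 0.9  # P(F-wave present) per stimulation
    chronodispersion_sd: float = 1.0  # ms, SD of F latency across stims
    m_amplitude_scale: float = 1.0
    f_amplitude_scale: float = 1.0
    latency_shift: float = 0.0  # ms added to the nerve's mean F latency
    affected_nerves: frozenset[Nerve] = frozenset(NERVE_ORDER)

    def validate(self) -> None:
        if not 0.0 <= self.f_persistence <= 1.0:
            raise ValueError(f"f_persistence must be in [0, 1], got {self.f_persistence}")
        if self.chronodispersion_sd < 0:
            raise ValueError(f"chronodispersion_sd must be >= 0, got {self.chronodispersion_sd}")
        if self.m_amplitude_scale <= 0 or self.f_amplitude_scale <= 0:
            raise ValueError("amplitude scales must be positive")


#: qualitative clinical signatures; magnitudes are free parameters.
PRESETS: dict[str, PhenotypePreset] = {
    "control": PhenotypePreset(label="control"),
    "als": PhenotypePreset(
        label="als",
        f_persistence=0.5,
        chronodispersion_sd=3.0,
        m_amplitude_scale=0.6,
        f_amplitude_scale=1.5,
    ),
    "ibm": PhenotypePreset(label="ibm", m_amplitude_scale=0.5),
    "cervical_radiculopathy": PhenotypePreset(
        label="cervical_radiculopathy",
        f_persistence=0.75,
        chronodispersion_sd=1.8,
        m_amplitude_scale=0.85,
        f_amplitude_scale=1.2,
        affected_nerves=frozenset(UPPER_LIMB_NERVES),
    ),
    "lumbar_radiculopathy": PhenotypePreset(
        label="lumbar_radiculopathy",
        f_persistence=0.75,
        chronodispersion_sd=1.8,
        m_amplitude_scale=0.85,
        f_amplitude_scale=1.2,
        affected_nerves=frozenset(LOWER_LIMB_NERVES),
    ),
    "peripheral_neuropathy": PhenotypePreset(
        label="peripheral_neuropathy",
        m_amplitude_scale=0.7,
        latency_shift=8.0,
    ),
}


#: control-condition physiology per nerve: M-wave onset/duration/amplitude
#: and mean F latency, consistent with 20 / 35 ms upper/lower segment cuts.
NERVE_PHYSIOLOGY: dict[Nerve, dict[str, float]] = {
    Nerve.ULNAR: dict(m_onset=3.5, m_duration=9.0, m_amplitude=8.0, f_latency_mean=28.0),
    Nerve.MEDIAN: dict(m_onset=4.0, m_duration=9.0, m_amplitude=9.0, f_latency_mean=29.0),
    Nerve.FIBULAR: dict(m_onset=5.0, m_duration=10.0, m_amplitude=4.0, f_latency_mean=48.0),
    Nerve.TIBIAL: dict(m_onset=5.5, m_duration=10.0, m_amplitude=10.0, f_latency_mean=50.0),
}

#: relative F-wave amplitude (fraction of the subject's M amplitude)
F_AMP_FRACTION = 0.12
#: log-SD of per-subject, per-nerve amplitude variability
SUBJECT_AMP_LOG_SD = 0.25

#: per-session nerve subsets and their probabilities: the fibular+tibial
#: pair dominates and the median nerve is the least stimulated.
DEFAULT_NERVE_SUBSETS: dict[tuple[str, ...], float] = {
    ("fibular", "tibial"): 0.30,
    ("ulnar", "median", "fibular", "tibial"): 0.25,
    ("ulnar", "fibular", "tibial"): 0.15,
    ("ulnar",): 0.10,
    ("tibial",): 0.08,
    ("fibular",): 0.07,
    ("ulnar", "median"): 0.05,
}

#: 5th/50th/95th percentile triples (matched ALS / control test cohort)
DEFAULT_AGE_TRIPLES = {"als": (42.5, 64.7, 80.3), "control": (42.5, 64.7, 80.3)}
DEFAULT_BMI_TRIPLES = {"als": (19.2, 26.2, 37.7), "control": (20.8, 27.5, 39.1)}
DEFAULT_FEMALE_FRACTION = 0.437


@dataclass
class CohortSpec:
    """Recipe for a labelled cohort of synthetic F-wave sessions."""

    n_per_group: int = 200
    group_presets: Sequence[PhenotypePreset] = (PRESETS["als"], PRESETS["control"])
    age_triples: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_TRIPLES))
    bmi_triples: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BMI_TRIPLES))
    sex_fraction_female: float = DEFAULT_FEMALE_FRACTION
    nerve_subset_distribution: Mapping[tuple[str, ...], float] = field(
        default_factory=lambda: dict(DEFAULT_NERVE_SUBSETS))
    stimulations_per_nerve: tuple[int, int] = (5, 8)
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ValueError("sex_fraction_female must be a probability")
        total = sum(self.nerve_subset_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"nerve_subset_distribution must sum to 1, sums to {total}")
        lo, hi = self.stimulations_per_nerve
        if not (5 <= lo <= hi <= 8):
            raise ValueError(f"stimulations_per_nerve must lie within [5, 8], got {lo, hi}")
        for preset in self.group_presets:
            preset.validate()
            for mapping, name in ((self.age_triples, "age"), (self.bmi_triples, "bmi")):
                triple = mapping.get(preset.label)
                if triple is None:
                    raise ValueError(f"missing {name} percentile triple for group {preset.label!r}")
                if not triple[0] < triple[1] < triple[2]:
                    raise ValueError(f"{name} percentile triple for {preset.label!r} must be strictly increasing")


@dataclass
class SurvivalGenSpec:
    """Weibull proportional-hazards generator for right-censored records.

    ``true_betas`` maps covariate names to log hazard ratios.  Numeric
    covariates (age_at_onset, bmi, diagnostic_delay, model_score) take their
    beta on the standardized (z) scale; categorical levels are keyed as
    ``"name=level"`` and take their beta on the 0/1 indicator.
    """

    n: int = 500
    true_betas: Mapping[str, float] = field(default_factory=dict)
    baseline_shape: float = 1.2  # Weibull k
    baseline_scale: float = 36.0  # months
    censor_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("baseline parameters must be positive")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ValueError(f"censor_fraction must be in [0, 1), got {self.censor_fraction}")


# ----------------------------------------------------------------------
# waveform synthesis
# ----------------------------------------------------------------------

def _hann_lobe(t_ms: np.ndarray, start_ms: float, width_ms: float, amplitude: float) -> np.ndarray:
    """Raised-cosine lobe: peak = ``amplitude`` at the centre, zero outside."""
    u = (t_ms - start_ms) / width_ms
    out = np.zeros_like(t_ms)
    inside = (u > 0.0) & (u < 1.0)
    out[inside] = amplitude * np.sin(np.pi * u[inside]) ** 2
    return out


def _m_wave_atom(t_ms: np.ndarray, params: WaveformParams) -> tuple[np.ndarray, dict]:
    """Biphasic M-wave: negative lobe then a smaller positive lobe."""
    onset, dur, amp = params.m_onset_latency, params.m_duration, params.m_amplitude
    neg = _hann_lobe(t_ms, onset, 0.55 * dur, -amp)
    pos = _hann_lobe(t_ms, onset + 0.45 * dur, 0.55 * dur, M_POS_FRACTION * amp)
    marks = {
        "m_onset": (onset, 0.0),
        "m_neg_peak": (onset + 0.275 * dur, -amp),
        "m_pos_peak": (onset + 0.725 * dur, M_POS_FRACTION * amp),
        "m_offset": (onset + dur, 0.0),
    }
    return neg + pos, marks


def _f_wave_atom(t_ms: np.ndarray, params: WaveformParams) -> tuple[np.ndarray, dict]:
    """Polyphasic F-wave: alternating tapered lobes, leading lobe negative."""
    onset, amp, n = params.f_onset_latency, params.f_amplitude, params.f_n_phases
    lobe_w = F_WAVE_DURATION_MS / n
    trace = np.zeros_like(t_ms)
    neg_peak = pos_peak = None
    for i in range(n):
        a = amp * (F_LOBE_TAPER ** i) * (-1 if i % 2 == 0 else 1)
        start = onset + i * lobe_w
        trace += _hann_lobe(t_ms, start, lobe_w, a)
        centre = start + lobe_w / 2
        if a < 0 and (neg_peak is None or a < neg_peak[1]):
            neg_peak = (centre, a)
        if a > 0 and (pos_peak is None or a > pos_peak[1]):
            pos_peak = (centre, a)
    marks = {
        "f_onset": (onset, 0.0),
        "f_neg_peak": neg_peak,
        "f_pos_peak": pos_peak,
        "f_offset": (onset + F_WAVE_DURATION_MS, 0.0),
    }
    return trace, marks


def generate_waveform(params: WaveformParams, rng_seed) -> tuple[Waveform, Annotations]:
    """Render one post-stimulus trace and its ground-truth annotations.

    ``rng_seed`` may be an int or a ``numpy.random.Generator``.  The trace is
    the sum of the M-wave atom, the F-wave atom (iff ``f_present``) and iid
    Gaussian noise of SD ``noise_sd``; annotations report the exact
    generative latencies and amplitudes.
    """
    params.validate()
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    n = round(params.record_duration * params.sampling_rate / 1000.0)
    t_ms = np.arange(n) / params.sampling_rate * 1000.0
    trace, m_marks = _m_wave_atom(t_ms, params)
    f_marks: dict = {}
    if params.f_present:
        f_trace, f_marks = _f_wave_atom(t_ms, params)
        trace = trace + f_trace
    if params.noise_sd > 0:
        trace = trace + rng.normal(0.0, params.noise_sd, size=n)
    wf = Waveform(
        samples=trace,
        sampling_rate=params.sampling_rate,
        nerve=params.nerve,
        stim_amplitude=params.stim_amplitude,
        stim_duration=params.stim_duration,
    )
    ann = Annotations(**m_marks, **f_marks)
    return wf, ann


# ----------------------------------------------------------------------
# sessions
# ----------------------------------------------------------------------

def _nerve_params(nerve: Nerve, preset: PhenotypePreset, rng: np.random.Generator,
                  noise_sd: float) -> dict:
    """Session-level (fixed across stimulations) parameters for one nerve."""
    phys = NERVE_PHYSIOLOGY[nerve]
    affected = nerve in preset.affected_nerves
    m_scale = preset.m_amplitude_scale if affected else 1.0
    f_scale = preset.f_amplitude_scale if affected else 1.0
    subject_factor = math.exp(rng.normal(0.0, SUBJECT_AMP_LOG_SD))
    m_amp = phys["m_amplitude"] * m_scale * subject_factor
    f_amp = min(F_AMP_FRACTION * f_scale, 0.2) * m_amp
    return dict(
        m_onset=phys["m_onset"],
        m_duration=phys["m_duration"],
        m_amplitude=m_amp,
        f_amplitude=f_amp,
        f_latency_mean=phys["f_latency_mean"] + (preset.latency_shift if affected else 0.0),
        f_persistence=preset.f_persistence if affected else PRESETS["control"].f_persistence,
        chronodispersion_sd=(preset.chronodispersion_sd if affected
                             else PRESETS["control"].chronodispersion_sd),
        stim_amplitude=float(rng.uniform(20.0, 60.0)),
        stim_duration=0.2,
        noise_sd=noise_sd,
    )


def plan_session_nerve(nerve: Nerve, preset: PhenotypePreset, n_stims: int,
                       rng: np.random.Generator, noise_sd: float = 0.02) -> list[WaveformParams]:
    """Draw the per-stimulation generative parameters for one nerve.

    F-wave presence is Bernoulli(f_persistence) per stimulation; F latency is
    Normal(nerve mean + shift, chronodispersion_sd), kept clear of the M/F
    segment boundary.  Stimulus amplitude/duration are fixed across the set.
    """
    base = _nerve_params(nerve, preset, rng, noise_sd)
    cut = SEGMENT_CUT_MS[nerve]
    out = []
    for _ in range(n_stims):
        present = bool(rng.random() < base["f_persistence"])
        latency = float(rng.normal(base["f_latency_mean"], base["chronodispersion_sd"]))
        latency = min(max(latency, cut + 0.5), 290.0 - F_WAVE_DURATION_MS)
        out.append(WaveformParams(
            nerve=nerve,
            m_onset_latency=base["m_onset"],
            m_amplitude=base["m_amplitude"],
            m_duration=base["m_duration"],
            f_present=present,
            f_onset_latency=latency,
            f_amplitude=base["f_amplitude"],
            noise_sd=base["noise_sd"],
            stim_amplitude=base["stim_amplitude"],
            stim_duration=base["stim_duration"],
        ))
    return out


def generate_session(preset: PhenotypePreset, demographics: Mapping, protocol: Mapping,
                     rng_seed, *, render: bool = True) -> Session:
    """Generate one session.

    ``protocol`` needs ``nerves`` (non-empty list) and ``stimulations_per_nerve``
    (int, 5-8).  ``demographics`` supplies age/sex/bmi/source and optional ids.
    With ``render=False`` only the generative plan is drawn (annotations carry
    the planned marks; waveform lists stay empty) — useful for calibration
    studies that do not need sampled traces.
    """
    preset.validate()
    nerves = [Nerve(n) for n in protocol["nerves"]]
    if not nerves:
        raise ValueError("protocol must name at least one nerve")
    k = int(protocol["stimulations_per_nerve"])
    if not 5 <= k <= 8:
        raise ValueError(f"stimulations_per_nerve must be in [5, 8], got {k}")
    noise_sd = float(protocol.get("noise_sd", 0.02))
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed

    session = Session(
        patient_id=str(demographics.get("patient_id", "P0")),
        session_id=str(demographics.get("session_id", "S0")),
        label=preset.label,
        age=float(demographics["age"]),
        sex=str(demographics["sex"]),
        bmi=float(demographics["bmi"]),
        source=str(demographics.get("source", "natus")),
    )
    for nerve in nerves:
        plans = plan_session_nerve(nerve, preset, k, rng, noise_sd)
        wfs, anns = [], []
        for i, p in enumerate(plans):
            if render:
                wf, _ = generate_waveform(p, rng)
                wf.patient_id, wf.session_id, wf.stim_index = session.patient_id, session.session_id, i
                wfs.append(wf)
            anns.append(_annotate(p))
        session.waveforms[nerve] = wfs
        session.annotations[nerve] = anns
    return session


def _annotate(params: WaveformParams) -> Annotations:
    t_empty = np.empty(0)
    _, m_marks = _m_wave_atom(t_empty, params)
    f_marks = _f_wave_atom(t_empty, params)[1] if params.f_present else {}
    return Annotations(**m_marks, **f_marks)


# ----------------------------------------------------------------------
# demographics
# ----------------------------------------------------------------------

_Z95 = 1.6448536269514722


def percentile_sampler(p5: float, p50: float, p95: float) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Sampler matching three percentiles exactly via a shifted log-normal.

    Right-skewed triples use ``loc + LogNormal``; left-skewed triples use the
    mirrored construction; symmetric triples collapse to a normal.  The
    returned callable maps ``(rng, n) -> samples``.
    """
    if not p5 < p50 < p95:
        raise ValueError(f"percentile triple must be strictly increasing, got {(p5, p50, p95)}")
    right, left = p95 - p50, p50 - p5

    if abs(right - left) < 1e-9 * (p95 - p5):
        sd = (p95 - p5) / (2 * _Z95)
        return lambda rng, n: rng.normal(p50, sd, size=n)

    def shifted_lognormal(r_right: float, r_left: float):
        sigma = math.log(r_right / r_left) / _Z95
        em = r_right * r_left / (r_right - r_left)
        mu = math.log(em)
        return sigma, mu, em

    if right > left:
        sigma, mu, em = shifted_lognormal(right, left)
        loc = p50 - em
        return lambda rng, n: loc + rng.lognormal(mu, sigma, size=n)
    sigma, mu, em = shifted_lognormal(left, right)
    loc = -p50 - em  # mirrored: Y = -X has the reflected, right-skewed triple
    return lambda rng, n: -(loc + rng.lognormal(mu, sigma, size=n))


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------

def generate_cohort(spec: CohortSpec, *, render: bool = True) -> list[Session]:
    """Generate a labelled cohort with exact group sizes, reproducibly."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    subsets = list(spec.nerve_subset_distribution.keys())
    subset_p = np.array([spec.nerve_subset_distribution[s] for s in subsets])
    lo, hi = spec.stimulations_per_nerve

    sessions: list[Session] = []
    pid = 0
    for preset in spec.group_presets:
        age_draw = percentile_sampler(*spec.age_triples[preset.label])
        bmi_draw = percentile_sampler(*spec.bmi_triples[preset.label])
        ages = age_draw(rng, spec.n_per_group)
        bmis = bmi_draw(rng, spec.n_per_group)
        for i in range(spec.n_per_group):
            pid += 1
            subset = subsets[rng.choice(len(subsets), p=subset_p)]
            demo = dict(
                patient_id=f"P{pid:05d}",
                session_id=f"S{pid:05d}",
                age=float(np.clip(ages[i], 18.0, 100.0)),
                sex="female" if rng.random() < spec.sex_fraction_female else "male",
                bmi=float(np.clip(bmis[i], 13.0, 60.0)),
                source="natus" if rng.random() < 0.5 else "cadwell",
            )
            protocol = dict(
                nerves=list(subset),
                stimulations_per_nerve=int(rng.integers(lo, hi + 1)),
                noise_sd=spec.noise_sd,
            )
            sessions.append(generate_session(preset, demo, protocol, rng, render=render))
    return sessions


# ----------------------------------------------------------------------
# survival
# ----------------------------------------------------------------------

ONSET_SITES = ("bulbar", "upper_limb", "lower_limb", "other")
ONSET_SITE_P = (0.25, 0.30, 0.40, 0.05)
FAMILY_HISTORIES = ("none", "als", "als_ftd", "ftd", "parkinsonism")
FAMILY_HISTORY_P = (0.85, 0.06, 0.03, 0.03, 0.03)

#: numeric covariates: (mean, sd) used both to scale z draws into natural
#: units and to define the standardized scale the betas act on
NUMERIC_COVARIATES = {
    "diagnostic_delay": (12.0, 6.0),
    "age_at_onset": (64.0, 10.0),
    "bmi": (26.5, 4.5),
    "model_score": (1.5, 1.5),
}


def generate_survival_records(spec: SurvivalGenSpec) -> list[SurvivalRecord]:
    """Sample right-censored records from a Weibull proportional-hazards model.

    ``S(t|z) = exp(-(t/scale)^shape * exp(eta))`` with ``eta = beta' z``;
    event times are drawn by inversion.  Censoring times are Uniform(0, c),
    with ``c`` calibrated by bisection so the expected censored fraction over
    the realized event times equals ``censor_fraction``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    z = {name: rng.normal(0.0, 1.0, size=n) for name in NUMERIC_COVARIATES}
    site = rng.choice(ONSET_SITES, size=n, p=ONSET_SITE_P)
    fh = rng.choice(FAMILY_HISTORIES, size=n, p=FAMILY_HISTORY_P)
    sex = np.where(rng.random(n) < 0.43, "female", "male")

    eta = np.zeros(n)
    for key, beta in spec.true_betas.items():
        if key in NUMERIC_COVARIATES:
            eta += beta * z[key]
        elif "=" in key:
            name, level = key.split("=", 1)
            col = {"onset_site": site, "family_history": fh, "sex": sex}[name]
            eta += beta * (col == level)
        else:
            raise ValueError(f"unknown covariate in true_betas: {key!r}")

    exp1 = rng.exponential(1.0, size=n)
    durations = spec.baseline_scale * (exp1 * np.exp(-eta)) ** (1.0 / spec.baseline_shape)
    durations = np.maximum(durations, 1e-3)

    if spec.censor_fraction > 0:
        c_max = _calibrate_censor_bound(durations, spec.censor_fraction)
        censor_times = rng.uniform(0.0, c_max, size=n)
        event = durations <= censor_times
        observed = np.where(event, durations, censor_times)
        observed = np.maximum(observed, 1e-3)
    else:
        event = np.ones(n, dtype=bool)
        observed = durations

    records = []
    for i in range(n):
        records.append(SurvivalRecord(
            duration=float(observed[i]),
            event=bool(event[i]),
            sex=str(sex[i]),
            onset_site=str(site[i]),
            family_history=str(fh[i]),
            diagnostic_delay=float(NUMERIC_COVARIATES["diagnostic_delay"][0]
                                   + NUMERIC_COVARIATES["diagnostic_delay"][1] * z["diagnostic_delay"][i]),
            age_at_onset=float(NUMERIC_COVARIATES["age_at_onset"][0]
                               + NUMERIC_COVARIATES["age_at_onset"][1] * z["age_at_onset"][i]),
            bmi=float(NUMERIC_COVARIATES["bmi"][0] + NUMERIC_COVARIATES["bmi"][1] * z["bmi"][i]),
            model_score=float(NUMERIC_COVARIATES["model_score"][0]
                              + NUMERIC_COVARIATES["model_score"][1] * z["model_score"][i]),
        ))
    return records


def _calibrate_censor_bound(durations: np.ndarray, target: float) -> float:
    """Find c so that mean_i P(U(0,c) < t_i) = target, by bisection."""
    def frac(c: float) -> float:
        return float(np.mean(np.minimum(durations / c, 1.0)))

    lo, hi = 1e-6, float(durations.max()) * 2
    while frac(hi) > target:
        hi *= 2
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
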