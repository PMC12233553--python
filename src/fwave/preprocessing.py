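"""Raw-trace normalisation: resample to 10 kHz, trim, split into M/F segments.

Time conventions: time zero is the stimulation instant; the trim window is
half-open ``[start_ms, end_ms)`` with sample index ``round(t * fs)``, which
makes segment counts deterministic and the M/F split an exact partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

from scipy.signal import resample_poly

from .types import Nerve, SEGMENT_CUT_MS, Waveform

__all__ = ["TARGET_RATE_HZ", "SegmentPair", "resample_to_10khz", "trim_window", "split_m_f", "preprocess"]

logger = logging.getLogger(__name__)

TARGET_RATE_HZ = 10_000.0
STANDARD_RATES_HZ = (10_000.0, 20_000.0, 40_000.0)

TRIM_START_MS = 2.5
TRIM_END_MS = 300.0


@dataclass
class SegmentPair:
    """M-wave and F-wave segments of one trimmed trace, split at ``cut_ms``."""

    m_segment: Waveform
    f_segment: Waveform
    cut_ms: float


def resample_to_10khz(w: Waveform) -> Waveform:
    """Polyphase rational resampling to 10 kHz (anti-aliased, duration preserving).

    The 2:1 and 4:1 ratios of clinical hardware decimate exactly; other rates
    are accepted with a warning.
    """
    if w.sampling_rate <= 0:
        raise ValueError(f"sampling_rate must be positive, got {w.sampling_rate}")
    if w.sampling_rate == TARGET_RATE_HZ:
        return w
    if w.sampling_rate not in STANDARD_RATES_HZ:
        logger.warning("non-standard sampling rate %s Hz; resampling anyway", w.sampling_rate)
    ratio = Fraction(int(round(TARGET_RATE_HZ)), int(round(w.sampling_rate))).limit_denominator(10_000)
    # beta=14 Kaiser: ~1e-7 passband ripple, so band-limited content survives
    samples = resample_poly(w.samples, ratio.numerator, ratio.denominator, window=("kaiser", 14.0))
    return w.replace_samples(samples, sampling_rate=TARGET_RATE_HZ)


def trim_window(w: Waveform, start_ms: float = TRIM_START_MS, end_ms: float = TRIM_END_MS) -> Waveform:
    """Keep samples with ``start_ms <= t < end_ms`` (drops the stimulation
    artefact edge and the post-F-wave tail).  Requires a 10 kHz trace covering
    the full window."""
    if w.sampling_rate != TARGET_RATE_HZ:
        raise ValueError(f"trim_window expects a 10 kHz trace, got {w.sampling_rate} Hz")
    fs_ms = w.sampling_rate / 1000.0
    i0 = round((start_ms - w.start_ms) * fs_ms)
    i1 = round((end_ms - w.start_ms) * fs_ms)
    if i1 > w.n_samples:
        raise ValueError(
            f"record covers only {w.start_ms + w.duration_ms:.1f} ms, "
            f"need at least {end_ms} ms to trim")
    if i0 < 0:
        raise ValueError(f"record starts at {w.start_ms} ms, after requested start {start_ms} ms")
    return w.replace_samples(w.samples[i0:i1], start_ms=start_ms)


def split_m_f(w: Waveform) -> SegmentPair:
    """Split a trimmed trace at the nerve's M/F boundary (20 ms for
    ulnar/median, 35 ms for fibular/tibial).  The two segments concatenate
    back to the input exactly."""
    if w.sampling_rate != TARGET_RATE_HZ:
        raise ValueError(f"split_m_f expects a 10 kHz trace, got {w.sampling_rate} Hz")
    cut_ms = SEGMENT_CUT_MS.get(Nerve(w.nerve))
    if cut_ms is None:
        raise ValueError(f"unknown nerve {w.nerve!r}")
    fs_ms = w.sampling_rate / 1000.0
    cut_idx = round((cut_ms - w.start_ms) * fs_ms)
    if not 0 < cut_idx < w.n_samples:
        raise ValueError(f"cut point {cut_ms} ms outside trace window")
    return SegmentPair(
        m_segment=w.replace_samples(w.samples[:cut_idx]),
        f_segment=w.replace_samples(w.samples[cut_idx:], start_ms=cut_ms),
        cut_ms=cut_ms,
    )


def preprocess(w: Waveform, start_ms: float = TRIM_START_MS, end_ms: float = TRIM_END_MS) -> Waveform:
    """Resample to 10 kHz then trim — the standard analysis representation."""
    return trim_window(resample_to_10khz(w), start_ms, end_ms)
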