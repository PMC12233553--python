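"""Wavelet-statistic feature engineering.

Each preprocessed trace is decomposed with a 4-level Daubechies-2 cascade
into five coefficient bands (cA4, cD4, cD3, cD2, cD1).  Ten statistics per
band plus the stimulus duration and amplitude give 52 stimulation-level
features; across-stimulation means and SDs per nerve give 416 session-level
values, and age, sex, BMI and recording source complete the 420-column model
table.  Nerves never stimulated in a session are *missing* (imputed later),
never zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pywt
from sklearn.impute import KNNImputer
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .preprocessing import preprocess, split_m_f
from .types import MARK_NAMES, NERVE_ORDER, Nerve, Session

logger = logging.getLogger(__name__)

__all__ = [
    "BANDS",
    "STAT_NAMES",
    "STIM_FEATURE_NAMES",
    "SESSION_FEATURE_COLUMNS",
    "DEMOGRAPHIC_COLUMNS",
    "WaveletDecomposition",
    "dwt_decompose",
    "band_statistics",
    "extract_stimulation_features",
    "aggregate_session",
    "sessions_to_table",
    "extract_annotation_features",
    "annotations_to_table",
    "TableTransform",
]

BANDS = ("cA4", "cD4", "cD3", "cD2", "cD1")
STAT_NAMES = ("mean", "var", "rms", "p5", "p95", "skew", "kurt", "crossings", "relpow", "entropy")
STIM_FEATURE_NAMES = tuple(f"{b}_{s}" for b in BANDS for s in STAT_NAMES) + ("stim_duration", "stim_amplitude")

DEMOGRAPHIC_COLUMNS = ("age", "sex", "bmi", "source")
SESSION_FEATURE_COLUMNS = tuple(
    f"{nerve.value}_{feat}_{agg}"
    for nerve in NERVE_ORDER
    for feat in STIM_FEATURE_NAMES
    for agg in ("mean", "sd")
) + DEMOGRAPHIC_COLUMNS

WAVELET = "db2"
DWT_LEVEL = 4
DWT_MODE = "symmetric"  # half-sample symmetric boundary extension


@dataclass
class WaveletDecomposition:
    """Ordered coefficient bands and their powers (sum of squared coeffs)."""

    bands: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if tuple(self.bands.keys()) != BANDS:
            raise ValueError(f"expected bands {BANDS}, got {tuple(self.bands)}")

    @property
    def band_powers(self) -> dict[str, float]:
        return {name: float(np.sum(c ** 2)) for name, c in self.bands.items()}


def dwt_decompose(samples: np.ndarray, *, mode: str = DWT_MODE) -> WaveletDecomposition:
    """4-level db2 discrete wavelet transform -> cA4, cD4, cD3, cD2, cD1."""
    x = np.asarray(samples, dtype=float)
    if x.size < 16:
        raise ValueError(f"need >= 16 samples for a {DWT_LEVEL}-level decomposition, got {x.size}")
    coeffs = pywt.wavedec(x, WAVELET, mode=mode, level=DWT_LEVEL)
    return WaveletDecomposition(bands=dict(zip(BANDS, coeffs)))


def _mean_crossings(x: np.ndarray, mu: float) -> int:
    """Sign changes of (x - mu); exact zeros inherit the previous sign."""
    d = x - mu
    s = np.sign(d)
    nz = s != 0
    if not nz.any():
        return 0
    idx = np.where(nz, np.arange(s.size), -1)
    np.maximum.accumulate(idx, out=idx)
    first = s[nz][0]
    filled = np.where(idx >= 0, s[np.maximum(idx, 0)], first)
    return int(np.count_nonzero(filled[1:] != filled[:-1]))


def band_statistics(decomp: WaveletDecomposition, band: str, *, rms_literal: bool = False) -> dict[str, float]:
    """Ten statistics for one band.

    Population (biased) moments throughout; kurtosis is excess; percentiles
    use linear interpolation; relative power ``r = p_band / sum(p)`` and
    spectral entropy ``-r ln r`` (both 0 when the trace has no power).
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}")
    x = decomp.bands[band]
    if x.size < 2:
        raise ValueError(f"band {band} has {x.size} coefficients; need >= 2")
    mu = float(np.mean(x))
    var = float(np.mean((x - mu) ** 2))
    ms = float(np.mean(x ** 2))
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(np.mean((x - mu) ** 3)) / sd ** 3
        kurt = float(np.mean((x - mu) ** 4)) / sd ** 4 - 3.0
    else:
        skew = kurt = 0.0
    total_power = sum(decomp.band_powers.values())
    r = decomp.band_powers[band] / total_power if total_power > 0 else 0.0
    entropy = -r * np.log(r) if r > 0 else 0.0
    return {
        "mean": mu,
        "var": var,
        "rms": ms if rms_literal else float(np.sqrt(ms)),
        "p5": float(np.percentile(x, 5)),
        "p95": float(np.percentile(x, 95)),
        "skew": skew,
        "kurt": kurt,
        "crossings": float(_mean_crossings(x, mu)),
        "relpow": r,
        "entropy": float(entropy),
    }


def extract_stimulation_features(samples: np.ndarray, stim_duration: float, stim_amplitude: float,
                                 *, rms_literal: bool = False, mode: str = DWT_MODE) -> np.ndarray:
    """52-value stimulation-level feature vector, in ``STIM_FEATURE_NAMES`` order."""
    decomp = dwt_decompose(samples, mode=mode)
    values = []
    for band in BANDS:
        stats = band_statistics(decomp, band, rms_literal=rms_literal)
        values.extend(stats[s] for s in STAT_NAMES)
    values.append(float(stim_duration))
    values.append(float(stim_amplitude))
    return np.asarray(values)


def aggregate_session(per_nerve: Mapping[Nerve, np.ndarray], demographics: Mapping[str, object]) -> pd.Series:
    """Session-level vector: per nerve per feature the across-stimulation mean
    and population SD (416 values), then age/sex/bmi/source (420 raw columns).

    ``per_nerve`` maps stimulated nerves to (n_stims, 52) arrays; unstimulated
    nerves become NaN.  A single-stimulation nerve gets SD 0 with a warning.
    """
    values: dict[str, object] = {}
    for nerve in NERVE_ORDER:
        feats = per_nerve.get(nerve)
        if feats is None:
            for feat in STIM_FEATURE_NAMES:
                values[f"{nerve.value}_{feat}_mean"] = np.nan
                values[f"{nerve.value}_{feat}_sd"] = np.nan
            continue
        feats = np.atleast_2d(np.asarray(feats, dtype=float))
        if feats.shape[1] != len(STIM_FEATURE_NAMES):
            raise ValueError(f"expected {len(STIM_FEATURE_NAMES)} features per stimulation, got {feats.shape[1]}")
        if feats.shape[0] == 1:
            warnings.warn(f"nerve {nerve.value}: single stimulation, SD set to 0", stacklevel=2)
        means = feats.mean(axis=0)
        sds = feats.std(axis=0)  # population SD; 0 when n == 1
        for j, feat in enumerate(STIM_FEATURE_NAMES):
            values[f"{nerve.value}_{feat}_mean"] = means[j]
            values[f"{nerve.value}_{feat}_sd"] = sds[j]
    for col in DEMOGRAPHIC_COLUMNS:
        values[col] = demographics[col]
    return pd.Series(values).reindex(list(SESSION_FEATURE_COLUMNS))


def _session_demographics(session: Session) -> dict[str, object]:
    return {"age": session.age, "sex": session.sex, "bmi": session.bmi, "source": session.source}


def sessions_to_table(sessions: Sequence[Session], variant: str = "full",
                      *, rms_literal: bool = False) -> pd.DataFrame:
    """Feature table (one row per session) for a waveform ``variant``.

    ``full`` uses the whole trimmed trace, ``m_only``/``f_only`` the segment
    before/after the nerve's cut point, ``no_wave`` demographics only.
    """
    if variant not in {"full", "m_only", "f_only", "no_wave"}:
        raise ValueError(f"unknown variant {variant!r}")
    rows, labels, index = [], [], []
    for session in sessions:
        if variant == "no_wave":
            row = pd.Series(_session_demographics(session)).reindex(list(DEMOGRAPHIC_COLUMNS))
        else:
            per_nerve = {}
            for nerve, wfs in session.waveforms.items():
                feats = []
                for wf in wfs:
                    trimmed = preprocess(wf)
                    if variant == "m_only":
                        trimmed = split_m_f(trimmed).m_segment
                    elif variant == "f_only":
                        trimmed = split_m_f(trimmed).f_segment
                    feats.append(extract_stimulation_features(
                        trimmed.samples, wf.stim_duration, wf.stim_amplitude, rms_literal=rms_literal))
                per_nerve[nerve] = np.vstack(feats)
            row = aggregate_session(per_nerve, _session_demographics(session))
        rows.append(row)
        labels.append(session.label)
        index.append(session.session_id)
    table = pd.DataFrame(rows, index=pd.Index(index, name="session_id"))
    table["label"] = labels
    return table


# ----------------------------------------------------------------------
# annotation (clinical-mark) comparator features
# ----------------------------------------------------------------------

def extract_annotation_features(session: Session) -> pd.Series:
    """Per-nerve mean/SD of the 8 clinical marks' latencies and amplitudes.

    F marks on stimulations without an F-wave are missing and excluded from
    the aggregation; a nerve with no F-waves at all yields missing F columns.
    """
    values: dict[str, float] = {}
    for nerve in NERVE_ORDER:
        anns = session.annotations.get(nerve)
        for mark in MARK_NAMES:
            for kind in ("latency", "amplitude"):
                for agg in ("mean", "sd"):
                    values[f"{nerve.value}_{mark}_{kind}_{agg}"] = np.nan
        if not anns:
            continue
        for mark in MARK_NAMES:
            pairs = [getattr(a, mark) for a in anns if getattr(a, mark) is not None]
            if not pairs:
                continue
            lat = np.array([p[0] for p in pairs])
            amp = np.array([p[1] for p in pairs])
            values[f"{nerve.value}_{mark}_latency_mean"] = float(lat.mean())
            values[f"{nerve.value}_{mark}_latency_sd"] = float(lat.std())
            values[f"{nerve.value}_{mark}_amplitude_mean"] = float(amp.mean())
            values[f"{nerve.value}_{mark}_amplitude_sd"] = float(amp.std())
    out = pd.Series(values)
    for col in DEMOGRAPHIC_COLUMNS:
        out[col] = _session_demographics(session)[col]
    return out


def annotations_to_table(sessions: Sequence[Session]) -> pd.DataFrame:
    rows = [extract_annotation_features(s) for s in sessions]
    table = pd.DataFrame(rows, index=pd.Index([s.session_id for s in sessions], name="session_id"))
    table["label"] = [s.label for s in sessions]
    return table


# ----------------------------------------------------------------------
# model-table transform: KNN imputation + scaling + one-hot encoding
# ----------------------------------------------------------------------

@dataclass
class TableTransform:
    """Frozen preprocessing fitted on training rows only.

    Numeric columns: KNN imputation (k=10, distances over mutually observed
    features) followed by standardization.  Categorical columns: one-hot.
    """

    n_neighbors: int = 10
    categorical_columns: tuple[str, ...] = ("sex", "source")
    numeric_columns_: list[str] = field(default_factory=list)
    imputer_: Optional[KNNImputer] = None
    scaler_: Optional[StandardScaler] = None
    encoder_: Optional[OneHotEncoder] = None
    feature_names_: list[str] = field(default_factory=list)

    def fit(self, table: pd.DataFrame) -> "TableTransform":
        table = table.drop(columns=["label"], errors="ignore")
        if len(table) < self.n_neighbors + 1:
            raise ValueError(
                f"need more than n_neighbors={self.n_neighbors} training rows, got {len(table)}")
        cats = [c for c in self.categorical_columns if c in table.columns]
        self.numeric_columns_ = [c for c in table.columns if c not in cats]
        self.imputer_ = KNNImputer(n_neighbors=self.n_neighbors)
        imputed = self.imputer_.fit_transform(table[self.numeric_columns_].to_numpy(dtype=float))
        self.scaler_ = StandardScaler().fit(imputed)
        self.feature_names_ = list(self.numeric_columns_)
        if cats:
            self.encoder_ = OneHotEncoder(sparse_output=False, handle_unknown="ignore")
            self.encoder_.fit(table[cats].to_numpy(dtype=object))
            self.feature_names_ += list(self.encoder_.get_feature_names_out(cats))
        else:
            self.encoder_ = None
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.imputer_ is None:
            raise RuntimeError("TableTransform is not fitted")
        table = table.drop(columns=["label"], errors="ignore")
        missing = [c for c in self.numeric_columns_ if c not in table.columns]
        if self.encoder_ is not None:
            missing += [c for c in self.categorical_columns if c not in table.columns]
        if missing:
            raise ValueError(f"table is missing columns: {missing}")
        blocks = [self.scaler_.transform(
            self.imputer_.transform(table[self.numeric_columns_].to_numpy(dtype=float)))]
        if self.encoder_ is not None:
            blocks.append(self.encoder_.transform(
                table[list(self.categorical_columns)].to_numpy(dtype=object)))
        out = np.hstack(blocks)
        return pd.DataFrame(out, index=table.index, columns=self.feature_names_)

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)
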