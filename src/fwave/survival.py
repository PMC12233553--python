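"""Cox proportional-hazards survival analysis of ALS risk factors.

Covariates follow the clinical convention: sex, onset site, family history
(one-hot with fixed reference levels), and diagnostic delay, age at onset,
BMI and the classifier's log-odds model score (standard scaled).  The fit
uses the partial likelihood with Efron tie handling; per-covariate Wald
tests flag significant hazards, and partial-effect survival curves show the
fitted model at a covariate held 2 SD below / at / above its mean with all
other covariates at their means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .types import SurvivalRecord

__all__ = [
    "NUMERIC_COVARIATES",
    "CATEGORICAL_COVARIATES",
    "REFERENCE_LEVELS",
    "CPHFit",
    "records_to_frame",
    "fit_cph",
    "partial_effect_curves",
    "tabulate_hazards",
]

NUMERIC_COVARIATES = ("diagnostic_delay", "age_at_onset", "bmi", "model_score")
CATEGORICAL_COVARIATES = ("sex", "onset_site", "family_history")
#: reference levels absorbed into the baseline hazard
REFERENCE_LEVELS = {"sex": "female", "onset_site": "lower_limb", "family_history": "none"}


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "duration": r.duration, "event": r.event, "sex": r.sex,
        "onset_site": r.onset_site, "family_history": r.family_history,
        "diagnostic_delay": r.diagnostic_delay, "age_at_onset": r.age_at_onset,
        "bmi": r.bmi, "model_score": r.model_score,
    } for r in records])


@dataclass
class CPHFit:
    """Fitted model plus the frozen scaling/encoding metadata."""

    fitter: CoxPHFitter
    design_columns: list[str]
    numeric_means: dict[str, float]
    numeric_sds: dict[str, float]
    reference_levels: dict[str, str]
    design_: pd.DataFrame = field(repr=False, default=None)

    @property
    def summary(self) -> pd.DataFrame:
        return self.fitter.summary


def _build_design(df: pd.DataFrame, means: dict, sds: dict, reference: dict) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for col in NUMERIC_COVARIATES:
        X[col] = (df[col] - means[col]) / sds[col]
    for col in CATEGORICAL_COVARIATES:
        levels = [l for l in sorted(df[col].unique()) if l != reference[col]]
        for level in levels:
            X[f"{col}={level}"] = (df[col] == level).astype(float)
    return X


def fit_cph(records: Sequence[SurvivalRecord], *,
            reference_levels: Optional[dict] = None) -> CPHFit:
    """Partial-likelihood CPH fit (Efron ties) with Wald tests per covariate."""
    reference = dict(REFERENCE_LEVELS if reference_levels is None else reference_levels)
    df = records_to_frame(records)
    if df["event"].sum() == 0:
        raise ValueError("no events observed; cannot fit a proportional-hazards model")
    means = {c: float(df[c].mean()) for c in NUMERIC_COVARIATES}
    sds = {c: float(df[c].std(ddof=0)) for c in NUMERIC_COVARIATES}
    for c, s in sds.items():
        if s == 0:
            raise ValueError(f"covariate {c} is constant")
    X = _build_design(df, means, sds, reference)
    # a level identical to another column (perfect collinearity) breaks the fit
    design = X.copy()
    design["duration"] = df["duration"].to_numpy()
    design["event"] = df["event"].astype(int).to_numpy()
    fitter = CoxPHFitter()
    fitter.fit(design, duration_col="duration", event_col="event")
    return CPHFit(fitter=fitter, design_columns=list(X.columns),
                  numeric_means=means, numeric_sds=sds,
                  reference_levels=reference, design_=design)


def partial_effect_curves(fit: CPHFit, covariate: str,
                          offsets: Sequence[float] = (-2.0, 0.0, 2.0)) -> dict:
    """Survival curves with ``covariate`` at mean + offset·SD, all other
    covariates held at their means.

    Offsets are in SD units of the covariate (the design is standard scaled).
    Median survival is the earliest time with S(t) <= 0.5, or ``None``
    (reported as not reached) if S never falls that far.
    """
    if covariate not in NUMERIC_COVARIATES:
        raise ValueError(f"unknown numeric covariate {covariate!r}; "
                         f"expected one of {NUMERIC_COVARIATES}")
    base = fit.design_[fit.design_columns].mean()
    rows = []
    for off in offsets:
        row = base.copy()
        row[covariate] = base[covariate] + float(off)
        rows.append(row)
    profile = pd.DataFrame(rows, index=[f"{off:+g} SD" for off in offsets])
    sf = fit.fitter.predict_survival_function(profile)
    out = {"covariate": covariate, "offsets": list(offsets), "curves": {}, "median_survival": {}}
    times = sf.index.to_numpy(dtype=float)
    for off, col in zip(offsets, sf.columns):
        surv = sf[col].to_numpy(dtype=float)
        below = np.nonzero(surv <= 0.5)[0]
        median = float(times[below[0]]) if below.size else None
        key = f"{off:+g}sd"
        out["curves"][key] = {"times": times.tolist(), "survival": surv.tolist()}
        out["median_survival"][key] = median
    return out


def tabulate_hazards(fit: CPHFit, alpha: float = 0.05) -> pd.DataFrame:
    """Report table: coefficient, hazard ratio, 95% CI, Wald p, significance."""
    s = fit.fitter.summary
    table = pd.DataFrame({
        "covariate": s.index,
        "coef": s["coef"].to_numpy(),
        "hazard_ratio": np.exp(s["coef"].to_numpy()),
        "ci_lower": np.exp(s["coef lower 95%"].to_numpy()),
        "ci_upper": np.exp(s["coef upper 95%"].to_numpy()),
        "p": s["p"].to_numpy(),
    }).reset_index(drop=True)
    table["significant"] = table["p"] < alpha
    return table
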