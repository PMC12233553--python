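"""Group-level statistics on model scores and bootstrapped metrics.

Diagnosis groups (ALS, controls and the clinical mimics) are compared on
their log-odds model-score distributions with one-way ANOVA plus Tukey HSD
post hoc tests; bootstrapped metric distributions from two models are
compared with a Welch t-test (flagged, since bootstrap replicates are not
independent observations); and per-group classification rates report, with
exact counts, how often each group falls on its correct side of the
decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .model import prob_to_score

__all__ = [
    "GroupComparison",
    "anova_tukey",
    "compare_bootstrap_distributions",
    "group_classification_rates",
]


@dataclass
class GroupComparison:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj, reject
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def anova_tukey(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA omnibus test plus all-pairs Tukey HSD on model scores."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, values in groups.items():
        if len(values) < 3:
            raise ValueError(f"group {name!r} has {len(values)} values; need >= 3")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    f_stat, p = stats.f_oneway(*arrays.values())
    data = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    hsd = pairwise_tukeyhsd(data, labels, alpha=alpha)
    frame = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    tukey = pd.DataFrame({
        "group1": frame["group1"], "group2": frame["group2"],
        "mean_diff": hsd.meandiffs, "p_adj": hsd.pvalues, "reject": hsd.reject,
    })
    return GroupComparison(f_statistic=float(f_stat), p_value=float(p), tukey=tukey, alpha=alpha)


def compare_bootstrap_distributions(metric_a: Sequence[float], metric_b: Sequence[float]) -> dict:
    """Welch t-test between two bootstrap metric vectors.

    The returned ``dependent_replicates`` flag is a standing caveat: bootstrap
    replicates re-use the same underlying predictions, so the nominal p-value
    overstates the evidence.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.size < 30 or b.size < 30:
        raise ValueError("need >= 30 bootstrap replicates per model")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p), "dependent_replicates": True}


def group_classification_rates(scores_by_group: Mapping[str, Sequence[float]], theta: float = 0.12,
                               positive_group: str = "als",
                               scores_are_log_odds: bool = True) -> pd.DataFrame:
    """Fraction of each group classified on its correct side of ``theta``.

    ``theta`` is a probability threshold; log-odds scores are compared
    against ``ln(theta / (1 - theta))``.  The positive group's rate counts
    scores at or above threshold (classified ALS); every other group's rate
    counts scores below it (classified not-ALS).  Counts are exact integers.
    """
    cut = float(prob_to_score(theta)) if scores_are_log_odds else float(theta)
    rows = []
    for group, values in scores_by_group.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {group!r} is empty")
        n_pos = int(np.sum(v >= cut))
        if group == positive_group:
            correct, description = n_pos, "classified_als"
        else:
            correct, description = v.size - n_pos, "classified_not_als"
        rows.append({
            "group": group, "n": int(v.size), "n_correct": correct,
            "rate": correct / v.size, "percent": 100.0 * correct / v.size,
            "criterion": description, "threshold_prob": float(theta),
        })
    return pd.DataFrame(rows)
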