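"""End-to-end orchestration: simulate -> featurize -> train -> evaluate ->
survival -> group statistics, driven by one structured config.

Every tunable that the package's design leaves open (atom shapes aside,
which are fixed) appears in :data:`DEFAULT_CONFIG` with its default.  One
global seed fans out to per-stage child seeds by stable hashing of stage
names, so a stage re-run in isolation reproduces its in-pipeline output.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import joblib
import numpy as np
import yaml

from . import __version__
from .features import sessions_to_table
from .group_stats import anova_tukey, group_classification_rates
from .io import read_cohort, read_survival, write_cohort
from .model import bootstrap_metrics, predict, train_classifier
from .survival import fit_cph, partial_effect_curves, tabulate_hazards
from .synthetic import (CohortSpec, PRESETS, SurvivalGenSpec, generate_cohort,
                        generate_session, generate_survival_records, percentile_sampler,
                        DEFAULT_AGE_TRIPLES, DEFAULT_BMI_TRIPLES, DEFAULT_FEMALE_FRACTION)
from .types import Session

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "derive_seed", "run_pipeline", "make_fixtures"]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "runs/fwave",
    "log_level": "INFO",
    "simulate": {
        "enabled": True,
        "n_per_group": 25,
        "groups": ["als", "control"],
        "noise_sd": 0.02,
        "stimulations_per_nerve": [5, 8],
        "sex_fraction_female": DEFAULT_FEMALE_FRACTION,
        "age_triples": {k: list(v) for k, v in DEFAULT_AGE_TRIPLES.items()},
        "bmi_triples": {k: list(v) for k, v in DEFAULT_BMI_TRIPLES.items()},
        # ALS / mimic preset effect sizes (qualitative clinical signatures)
        "presets": {
            label: {
                "f_persistence": p.f_persistence,
                "chronodispersion_sd": p.chronodispersion_sd,
                "m_amplitude_scale": p.m_amplitude_scale,
                "f_amplitude_scale": p.f_amplitude_scale,
                "latency_shift": p.latency_shift,
            } for label, p in PRESETS.items()
        },
    },
    "preprocess": {
        "trim_start_ms": 2.5,
        "trim_end_ms": 300.0,
        "resample_method": "polyphase",
        "warn_nonstandard_rates": True,
    },
    "features": {
        "rms_literal": False,       # printed formula omits the square root
        "dwt_mode": "symmetric",    # half-sample symmetric boundary extension
        "knn_neighbors": 10,
    },
    "model": {
        "folds": 5,
        "test_fraction": 0.3,
        "threshold": "prevalence",  # or a number in (0, 1); 0.5 for mimics
        "bootstrap_reps": 1000,
        "prob_clip": 1e-9,
        "importance_backend": "shap",  # or "permutation"
        "grid": [
            {"learning_rate": 0.05, "num_leaves": 15},
            {"learning_rate": 0.1, "num_leaves": 15},
            {"learning_rate": 0.05, "num_leaves": 31},
            {"learning_rate": 0.1, "num_leaves": 31},
        ],
    },
    "survival": {
        "enabled": True,
        "n": 400,
        "true_betas": {"model_score": 0.3, "age_at_onset": 0.3, "diagnostic_delay": -0.3,
                       "family_history=als": 0.4, "onset_site=upper_limb": -0.3},
        "baseline_shape": 1.2,
        "baseline_scale": 36.0,
        "censor_fraction": 0.3,
        "ties": "efron",
        "reference_levels": {"sex": "female", "onset_site": "lower_limb", "family_history": "none"},
        "partial_effect_covariates": ["model_score", "age_at_onset", "diagnostic_delay"],
    },
    "groupstats": {
        "enabled": True,
        "alpha": 0.05,
        "theta": 0.12,
        "theta_mimics": 0.5,
    },
}


def _deep_update(base: dict, overrides: Mapping) -> dict:
    for key, value in overrides.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = copy.deepcopy(value)
    return base


def load_config(path: Optional[str | Path] = None, overrides: Optional[Mapping] = None) -> dict:
    """Defaults, optionally updated from a YAML file and an override mapping."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        _deep_update(config, loaded)
    if overrides:
        _deep_update(config, overrides)
    for section in ("simulate", "preprocess", "features", "model", "survival", "groupstats"):
        if section not in config:
            raise ValueError(f"config is missing required section {section!r}")
    return config


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2^31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _cohort_spec(config: dict, seed: int) -> CohortSpec:
    sim = config["simulate"]
    presets = []
    for label in sim["groups"]:
        base = PRESETS[label]
        tuned = sim.get("presets", {}).get(label, {})
        presets.append(type(base)(label=label, affected_nerves=base.affected_nerves,
                                  **{k: tuned.get(k, getattr(base, k))
                                     for k in ("f_persistence", "chronodispersion_sd",
                                               "m_amplitude_scale", "f_amplitude_scale",
                                               "latency_shift")}))
    age_triples = {k: tuple(v) for k, v in sim["age_triples"].items()}
    bmi_triples = {k: tuple(v) for k, v in sim["bmi_triples"].items()}
    for p in presets:  # groups without published triples fall back to control's
        age_triples.setdefault(p.label, tuple(sim["age_triples"]["control"]))
        bmi_triples.setdefault(p.label, tuple(sim["bmi_triples"]["control"]))
    return CohortSpec(
        n_per_group=sim["n_per_group"], group_presets=presets,
        age_triples=age_triples, bmi_triples=bmi_triples,
        sex_fraction_female=sim["sex_fraction_female"],
        stimulations_per_nerve=tuple(sim["stimulations_per_nerve"]),
        noise_sd=sim["noise_sd"], seed=seed)


def run_pipeline(config: dict, cohort_dir: Optional[str | Path] = None) -> Path:
    """Execute all stages, writing artifacts and a checksum manifest.

    With ``simulate.enabled`` false, ``cohort_dir`` (or ``<out_dir>/cohort``)
    must already hold a cohort archive; downstream stages are unchanged.
    """
    for section in ("simulate", "preprocess", "features", "model", "survival", "groupstats"):
        if section not in config:
            raise ValueError(f"config is missing required section {section!r}")
    logging.basicConfig(level=config.get("log_level", "INFO"))
    seed = int(config["seed"])
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    # --- simulate ------------------------------------------------------
    cohort_path = Path(cohort_dir) if cohort_dir is not None else out / "cohort"
    surv_cfg = config["survival"]
    if config["simulate"]["enabled"]:
        spec = _cohort_spec(config, derive_seed(seed, "simulate"))
        sessions = generate_cohort(spec)
        records = None
        if surv_cfg["enabled"]:
            records = generate_survival_records(SurvivalGenSpec(
                n=surv_cfg["n"], true_betas=surv_cfg["true_betas"],
                baseline_shape=surv_cfg["baseline_shape"], baseline_scale=surv_cfg["baseline_scale"],
                censor_fraction=surv_cfg["censor_fraction"], seed=derive_seed(seed, "survival_gen")))
        write_cohort(sessions, cohort_path, survival=records)
        logger.info("simulate: %d sessions -> %s", len(sessions), cohort_path)
    else:
        sessions = read_cohort(cohort_path)
        logger.info("simulate skipped: read %d sessions from %s", len(sessions), cohort_path)
    for name in ("waveforms.csv", "sessions.csv", "annotations.csv", "survival.csv"):
        p = cohort_path / name
        if p.exists():
            artifacts.append(p)

    # --- featurize -----------------------------------------------------
    table = sessions_to_table(sessions, variant="full",
                              rms_literal=config["features"]["rms_literal"])
    features_path = out / "features.csv"
    table.to_csv(features_path, float_format="%.10g")
    artifacts.append(features_path)
    logger.info("featurize: %d sessions x %d columns", *table.shape)

    # --- train ---------------------------------------------------------
    mdl = config["model"]
    labels = table["label"].to_numpy()
    feat = table.drop(columns=["label"])
    from sklearn.model_selection import train_test_split
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(idx, test_size=mdl["test_fraction"],
                                           random_state=derive_seed(seed, "split"),
                                           stratify=labels)
    threshold = None if mdl["threshold"] == "prevalence" else float(mdl["threshold"])
    bundle = train_classifier(
        feat.iloc[train_idx], labels[train_idx], folds=mdl["folds"],
        seed=derive_seed(seed, "train"), grid=mdl["grid"], threshold=threshold,
        n_neighbors=min(config["features"]["knn_neighbors"], len(train_idx) - 1))
    bundle_dir = out / "bundle"
    bundle_dir.mkdir(exist_ok=True)
    (bundle_dir / "model.txt").write_text(bundle.model.booster_.model_to_string())
    joblib.dump(bundle, bundle_dir / "bundle.joblib")
    _write_json({"feature_order": bundle.feature_names, "cv_pr_auc": bundle.cv_pr_auc,
                 "best_params": bundle.best_params, "threshold": bundle.threshold,
                 "folds": bundle.folds, "seed": bundle.seed},
                bundle_dir / "manifest.json")
    artifacts += [bundle_dir / "model.txt", bundle_dir / "manifest.json"]
    logger.info("train: cv PR-AUC %.3f, threshold %.3f", bundle.cv_pr_auc, bundle.threshold)

    # --- evaluate ------------------------------------------------------
    preds = predict(bundle, feat.iloc[test_idx])
    probs = np.array([p.prob_als for p in preds])
    y_test = (labels[test_idx] == bundle.positive_label).astype(int)
    report = bootstrap_metrics(probs, y_test, bundle.threshold,
                               B=mdl["bootstrap_reps"], seed=derive_seed(seed, "bootstrap"))
    report_path = out / "report.json"
    _write_json({"metrics": report.as_dict(), "seed": seed,
                 "n_train": len(train_idx), "n_test": len(test_idx)}, report_path)
    artifacts.append(report_path)

    # --- survival ------------------------------------------------------
    if surv_cfg["enabled"] and (cohort_path / "survival.csv").exists():
        records = read_survival(cohort_path / "survival.csv")
        fit = fit_cph(records, reference_levels=surv_cfg["reference_levels"])
        surv_out = {"hazards": tabulate_hazards(fit).to_dict(orient="records"),
                    "reference_levels": fit.reference_levels, "partial_effects": {}}
        for cov in surv_cfg["partial_effect_covariates"]:
            surv_out["partial_effects"][cov] = partial_effect_curves(fit, cov)
        surv_path = out / "surv_report.json"
        _write_json(surv_out, surv_path)
        artifacts.append(surv_path)
        logger.info("survival: %d records, %d events", len(records),
                    sum(r.event for r in records))

    # --- groupstats ----------------------------------------------------
    gs = config["groupstats"]
    if gs["enabled"]:
        scores_by_group: dict[str, list[float]] = {}
        for i, p in zip(test_idx, preds):
            scores_by_group.setdefault(labels[i], []).append(p.score)
        groups_out: dict = {"theta": gs["theta"]}
        if len(scores_by_group) >= 2 and min(len(v) for v in scores_by_group.values()) >= 3:
            comparison = anova_tukey(scores_by_group, alpha=gs["alpha"])
            groups_out["anova"] = {"f": comparison.f_statistic, "p": comparison.p_value}
            groups_out["tukey"] = comparison.tukey.to_dict(orient="records")
        rates = group_classification_rates(scores_by_group, theta=gs["theta"])
        groups_out["rates"] = rates.to_dict(orient="records")
        groups_path = out / "groups_report.json"
        _write_json(groups_out, groups_path)
        artifacts.append(groups_path)

    # --- manifest ------------------------------------------------------
    hashable = {k: v for k, v in config.items() if k != "out_dir"}
    config_hash = hashlib.sha256(
        json.dumps(hashable, sort_keys=True, default=_json_default).encode()).hexdigest()
    manifest = {
        "config_hash": config_hash,
        "seed": seed,
        "version": __version__,
        "checksums": {str(p.relative_to(out.parent) if p.is_relative_to(out.parent) else p): _sha256(p)
                      for p in artifacts},
    }
    _write_json(manifest, out / "manifest.json")
    return out


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------

#: fixed fixture protocols: cover all four nerves and missing-nerve sessions
_FIXTURE_PROTOCOLS = (
    ("ulnar", "median", "fibular", "tibial"),
    ("fibular", "tibial"),
    ("ulnar", "median"),
    ("ulnar", "fibular", "tibial"),
    ("tibial",),
    ("ulnar", "median", "fibular", "tibial"),
)


def make_fixtures(seed: int = 0, out_dir: Optional[str | Path] = None,
                  n_per_group: int = 6) -> list[Session]:
    """Deterministic miniature cohort (<= 40 sessions) for tests.

    By construction it covers all four nerves, both labels and at least one
    missing-nerve session, for any seed.  With ``out_dir`` the cohort archive
    (plus a small survival table) is written there.
    """
    if n_per_group * 2 > 40:
        raise ValueError("fixture cohort must stay at or under 40 sessions")
    rng = np.random.default_rng(seed)
    sessions: list[Session] = []
    pid = 0
    for label in ("als", "control"):
        preset = PRESETS[label]
        age_draw = percentile_sampler(*DEFAULT_AGE_TRIPLES[label])
        bmi_draw = percentile_sampler(*DEFAULT_BMI_TRIPLES[label])
        for i in range(n_per_group):
            pid += 1
            demo = dict(patient_id=f"P{pid:05d}", session_id=f"S{pid:05d}",
                        age=float(np.clip(age_draw(rng, 1)[0], 18, 100)),
                        sex="female" if rng.random() < DEFAULT_FEMALE_FRACTION else "male",
                        bmi=float(np.clip(bmi_draw(rng, 1)[0], 13, 60)),
                        source="natus" if rng.random() < 0.5 else "cadwell")
            protocol = dict(nerves=list(_FIXTURE_PROTOCOLS[i % len(_FIXTURE_PROTOCOLS)]),
                            stimulations_per_nerve=5 + (i % 4))
            sessions.append(generate_session(preset, demo, protocol, rng))
    if out_dir is not None:
        records = generate_survival_records(SurvivalGenSpec(
            n=40, true_betas={"model_score": 0.3}, censor_fraction=0.3,
            seed=derive_seed(seed, "fixture_survival")))
        write_cohort(sessions, out_dir, survival=records)
    return sessions
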