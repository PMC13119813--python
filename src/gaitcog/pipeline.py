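"""End-to-end pipeline: simulate -> extract -> assemble -> screen ->
model -> network -> classify, as a configurable, logged, seeded run.

Every artifact is a deterministic function of the resolved
configuration and the master seed: per-stage seeds are derived by
hashing the stage name with the master seed, timestamps are never
written, and JSON output is key-sorted, so two runs with the same
configuration produce byte-identical artifact trees.

The analysis table consumed by screening and classification comes from
the tabular cohort generator (which plants the couplings directly at
the participant level); the raw-signal path (IMU + marker trials ->
feature extraction) is exercised by the optional ``features`` stage on
a configurable number of participants and written as an audit artifact,
since extracting all 108 recordings for every participant is an
expensive validation exercise rather than a prerequisite for the
statistical stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, schema
from ._utils import derive_seed
from .classify import MODEL_FAMILIES, CvConfig, ModelSpec, nested_cv
from .cohort import CohortTable, ImputationSpec, exclude_cognitive, knn_impute, zscore
from .features import (
    FilterSpec,
    CycleDetectionError,
    detect_gait_cycles,
    extract_spatiotemporal,
    extract_wearable_features,
)
from .network import fit_glasso_network, layout_network
from .screen import COVARIATES, compare_groups, screen_cascade
from .simulate import (
    CohortSpec,
    LatentProfile,
    SignalSpec,
    generate_cohort,
    generate_imu_trials,
    generate_mocap_trial,
)
from .stepwise import stepwise_fit

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config", "extract_participant_features"]

STAGES = ("simulate", "features", "screen", "model", "network", "classify")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/default"
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True,
            "features": False,
            "screen": True,
            "model": True,
            "network": True,
            "classify": True,
        }
    )
    cohort: CohortSpec = field(default_factory=CohortSpec)
    signal: SignalSpec = field(default_factory=SignalSpec)
    filter: FilterSpec = field(default_factory=FilterSpec)
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    cv: CvConfig = field(default_factory=CvConfig)
    configurations: tuple[str, ...] = ("clinical_only", "gait_only", "combined")
    families: tuple[str, ...] = MODEL_FAMILIES
    features_n_participants: int = 2
    log_level: str = "INFO"

    def resolved_cohort(self) -> CohortSpec:
        return dataclasses.replace(self.cohort, seed=derive_seed(self.seed, "simulate"))

    def to_dict(self) -> dict:
        def as_plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: as_plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: as_plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [as_plain(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return as_plain(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file plus keyword overrides."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})

    def build(cls, key):
        section = raw.get(key, {}) or {}
        if isinstance(section, cls):
            return section
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - fields
        if unknown:
            raise ValueError(f"unknown keys in config section {key!r}: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in section and isinstance(section[f.name], list):
                section[f.name] = tuple(section[f.name])
        return cls(**section)

    stages = dict(RunConfig().stages)
    stages.update(raw.get("stages", {}) or {})
    unknown_stages = set(stages) - set(STAGES)
    if unknown_stages:
        raise ValueError(f"unknown stages: {sorted(unknown_stages)}")
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "runs/default")),
        stages=stages,
        cohort=build(CohortSpec, "cohort"),
        signal=build(SignalSpec, "signal"),
        filter=build(FilterSpec, "filter"),
        imputation=build(ImputationSpec, "imputation"),
        cv=build(CvConfig, "cv"),
        configurations=tuple(raw.get("configurations", RunConfig().configurations)),
        families=tuple(raw.get("families", MODEL_FAMILIES)),
        features_n_participants=int(raw.get("features_n_participants", 2)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, sort_keys=True, indent=2, allow_nan=True) + "\n")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name}, but the upstream stage that "
            f"produces it is disabled and no cached copy exists at {path}"
        )
    return path


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, out: Path) -> None:
    cohort, profiles = generate_cohort(config.resolved_cohort())
    d = out / "cohort"
    d.mkdir(parents=True, exist_ok=True)
    table = cohort.data.copy()
    table["moca_adjusted"] = cohort.outcome
    table["label"] = cohort.label
    table.to_csv(d / "cohort.csv")
    if cohort.mask is not None:
        cohort.mask.astype(int).to_csv(d / "mask.csv")
    rows = []
    for p in profiles:
        rows.append(
            {
                "participant_id": p.participant_id,
                "latent_motor_severity": p.latent_motor_severity,
                "latent_cognition": p.latent_cognition,
                "more_affected_side": p.more_affected_side,
                "stride_frequency": p.stride_frequency,
                "stride_length_more": p.stride_length_true["more"],
                "stride_length_less": p.stride_length_true["less"],
                "jerk_scale_true": p.jerk_scale_true,
                "seed": p.seed,
            }
        )
    pd.DataFrame(rows).set_index("participant_id").to_csv(d / "profiles.csv")


def load_cohort(out: Path) -> CohortTable:
    path = out / "cohort" / "cohort.csv"
    table = pd.read_csv(path, index_col=0)
    outcome = table.pop("moca_adjusted").astype(int)
    label = table.pop("label")
    mask_path = out / "cohort" / "mask.csv"
    mask = (
        pd.read_csv(mask_path, index_col=0).astype(bool) if mask_path.exists() else None
    )
    return CohortTable(data=table, mask=mask, outcome=outcome, label=label)


def load_profiles(out: Path) -> list[LatentProfile]:
    frame = pd.read_csv(out / "cohort" / "profiles.csv", index_col=0)
    profiles = []
    for pid, row in frame.iterrows():
        profiles.append(
            LatentProfile(
                participant_id=str(pid),
                latent_motor_severity=float(row["latent_motor_severity"]),
                latent_cognition=float(row["latent_cognition"]),
                more_affected_side=str(row["more_affected_side"]),
                stride_frequency=float(row["stride_frequency"]),
                stride_length_true={
                    "more": float(row["stride_length_more"]),
                    "less": float(row["stride_length_less"]),
                },
                jerk_scale_true=float(row["jerk_scale_true"]),
                seed=int(row["seed"]),
            )
        )
    return profiles


def extract_participant_features(
    profile: LatentProfile,
    signal_spec: SignalSpec,
    filter_spec: FilterSpec = FilterSpec(),
) -> pd.DataFrame:
    """Raw-signal path for one participant: generate every trial,
    detect cycles on the more-affected ankle sensor, and extract the
    wearable and spatiotemporal features.  Returns a long-format frame
    (participant, source, placement, task, repeat, feature, value)."""
    trials = generate_imu_trials(profile, signal_spec)
    by_key = {(t.placement, t.task, t.repeat_index): t for t in trials}
    rows = []
    for task in schema.TASKS:
        for rep in range(signal_spec.n_repeats):
            try:
                events = detect_gait_cycles(by_key[("MANK", task, rep)], filter_spec)
            except CycleDetectionError as exc:
                log.warning(
                    "participant %s %s repeat %d excluded: %s",
                    profile.participant_id,
                    task,
                    rep,
                    exc,
                )
                continue
            for placement in schema.PLACEMENTS:
                feats = extract_wearable_features(
                    by_key[(placement, task, rep)], events, filter_spec=filter_spec
                )
                for name, value in feats.as_dict().items():
                    rows.append(
                        {
                            "participant": profile.participant_id,
                            "source": "wearable",
                            "placement": placement,
                            "task": task,
                            "repeat": rep,
                            "feature": f"{task}_{placement}_{name}",
                            "value": value,
                        }
                    )
            st = extract_spatiotemporal(
                generate_mocap_trial(profile, signal_spec, task=task, repeat_index=rep)
            )
            for name, value in st.as_dict().items():
                if name in ("CoordMALA", "CoordLAMA") and task != "FW":
                    continue
                rows.append(
                    {
                        "participant": profile.participant_id,
                        "source": "mocap",
                        "placement": "",
                        "task": task,
                        "repeat": rep,
                        "feature": f"{task}_{name}",
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def _stage_features(config: RunConfig, out: Path) -> None:
    _require(out / "cohort" / "profiles.csv", "features")
    profiles = load_profiles(out)[: config.features_n_participants]
    frames = [
        extract_participant_features(p, config.signal, config.filter) for p in profiles
    ]
    d = out / "features"
    d.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(d / "trial_features.csv", index=False)


def _analysis_tables(config: RunConfig, out: Path):
    cohort = load_cohort(out)
    cohort = exclude_cognitive(cohort)
    imputed = knn_impute(cohort, config.imputation)
    standardized = zscore(imputed)
    outcome_z = (cohort.outcome - cohort.outcome.mean()) / cohort.outcome.std(ddof=0)
    return cohort, imputed, standardized, outcome_z


def _stage_screen(config: RunConfig, out: Path) -> None:
    _require(out / "cohort" / "cohort.csv", "screen")
    cohort, imputed, standardized, outcome_z = _analysis_tables(config, out)
    candidates = standardized.candidate_frame()
    candidates = candidates[[c for c in candidates.columns if schema.category_of(c) != "meta"]]
    covariates = standardized.data[list(COVARIATES)]
    stage1, stage2, final = screen_cascade(candidates, cohort.outcome, covariates)
    d = out / "screening"
    d.mkdir(parents=True, exist_ok=True)
    stage1.to_csv(d / "stage1.csv", index=False)
    stage2.to_csv(d / "stage2.csv", index=False)
    _write_json(d / "candidates.json", {"final_candidates": final})
    comparisons = []
    for col in imputed.candidate_frame().columns:
        if schema.category_of(col) == "meta":
            continue
        res = compare_groups(imputed.data[col], cohort.label)
        comparisons.append(
            {
                "feature": res.feature,
                "test": res.test,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    pd.DataFrame(comparisons).to_csv(d / "group_comparisons.csv", index=False)
    # cache the assembled tables for the downstream stages
    imputed.candidate_frame().to_csv(d / "imputed_candidates.csv")
    analysis = standardized.data.copy()
    analysis["moca_z"] = outcome_z
    analysis.to_csv(d / "analysis_table.csv")


def _load_screening(out: Path, stage: str):
    d = out / "screening"
    _require(d / "candidates.json", stage)
    final = json.loads((d / "candidates.json").read_text())["final_candidates"]
    analysis = pd.read_csv(_require(d / "analysis_table.csv", stage), index_col=0)
    imputed = pd.read_csv(_require(d / "imputed_candidates.csv", stage), index_col=0)
    return final, analysis, imputed


def _stage_model(config: RunConfig, out: Path) -> None:
    final, analysis, _ = _load_screening(out, "model")
    outcome = analysis["moca_z"]
    covariates = analysis[list(COVARIATES)]
    candidates = analysis[[c for c in final if c not in COVARIATES]]
    model = stepwise_fit(candidates, outcome, covariates)
    d = out / "model"
    d.mkdir(parents=True, exist_ok=True)
    model.summary_frame().to_csv(d / "stepwise.csv", index=False)
    _write_json(
        d / "model.json",
        {
            "selected": model.selected,
            "adjusted_r2": model.adjusted_r2,
            "entry_p": model.entry_p,
            "stay_p": model.stay_p,
            "note": model.note,
            "covariates": [
                {"term": t.name, "beta": t.beta, "p": t.p} for t in model.covariate_terms
            ],
        },
    )


def _stage_network(config: RunConfig, out: Path) -> None:
    _require(out / "model" / "model.json", "network")
    model_info = json.loads((out / "model" / "model.json").read_text())
    selected = model_info["selected"]
    final, analysis, _ = _load_screening(out, "network")
    if len(selected) < 2:
        log.warning("fewer than 2 selected terms; network spans outcome + candidates")
        selected = [c for c in final if c not in COVARIATES][:5]
    stepwise_frame = pd.read_csv(out / "model" / "stepwise.csv")
    data = analysis[["moca_z"] + selected]
    from .stepwise import RegressionTerm, StepwiseModel

    terms = tuple(
        RegressionTerm(
            name=r["term"], beta=r["beta"], se=r["se"], t=r["t"], p=r["p"], vif=r["vif"]
        )
        for _, r in stepwise_frame.iterrows()
    )
    sw = StepwiseModel(
        terms=terms,
        covariate_terms=(),
        adjusted_r2=model_info["adjusted_r2"],
        entry_p=model_info["entry_p"],
        stay_p=model_info["stay_p"],
    )
    net = fit_glasso_network(data, outcome="moca_z", stepwise_model=sw)
    layout = layout_network(net, seed=derive_seed(config.seed, "network"))
    d = out / "network"
    d.mkdir(parents=True, exist_ok=True)
    net.edge_frame().to_csv(d / "edges.csv", index=False)
    _write_json(
        d / "network.json",
        {
            "nodes": [
                {
                    "name": n,
                    "weight": net.node_weights[n],
                    "is_outcome": n == net.outcome,
                    "x": layout[n][0],
                    "y": layout[n][1],
                }
                for n in net.nodes
            ],
            "edges": [
                {"source": u, "target": v, "partial_correlation": r}
                for u, v, r in net.edges
            ],
            "threshold": net.threshold,
            "penalty": net.penalty,
        },
    )


def _stage_classify(config: RunConfig, out: Path) -> None:
    final, _, imputed = _load_screening(out, "classify")
    cohort = load_cohort(out)
    d = out / "classification"
    d.mkdir(parents=True, exist_ok=True)
    specs = [ModelSpec(family=f) for f in config.families]
    for configuration in config.configurations:
        cols = schema.columns_in(final, schema.CONFIGURATION_CATEGORIES[configuration])
        if not cols:
            log.warning("configuration %s has no screened candidates; skipped", configuration)
            continue
        cv_config = dataclasses.replace(config.cv, configuration=configuration)
        results = nested_cv(imputed[cols], cohort.label, cv_config, specs)
        for family, res in results.items():
            prefix = f"{configuration}_{family}"
            _write_json(
                d / f"{prefix}_metrics.json",
                {
                    "metrics": res.metrics,
                    "mean_fold_accuracy": res.mean_accuracy,
                    "sd_fold_accuracy": float(res.fold_metrics["accuracy"].std()),
                    "mean_fold_auc": res.mean_auc,
                    "sd_fold_auc": float(res.fold_metrics["roc_auc"].std()),
                    "metric_cis": {k: list(v) for k, v in res.metric_cis.items()},
                },
            )
            res.pooled_predictions.to_frame().assign(label=res.labels).to_csv(
                d / f"{prefix}_pooled_predictions.csv"
            )
            res.roc_points.to_csv(d / f"{prefix}_roc_points.csv", index=False)
        stability = results[specs[0].family].stability
        stability.rename("selection_frequency").to_csv(d / f"{configuration}_stability.csv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "screen": _stage_screen,
    "model": _stage_model,
    "network": _stage_network,
    "classify": _stage_classify,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages and write a manifest; returns out_dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = config.to_dict()
    config_text = yaml.safe_dump(resolved, sort_keys=True)
    (out / "config.yaml").write_text(config_text)
    executed = []
    for stage in STAGES:
        if config.stages.get(stage, False):
            log.info("running stage %s", stage)
            _STAGE_FUNCS[stage](config, out)
            executed.append(stage)
    artifacts = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": config.seed,
        "stages_executed": executed,
        "artifacts": artifacts,
    }
    _write_json(out / "manifest.json", manifest)
    return out
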