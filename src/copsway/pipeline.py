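"""End-to-end orchestration: simulate/read -> filter -> extract -> match ->
analyze -> report tables, with a serializable config and a run manifest.

Every stage writes plain delimited tables; the manifest (JSON) records the
config, derived seeds, package versions, participant/trial counts at every
filter step and a checksum per output table, so a rerun with the same
config is verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from copsway.core import CONDITIONS, FEATURE_NAMES, CohortSelection, CoPTrial
from copsway.linear_features import compute_linear_features
from copsway.matching import (
    fit_propensity,
    nn_caliper_match,
    records_frame,
    sensitivity_analyses,
    smd_table,
    welch_compare,
)
from copsway.nonlinear_features import NonlinearConfig, compute_nonlinear_features
from copsway.preprocess import filter_cop, select_cohort
from copsway.shap_cv import make_cv_plan, run_condition_analysis
from copsway.synthetic_data import SynthCohortParams, gen_cohort

logger = logging.getLogger("copsway")

__all__ = ["RunConfig", "extract_features", "run_full"]


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    # data source: either synthetic generation ...
    n_fallers: int = 8
    n_nonfallers: int = 16
    confound_strength: float = 0.5
    effect_features: List[Tuple[str, float]] = field(default_factory=list)
    trials_per_condition: int = 3
    n_samples: int = 6000
    fs: float = 100.0
    # ... or files on disk (set both to use real data)
    trials_dir: Optional[str] = None
    metadata_path: Optional[str] = None

    # preprocessing
    filter_cutoff_hz: float = 20.0
    filter_order: int = 2
    min_age: float = 60.0

    # nonlinear estimator knobs (NonlinearConfig fields)
    nonlinear: Dict = field(default_factory=dict)

    # matching
    caliper_factor: float = 0.2
    match_order: str = "descending"
    propensity_ridge: float = 1e-4
    n_strata: int = 5

    # SHAP-CV
    cv_k: int = 5
    cv_repeats: int = 30
    shap_n_sim: int = 64
    model_ridge: float = 1.0
    shap_output_scale: str = "prob"
    conditions: List[str] = field(default_factory=lambda: list(CONDITIONS))

    out_dir: str = "copsway_run"
    seed: int = 0

    def nonlinear_config(self) -> NonlinearConfig:
        return NonlinearConfig(**self.nonlinear)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "effect_features" in d:
            d["effect_features"] = [tuple(e) for e in d["effect_features"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_features(
    trials: Sequence[CoPTrial],
    nonlinear: Optional[NonlinearConfig] = None,
    return_trial_level: bool = False,
) -> pd.DataFrame:
    """Per-trial metrics averaged within participant x condition.

    Input trials must already be filtered.  Undefined per-trial metrics
    (NaN) are averaged over the defined trials only; a metric missing in
    every trial stays NaN.  Returns one row per participant x condition
    with the canonical metric columns; with ``return_trial_level=True`` the
    per-trial table is returned alongside as ``(averaged, trial_level)``.
    """
    if not trials:
        warnings.warn("empty trial list: returning empty feature table")
        cols = ["participant_id", "condition", "trial_index", *FEATURE_NAMES]
        empty = pd.DataFrame(columns=cols)
        out = pd.DataFrame(columns=["participant_id", "condition", *FEATURE_NAMES])
        return (out, empty) if return_trial_level else out
    rows = []
    for t in trials:
        feats = compute_linear_features(t)
        feats.update(compute_nonlinear_features(t, nonlinear))
        rows.append(
            {
                "participant_id": t.participant_id,
                "condition": t.condition,
                "trial_index": t.trial_index,
                **{name: feats[name] for name in FEATURE_NAMES},
            }
        )
    trial_level = pd.DataFrame(rows)
    averaged = (
        trial_level.groupby(["participant_id", "condition"], as_index=False)[list(FEATURE_NAMES)]
        .mean()  # skipna by default: undefined trials do not drag the mean
    )
    return (averaged, trial_level) if return_trial_level else averaged


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest["outputs"][path.name] = _sha256(path)


def _load_inputs(config: RunConfig, manifest: dict):
    if config.trials_dir and config.metadata_path:
        from copsway.preprocess import TrialDialect, read_metadata, read_trial

        meta = read_metadata(config.metadata_path)
        dialect = TrialDialect(fs=config.fs, duration_s=None)
        trials = [
            read_trial(p, dialect) for p in sorted(Path(config.trials_dir).glob("*.csv"))
        ]
        manifest["counts"]["metadata_rows_excluded"] = len(meta.exclusions)
        return meta.records, trials
    state = np.random.SeedSequence(config.seed).generate_state(1)
    params = SynthCohortParams(
        n_fallers=config.n_fallers,
        n_nonfallers=config.n_nonfallers,
        confound_strength=config.confound_strength,
        effect_features=config.effect_features,
        trials_per_condition=config.trials_per_condition,
        n_samples=config.n_samples,
        fs=config.fs,
        seed=int(state[0]),
    )
    return gen_cohort(params)


def run_full(config: RunConfig) -> dict:
    """Execute the whole pipeline and write the report bundle.

    Stages: load/simulate -> eligibility screen -> filter -> feature
    extraction -> propensity matching + balance -> matched Welch and
    sensitivity comparisons -> per-condition SHAP-CV.  Any stage failure is
    recorded in the manifest and downstream stages are skipped with an
    explicit status.  Returns the manifest dict (also written as JSON).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import scipy
    import sklearn
    import statsmodels

    import copsway

    manifest: dict = {
        "config": config.to_dict(),
        "versions": {
            "copsway": copsway.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "counts": {},
        "status": {},
        "outputs": {},
    }
    seeds = np.random.SeedSequence(config.seed).generate_state(8)
    config.to_yaml(out_dir / "config.yaml")

    def _finish() -> dict:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    # ---- load / simulate -------------------------------------------------
    try:
        records, trials = _load_inputs(config, manifest)
        manifest["counts"]["participants_input"] = len(records)
        manifest["counts"]["trials_input"] = len(trials)
        manifest["status"]["load"] = "ok"
    except Exception as exc:  # noqa: BLE001
        manifest["status"]["load"] = f"failed: {exc}"
        logger.error("load stage failed: %s", exc)
        return _finish()

    # ---- eligibility -----------------------------------------------------
    try:
        cohort: CohortSelection = select_cohort(records, trials, min_age=config.min_age)
        manifest["counts"].update(
            {
                "eligible_participants": len(cohort.records),
                "fallers": cohort.n_fallers,
                "nonfallers": cohort.n_nonfallers,
                "recurrent_fallers": cohort.n_recurrent_fallers,
                "excluded": {k: len(v) for k, v in cohort.excluded.items()},
                "eligible_trials": len(cohort.trials),
            }
        )
        manifest["status"]["select"] = "ok"
    except Exception as exc:  # noqa: BLE001
        manifest["status"]["select"] = f"failed: {exc}"
        return _finish()

    # ---- filter + extract ------------------------------------------------
    try:
        filtered = [
            filter_cop(t, cutoff_hz=config.filter_cutoff_hz, order=config.filter_order)
            for t in cohort.trials
        ]
        features, trial_level = extract_features(
            filtered, config.nonlinear_config(), return_trial_level=True
        )
        groups = cohort.groups
        features["faller"] = features["participant_id"].map(groups)
        _write(trial_level, out_dir / "trial_features.tsv", manifest)
        _write(features, out_dir / "features.tsv", manifest)
        n_missing = int(features[list(FEATURE_NAMES)].isna().sum().sum())
        manifest["counts"]["feature_rows"] = len(features)
        manifest["counts"]["missing_feature_cells"] = n_missing
        manifest["status"]["extract"] = "ok"
    except Exception as exc:  # noqa: BLE001
        manifest["status"]["extract"] = f"failed: {exc}"
        return _finish()

    # ---- matching and univariate comparisons -----------------------------
    try:
        fit = fit_propensity(cohort.records, ridge_lambda=config.propensity_ridge)
        match = nn_caliper_match(
            fit, cohort.records, caliper_factor=config.caliper_factor,
            order=config.match_order,
        )
        smd = smd_table(cohort.records, match)
        welch = welch_compare(features, match)
        sens = sensitivity_analyses(features, cohort.records, fit)
        _write(
            pd.DataFrame(match.pairs, columns=["faller_id", "nonfaller_id"]),
            out_dir / "match_pairs.tsv", manifest,
        )
        _write(smd.reset_index(names="covariate"), out_dir / "smd_love.tsv", manifest)
        _write(welch, out_dir / "welch.tsv", manifest)
        _write(sens, out_dir / "sensitivity.tsv", manifest)
        # matched per-metric distributions, violin-plot ready
        matched = features[features["participant_id"].isin(match.matched_ids)]
        violin = matched.melt(
            id_vars=["participant_id", "condition", "faller"],
            value_vars=list(FEATURE_NAMES), var_name="metric",
        )
        _write(violin, out_dir / "violin.tsv", manifest)
        manifest["counts"]["matched_pairs"] = match.n_pairs
        manifest["counts"]["unmatched_treated"] = len(match.unmatched)
        manifest["counts"]["caliper_logit"] = match.caliper
        manifest["status"]["match"] = "ok"
    except Exception as exc:  # noqa: BLE001
        manifest["status"]["match"] = f"failed: {exc}"
        return _finish()

    # ---- SHAP-CV per condition -------------------------------------------
    oof_rows = []
    for ci, cond in enumerate(CONDITIONS):
        if cond not in config.conditions:
            manifest["status"][f"shap_{cond}"] = "skipped (not in config.conditions)"
            continue
        try:
            block = features[features["condition"] == cond].set_index("participant_id")
            X = block[list(FEATURE_NAMES)]
            # mean-impute metrics undefined for some participants (counted above)
            X = X.fillna(X.mean())
            X = X.dropna(axis=1, how="all")
            y = block["faller"].to_numpy(dtype=int)
            plan = make_cv_plan(
                y, k=config.cv_k, repeats=config.cv_repeats, base_seed=int(seeds[2 + ci])
            )
            analysis = run_condition_analysis(
                X, y, plan,
                n_sim=config.shap_n_sim,
                ridge_lambda=config.model_ridge,
                output_scale=config.shap_output_scale,
                base_seed=int(seeds[4 + ci]),
            )
            _write(
                analysis.stability.rename("top5_proportion")
                .rename_axis("feature").reset_index(),
                out_dir / f"stability_{cond}.tsv", manifest,
            )
            _write(
                analysis.mean_abs_shap.rename("mean_abs_shap")
                .rename_axis("feature").reset_index(),
                out_dir / f"mean_abs_shap_{cond}.tsv", manifest,
            )
            _write(analysis.beeswarm, out_dir / f"beeswarm_{cond}.tsv", manifest)
            _write(analysis.split_metrics, out_dir / f"split_metrics_{cond}.tsv", manifest)
            oof_rows.append(
                {
                    "condition": cond,
                    "oof_auroc": analysis.oof_auroc,
                    "oof_accuracy": analysis.oof_accuracy,
                    "n_splits": plan.n_splits,
                    "n_splits_completed": analysis.n_splits_completed,
                    "n_split_failures": len(analysis.failures),
                }
            )
            manifest["counts"][f"cv_splits_{cond}"] = plan.n_splits
            manifest["counts"][f"cv_failures_{cond}"] = len(analysis.failures)
            manifest["status"][f"shap_{cond}"] = "ok"
        except Exception as exc:  # noqa: BLE001
            manifest["status"][f"shap_{cond}"] = f"failed: {exc}"
    if oof_rows:
        _write(pd.DataFrame(oof_rows), out_dir / "oof_summary.tsv", manifest)

    return _finish()
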