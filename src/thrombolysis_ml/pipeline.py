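"""End-to-end pipeline: generate, train, select, explain, analyse.

Every stage writes declared CSV/JSON artefacts into the run directory;
no stage reads another's internals except through those files or the
returned in-memory objects. A manifest records per-stage outputs with
SHA-256 checksums, so re-running with the same config must reproduce
identical files. All randomness flows from the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import explain, hospital, model, selection, subgroups, synthetic, variance

logger = logging.getLogger("thrombolysis_ml")

__all__ = ["RunConfig", "PipelineError", "run_all", "report"]

STAGES = ["generate", "train", "select_features", "explain",
          "hospital_analysis", "variance", "subgroups"]

#: Default per-feature bins for the fold-change table.
DEFAULT_BINS: dict[str, list[float] | None] = {
    "arrival_to_scan_min": [0, 15, 30, 45, 60, 75, 90, 105, 120, 180, 360],
    "infarction": None,
    "nihss": [0, 5, 10, 15, 20, 25, 30, 43],
    "precise_onset": None,
    "prior_mrs": None,
    "stroke_team": None,
    "anticoagulant": None,
    "onset_to_arrival_min": [0, 30, 60, 90, 120, 150, 180, 210, 241],
    "onset_during_sleep": None,
    "age_midpoint": None,
}


class PipelineError(RuntimeError):
    """A stage failed; message carries the stage name and cause."""


@dataclass
class RunConfig:
    """Master configuration of a full pipeline run."""

    seed: int = 0
    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig)
    model: model.ModelConfig = field(default_factory=model.ModelConfig)
    selection_epsilon: float = 0.001
    selection_folds: int = 3
    holdout_size: int = 5000
    subset_assignment: dict[str, str] = field(
        default_factory=variance.default_subset_assignment)
    run_selection: bool = True

    def __post_init__(self):
        # master seed drives every stage's seed
        self.generator.seed = self.seed
        self.model.seed = self.seed

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        gen = raw.pop("generator", {})
        eff = gen.pop("effect_params", {}) if isinstance(gen, dict) else {}
        mdl = raw.pop("model", {})
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        if gen:
            cfg.generator = synthetic.GeneratorConfig(
                **gen, effect_params=synthetic.EffectParams(**eff))
        elif eff:
            cfg.generator.effect_params = synthetic.EffectParams(**eff)
        if mdl:
            cfg.model = model.ModelConfig(**mdl)
        cfg.__post_init__()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    def __init__(self, out_dir: Path):
        self.out = out_dir
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"stages": {}}

    def record(self, stage: str, files: list[Path], t0: float) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in files},
            "elapsed_s": round(time.time() - t0, 2),
        }


def run_all(config: RunConfig, out_dir) -> dict:
    """Execute every stage in order and return the run manifest.

    Writes a resolved copy of the config, per-stage CSV/JSON artefacts
    and ``manifest.json`` into ``out_dir``. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    run = _Run(out)
    config.to_yaml(out / "config.resolved.yaml")
    run.manifest["seed"] = config.seed
    state: dict = {}

    def stage(name, fn):
        t0 = time.time()
        logger.info("stage %s ...", name)
        try:
            files = fn()
        except Exception as exc:
            raise PipelineError(f"stage {name} failed: {exc}") from exc
        run.record(name, files, t0)

    def do_generate():
        table, hospitals, truth = synthetic.generate_dataset(config.generator)
        state.update(table=table, hospitals=hospitals, truth=truth)
        path = out / "dataset.csv"
        synthetic.write_dataset(table, path, hospitals, truth)
        return [path, out / "dataset.csv.truth.yaml"]

    def do_train():
        cfg = config.model
        if config.holdout_size >= len(state["table"]):
            raise ValueError("holdout_size must be smaller than the dataset")
        _, metrics, oof = model.fit_kfold(state["table"], cfg)
        all_model = model.fit_all_data(state["table"], cfg)
        hold_cfg = dataclasses.replace(cfg, holdout_size=config.holdout_size)
        hold_model, cohort = model.fit_holdout(state["table"], hold_cfg)
        state.update(all_model=all_model, hold_model=hold_model,
                     cohort=cohort, oof=oof)
        mpath = out / "metrics.json"
        mpath.write_text(json.dumps(asdict(metrics), indent=2))
        bpath = out / "model_all_data.json"
        all_model.booster_.save_model(str(bpath))
        return [mpath, bpath]

    def do_select():
        if not config.run_selection:
            path = out / "selection_trace.csv"
            pd.DataFrame(columns=["round", "feature", "auc"]).to_csv(
                path, index=False)
            return [path]
        candidates = [c for c in state["table"].columns
                      if c != synthetic.LABEL_COLUMN]
        trace = selection.forward_select(
            state["table"], candidates, k_folds=config.selection_folds,
            epsilon=config.selection_epsilon, config=config.model)
        state["trace"] = trace
        path = out / "selection_trace.csv"
        trace.to_frame().to_csv(path, index=False)
        return [path]

    def do_explain():
        shap = explain.compute_shap(state["all_model"], state["table"])
        tensor = explain.compute_interactions(state["all_model"],
                                              state["table"])
        state.update(shap=shap, tensor=tensor)
        spath = out / "shap_values.csv"
        shap.values.to_csv(spath, index=False)
        mpath = out / "shap_main_effects.csv"
        pd.DataFrame(
            {f: tensor.main_effect(f) for f in tensor.feature_names}
        ).to_csv(mpath, index=False)
        return [spath, mpath]

    def do_hospital():
        effects = hospital.mean_hospital_main_effect(
            state["tensor"], state["table"]).with_descriptors(
            state["hospitals"])
        cf = hospital.counterfactual_cohort(
            state["hold_model"], state["cohort"], seed=config.seed)
        corr = hospital.process_correlates(effects)
        state.update(effects=effects, counterfactual=cf)
        e = out / "hospital_effects.csv"
        effects.table.to_csv(e)
        c = out / "counterfactual_rates.csv"
        cf.table.to_csv(c)
        p = out / "process_correlates.csv"
        corr.to_csv(p, index=False)
        return [e, c, p]

    def do_variance():
        rep = variance.regress_partition(
            state["tensor"], state["table"], config.subset_assignment)
        state["partition"] = rep
        m = out / "subset_means.csv"
        rep.hospital_means.to_csv(m)
        f = out / "variance_fits.json"
        f.write_text(rep.fits.to_json(orient="records", indent=2))
        return [m, f]

    def do_subgroups():
        obs = subgroups.observed_subgroup_rates(state["table"])
        pred = subgroups.predicted_subgroup_rates(
            state["hold_model"], state["cohort"])
        state.update(obs_matrix=obs, pred_matrix=pred)
        o = out / "subgroup_observed.csv"
        obs.to_csv(o, index=False)
        p = out / "subgroup_predicted.csv"
        pred.to_csv(p, index=False)
        return [o, p]

    stage("generate", do_generate)
    stage("train", do_train)
    stage("select_features", do_select)
    stage("explain", do_explain)
    stage("hospital_analysis", do_hospital)
    stage("variance", do_variance)
    stage("subgroups", do_subgroups)

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(run.manifest, indent=2, sort_keys=True))
    state["manifest"] = run.manifest
    return run.manifest


def fold_change_table(table: pd.DataFrame,
                      shap: "explain.ShapMatrix") -> pd.DataFrame:
    """Span of binned median SHAP values per feature, as an odds ratio.

    For each feature the SHAP values are binned (default bins per
    feature) and the fold change ``exp(max bin median - min bin median)``
    is reported together with the extreme bins.
    """
    rows = []
    for feature in shap.values.columns:
        bins = DEFAULT_BINS.get(feature)
        summary = explain.shap_vs_value_summary(table, shap, feature, bins)
        t = summary.table
        hi, lo = t["median"].idxmax(), t["median"].idxmin()
        rows.append({
            "feature": feature,
            "fold_change": float(np.exp(t.loc[hi, "median"]
                                        - t.loc[lo, "median"])),
            "highest_bin": t.loc[hi, "bin"],
            "lowest_bin": t.loc[lo, "bin"],
        })
    return pd.DataFrame(rows)


def report(out_dir) -> list[Path]:
    """Write one human-readable summary per analysis stage.

    Requires a completed run directory (``manifest.json`` present and all
    stages recorded); otherwise raises :class:`PipelineError` listing the
    missing stages. Returns the summary file paths.
    """
    out = Path(out_dir)
    mpath = out / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {"stages": {}}
    missing = [s for s in STAGES if s not in manifest.get("stages", {})]
    if missing:
        raise PipelineError(f"incomplete run; missing stages: {missing}")
    rep = out / "report"
    rep.mkdir(exist_ok=True)
    files = []

    table = synthetic.read_dataset(out / "dataset.csv")
    p = rep / "summary_generate.md"
    rate = table[synthetic.LABEL_COLUMN].mean()
    p.write_text(
        f"# Dataset\n\n{len(table)} patients, "
        f"{table['stroke_team'].nunique()} hospitals, "
        f"overall thrombolysis rate {rate:.1%}.\n")
    files.append(p)

    p = rep / "summary_train.md"
    metrics = json.loads((out / "metrics.json").read_text())
    lines = [f"- {k}: {v:.4g}" for k, v in metrics.items()]
    p.write_text("# Model accuracy (pooled out-of-fold)\n\n"
                 + "\n".join(lines) + "\n")
    files.append(p)

    p = rep / "summary_selection.csv"
    pd.read_csv(out / "selection_trace.csv").to_csv(p, index=False)
    files.append(p)

    # fold-change table over all reported features
    shap_values = pd.read_csv(out / "shap_values.csv")
    sm = explain.ShapMatrix(values=shap_values, base_value=0.0,
                            margins=np.zeros(len(shap_values)))
    p = rep / "summary_fold_changes.csv"
    fold_change_table(table, sm).to_csv(p, index=False)
    files.append(p)

    p = rep / "summary_hospital.csv"
    eff = pd.read_csv(out / "hospital_effects.csv")
    cf = pd.read_csv(out / "counterfactual_rates.csv")
    eff.merge(cf, on="team_id", how="outer").to_csv(p, index=False)
    files.append(p)

    p = rep / "summary_variance.csv"
    pd.read_json(out / "variance_fits.json").to_csv(p, index=False)
    files.append(p)

    p = rep / "summary_subgroups.csv"
    obs = subgroups.summarize_matrix(pd.read_csv(out / "subgroup_observed.csv"))
    pred = subgroups.summarize_matrix(pd.read_csv(out / "subgroup_predicted.csv"))
    obs["matrix"] = "observed"
    pred["matrix"] = "predicted"
    pd.concat([obs, pred]).to_csv(p, index=False)
    files.append(p)

    return files
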