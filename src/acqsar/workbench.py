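"""End-to-end orchestration: staged pipeline runs with manifests.

Stages — generate, curate, mmp, split, train, evaluate, report — read the
artefacts of their upstream stages from the output directory and write their
own artefacts plus a JSON manifest (configuration hash, seeds, input/output
checksums), so runs are resumable and reruns with an unchanged configuration
reproduce identical outputs (neural stages within floating-point tolerance).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import curation, mmp, paireval, splitting, synth
from .hpo import HPOPlan, default_plan
from .models import OracleModel, QSARRegressor
from .paireval import PairClassifierConfig, aggregate, reports_to_frame, score_trial

STAGES = ("generate", "curate", "mmp", "split", "train", "evaluate", "report")

DEFAULT_MODELS = tuple(
    f"{rep}-{reg}" for rep in ("ecfp", "pdv", "gin") for reg in ("rf", "knn", "mlp")
)


class StageOrderError(RuntimeError):
    """Raised when a stage is run before its upstream artefacts exist."""


@dataclass
class RunConfig:
    """Full configuration of one experimental run.

    Defaults equal the study's printed settings: MMP constraints (2x core
    dominance, <= 13 heavy atoms per variable part, <= 8 atoms difference),
    AC thresholds 2.0 / 1.0 log10 units, d_crit 1.5, and 2-fold
    cross-validation repeated with 3 seeds.
    """

    outdir: str = "runs/default"
    input_csv: str | None = None          # None -> synthetic generation
    synthetic_seed: int = 0
    n_scaffolds: int = 25
    n_substituents: int = 40
    noise_sd: float = 0.3
    core_ratio: float = 2.0
    max_var_atoms: int = 13
    max_var_diff: int = 8
    ac_threshold: float = 2.0
    non_ac_threshold: float = 1.0
    d_crit: float = 1.5
    m: int = 3
    k: int = 2
    cv_seeds: tuple[int, ...] = (0, 1, 2)
    models: tuple[str, ...] = ("ecfp-rf",)
    n_trials: int = 4
    epochs: int = 30
    model_seed: int = 0
    include_oracle: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["cv_seeds"] = tuple(raw.get("cv_seeds", (0, 1, 2)))
        raw["models"] = tuple(raw.get("models", ("ecfp-rf",)))
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def plan(self) -> splitting.CrossValidationPlan:
        return splitting.CrossValidationPlan(m=self.m, k=self.k, seeds=tuple(self.cv_seeds))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(stage: str, config: RunConfig, inputs: list[Path], outputs: list[Path]) -> Path:
    out = Path(config.outdir) / f"manifest_{stage}.json"
    payload = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "inputs": {p.name: _checksum(p) for p in inputs},
        "outputs": {p.name: _checksum(p) for p in outputs},
    }
    out.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return out


def _require(config: RunConfig, *names: str) -> list[Path]:
    paths = [Path(config.outdir) / n for n in names]
    missing = [p for p in paths if not p.exists()]
    if missing:
        raise StageOrderError(f"missing upstream artefact(s): {[str(p) for p in missing]}")
    return paths


# -- stages --------------------------------------------------------------


def stage_generate(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = synth.default_landscape(
        seed=config.synthetic_seed,
        n_scaffolds=config.n_scaffolds,
        n_substituents=config.n_substituents,
        noise_sd=config.noise_sd,
    )
    table, truth = synth.generate(spec)
    raw = outdir / "raw.csv"
    table.to_csv(raw, index=False)
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    _write_manifest("generate", config, [], [raw, truth_path])
    return {"n_rows": len(table), "n_unique": len(truth.true_labels)}


def stage_curate(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.input_csv is not None:
        raw = Path(config.input_csv)
        if not raw.exists():
            raise StageOrderError(f"missing input table: {raw}")
    else:
        (raw,) = _require(config, "raw.csv")
    compounds, log = curation.curate_table(raw)
    compounds_path = outdir / "compounds.csv"
    curation.write_compound_set(compounds, compounds_path)
    log_path = outdir / "curation_log.json"
    log_path.write_text(log.to_json())
    _write_manifest("curate", config, [raw], [compounds_path, log_path])
    return {"n_compounds": len(compounds), "log": json.loads(log.to_json())}


def stage_mmp(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    (compounds_path,) = _require(config, "compounds.csv")
    compounds = curation.read_compound_set(compounds_path)
    detected = mmp.detect_mmps(
        compounds,
        core_ratio=config.core_ratio,
        max_var_atoms=config.max_var_atoms,
        max_var_diff=config.max_var_diff,
    )
    mmp.check_constraints(detected, config.core_ratio, config.max_var_atoms, config.max_var_diff)
    labelled = mmp.label_mmps(detected, compounds, config.ac_threshold, config.non_ac_threshold)
    final, summary = mmp.finalise_mmp_set(labelled)
    mmps_path = outdir / "mmps.csv"
    mmp.write_mmp_set(final, mmps_path)
    summary_path = outdir / "mmp_summary.json"
    summary_path.write_text(
        json.dumps(
            {
                "n_mmps": summary.n_mmps,
                "n_ac": summary.n_ac,
                "n_half_ac": summary.n_half_ac,
                "n_non_ac": summary.n_non_ac,
            },
            indent=2,
        )
    )
    _write_manifest("mmp", config, [compounds_path], [mmps_path, summary_path])
    return {"summary": summary.__dict__}


def _load_mmps(path: Path) -> mmp.MMPSet:
    df = pd.read_csv(path)
    records = [
        mmp.MMPRecord(
            id_1=str(r.compound_id_1),
            id_2=str(r.compound_id_2),
            core_smiles=str(r.core_smiles),
            var_smiles_1=str(r.var_smiles_1),
            var_smiles_2=str(r.var_smiles_2),
            n_core=0,
            n_var_1=0,
            n_var_2=0,
            delta_label=float(r.delta_label),
            ac_class=str(r.ac_class),
            pd_label=None if pd.isna(r.pd_label) else str(r.pd_label),
        )
        for r in df.itertuples()
    ]
    return mmp.MMPSet(records=records)


def stage_split(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    compounds_path, mmps_path = _require(config, "compounds.csv", "mmps.csv")
    compounds = curation.read_compound_set(compounds_path)
    mmps = _load_mmps(mmps_path)
    instances = splitting.make_split_instances(compounds, mmps, config.plan())
    outputs = []
    for inst in instances:
        tag = f"n{inst.seed_index}_l{inst.fold_index}"
        cpath = outdir / f"split_{tag}_compounds.csv"
        ppath = outdir / f"split_{tag}_pairs.csv"
        mpath = outdir / f"split_{tag}_manifest.json"
        splitting.write_split_instance(inst, cpath, ppath, mpath)
        outputs += [cpath, ppath, mpath]
    _write_manifest("split", config, [compounds_path, mmps_path], outputs)
    return {"n_instances": len(instances), "counts": [i.counts() for i in instances]}


def _rebuild_splits(config: RunConfig) -> tuple[curation.CompoundSet, list[splitting.SplitInstance]]:
    compounds_path, mmps_path = _require(config, "compounds.csv", "mmps.csv")
    compounds = curation.read_compound_set(compounds_path)
    mmps = _load_mmps(mmps_path)
    return compounds, splitting.make_split_instances(compounds, mmps, config.plan())


def _build_model(tag: str, config: RunConfig) -> QSARRegressor | OracleModel:
    if tag == "oracle":
        return OracleModel()
    rep, reg = tag.split("-")
    return QSARRegressor(
        representation=rep,
        regressor=reg,
        n_trials=config.n_trials,
        epochs=config.epochs,
        random_state=config.model_seed,
    )


def stage_train(config: RunConfig) -> dict:
    """Train every configured model on every split and persist predictions
    for all compounds (training- and test-side)."""
    outdir = Path(config.outdir)
    compounds, instances = _rebuild_splits(config)
    labels = compounds.labels()
    smiles_of = {r.compound_id: r.smiles_canonical for r in compounds}
    model_tags = list(config.models) + (["oracle"] if config.include_oracle else [])
    rows = []
    for tag in model_tags:
        for inst in instances:
            model = _build_model(tag, config)
            train_ids = sorted(inst.d_train)
            model.fit([smiles_of[c] for c in train_ids], [labels[c] for c in train_ids])
            if isinstance(model, OracleModel):
                all_ids = sorted(inst.d_train | inst.d_test)
                preds = {c: labels[c] for c in all_ids}
            else:
                all_ids = sorted(inst.d_train | inst.d_test)
                pred_values = model.predict([smiles_of[c] for c in all_ids])
                preds = dict(zip(all_ids, map(float, pred_values)))
            for cid in all_ids:
                rows.append(
                    {
                        "compound_id": cid,
                        "y_true": labels[cid],
                        "y_pred": preds[cid],
                        "model_tag": tag,
                        "trial_n": inst.seed_index,
                        "trial_l": inst.fold_index,
                    }
                )
    pred_path = outdir / "predictions.csv"
    pd.DataFrame(rows).to_csv(pred_path, index=False)
    _write_manifest("train", config, _require(config, "compounds.csv", "mmps.csv"), [pred_path])
    return {"n_predictions": len(rows), "models": model_tags}


def stage_evaluate(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    (pred_path,) = _require(config, "predictions.csv")
    compounds, instances = _rebuild_splits(config)
    labels = compounds.labels()
    preds_df = pd.read_csv(pred_path)
    pair_config = PairClassifierConfig(d_crit=config.d_crit)
    all_rows = []
    aggregates = {}
    for tag, per_model in preds_df.groupby("model_tag"):
        reports = []
        for inst in instances:
            sub = per_model[
                (per_model.trial_n == inst.seed_index) & (per_model.trial_l == inst.fold_index)
            ]
            predictions = dict(zip(sub.compound_id.astype(str), sub.y_pred.astype(float)))
            reports.append(score_trial(predictions, labels, inst, pair_config))
        all_rows.append(reports_to_frame(reports, model_tag=str(tag)))
        agg = aggregate(reports)
        aggregates[str(tag)] = {
            "n_trials": agg.n_trials,
            "qsar_mae": agg.qsar_mae.__dict__,
            "pair_sets": {
                ps: {name: m.__dict__ for name, m in metrics.items()}
                for ps, metrics in agg.pair_sets.items()
            },
        }
    results_path = outdir / "results.csv"
    pd.concat(all_rows, ignore_index=True).to_csv(results_path, index=False)
    agg_path = outdir / "aggregate.json"
    agg_path.write_text(json.dumps(aggregates, indent=2, sort_keys=True))
    _write_manifest("evaluate", config, [pred_path], [results_path, agg_path])
    return {"models": sorted(aggregates)}


def stage_report(config: RunConfig) -> dict:
    """Scatter plots of pair-set metrics vs QSAR-MAE with 2-std error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(config.outdir)
    (agg_path,) = _require(config, "aggregate.json")
    aggregates = json.loads(agg_path.read_text())
    metric_names = ("mcc", "sensitivity", "precision", "pd_accuracy", "pd_accuracy_predicted_ac")
    pair_sets = ("inter", "test", "cores")
    fig, axes = plt.subplots(
        len(metric_names), len(pair_sets), figsize=(4 * len(pair_sets), 3 * len(metric_names))
    )
    for i, metric in enumerate(metric_names):
        for j, ps in enumerate(pair_sets):
            ax = axes[i][j]
            plotted = False
            for tag, agg in sorted(aggregates.items()):
                m = agg["pair_sets"][ps][metric]
                mae = agg["qsar_mae"]
                if m["mean"] is None or mae["mean"] is None:
                    continue
                ax.errorbar(
                    m["mean"],
                    mae["mean"],
                    xerr=m["std"],
                    yerr=mae["std"],
                    fmt="o",
                    capsize=3,
                    label=tag,
                )
                plotted = True
            if not plotted:
                ax.annotate("missing", (0.5, 0.5), xycoords="axes fraction", ha="center")
            ax.set_xlabel(f"{ps}: {metric}")
            ax.set_ylabel("QSAR MAE (test compounds)")
    handles, labels_ = axes[0][0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels_, loc="upper right")
    fig.tight_layout()
    fig_path = outdir / "report.png"
    fig.savefig(fig_path, dpi=100)
    plt.close(fig)

    summary_path = outdir / "report_summary.json"
    summary = {"models": sorted(aggregates)}
    mmp_summary = Path(config.outdir) / "mmp_summary.json"
    if mmp_summary.exists():
        summary["dataset"] = json.loads(mmp_summary.read_text())
    summary_path.write_text(json.dumps(summary, indent=2))
    _write_manifest("report", config, [agg_path], [fig_path, summary_path])
    return summary


_STAGE_FUNCS = {
    "generate": stage_generate,
    "curate": stage_curate,
    "mmp": stage_mmp,
    "split": stage_split,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "report": stage_report,
}


def run_stage(stage: str, config: RunConfig) -> dict:
    """Execute one pipeline stage; raises StageOrderError when upstream
    artefacts are missing."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return _STAGE_FUNCS[stage](config)


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline (skipping generation when an input table is given)."""
    out = {}
    for stage in STAGES:
        if stage == "generate" and config.input_csv is not None:
            continue
        out[stage] = run_stage(stage, config)
    return out
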