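"""End-to-end orchestration: preprocess -> spectral -> DE -> modules -> NN -> SVM.

`run_all` consumes either user-supplied expression/metadata TSVs or, when no
paths are given, a fully synthetic study generated from the stage-scoped
seeds, and emits a single JSON-serializable report with one block per stage
plus per-stage TSV artifacts.  Reports are deterministic for a fixed config
(no timestamps), so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, modules, nn, preprocess, simulate, spectral, svm
from .io import (
    ExpressionMatrix,
    GenePanel,
    GROUP_NAMES,
    Scale,
    read_expression,
    read_metadata,
    write_expression,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A stage failed; carries the stage name for attribution."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """Effective configuration of a full run; persisted next to the outputs."""

    expression_path: str | None = None
    metadata_path: str | None = None
    dialect: str = "plain_tsv"
    panel: tuple[str, ...] = ("BAG2", "HSC70", "STUB1", "MAPT")
    alpha: float = 0.05
    ttest_variant: str = "welch"
    beta: int = 8
    min_module_size: int = 30
    merge_cut: float = 0.25
    nn_learning_rate: float = 0.01
    nn_epochs: int = 2000
    nn_test_fraction: float = 0.25
    svm_sigma2: float = 0.5
    svm_C: float = 1.0
    seed_sim: int = 0
    seed_nn: int = 0
    seed_svm: int = 0
    out_dir: str = "foldnet_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["panel"] = list(self.panel)
        return d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, np.bool_)):
        return obj.item()
    return obj


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # attribute failures to the stage
                raise StageError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("preprocess")
def _load_inputs(config: PipelineConfig):
    if config.expression_path is None:
        sim = simulate.simulate_panel(simulate.PanelSimConfig(seed=config.seed_sim))
        meta = sim.metadata.copy()
        cohort = simulate.CohortSimConfig(seed=config.seed_sim)
        # background co-expression modules over the same samples, with the
        # first module's factor tied to severity so module-trait links exist
        bg = simulate.simulate_background_modules(
            cohort, seed=config.seed_sim + 2, trait=meta["group"].to_numpy(dtype=float)
        )
        bg_raw = np.power(10.0, np.clip(bg.expression.values, 0.0, None)) - 1.0
        expr = ExpressionMatrix(
            list(sim.expression.gene_ids) + list(bg.expression.gene_ids),
            list(sim.expression.sample_ids),
            np.vstack([sim.expression.values, bg_raw]),
            Scale.RAW,
        )
        logx = preprocess.log_transform(expr)
        panel_log = preprocess.extract_panel(logx, GenePanel(tuple(config.panel)))
        meta["mmse"] = simulate.simulate_mmse(panel_log, cohort, seed=config.seed_sim + 1)
    else:
        if config.metadata_path is None:
            raise StageError("preprocess", "metadata path is required with an expression path")
        expr = read_expression(config.expression_path, config.dialect)
        meta = read_metadata(config.metadata_path)
        logx = preprocess.log_transform(expr)
    panel = GenePanel(tuple(config.panel))
    grouped = preprocess.grouped_panel(logx, meta, panel)
    return expr, logx, meta, grouped


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write report.json plus stage TSVs to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict()}

    expr, logx, meta, grouped = _load_inputs(config)
    report["preprocess"] = {
        "n_genes": expr.n_genes,
        "n_samples": expr.n_samples,
        "group_sizes": {GROUP_NAMES.get(g, str(g)): n for g, n in grouped.sizes.items()},
    }

    report["spectral"] = _spectral_stage(grouped, out)
    report["de"] = _de_stage(logx, meta, config, out)
    report["modules"] = _modules_stage(logx, meta, config, out)
    report["nn"] = _nn_stage(grouped, meta, config, out)
    report["svm"] = _svm_stage(grouped, meta, config, out)

    report = _jsonable(report)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    return report


@_stage("spectral")
def _spectral_stage(grouped, out: Path) -> dict:
    results = []
    block: dict = {"groups": {}}
    for g in sorted(grouped.matrices):
        name = GROUP_NAMES.get(g, str(g))
        sr = spectral.eigendecompose(spectral.gram_matrix(grouped.matrices[g], name))
        results.append(sr)
        block["groups"][name] = {
            "fractions": sr.fractions,
            "leading_fraction": spectral.leading_fraction(sr),
            "eigenvectors": sr.vectors,  # genes as rows, one column per eigenvector
        }
        pd.DataFrame(
            sr.vectors,
            index=list(grouped.panel.symbols),
            columns=[f"lambda_{i + 1}" for i in range(sr.s)],
        ).to_csv(out / f"spectral_{name}.tsv", sep="\t", index_label="gene")
    traj = spectral.coordination_trajectory(results)
    block["trajectory"] = {
        "groups": traj.groups,
        "leading_fractions": traj.leading_fractions,
        "deltas": traj.deltas,
        "alignment": traj.alignment,
        "reversed_vs_first": traj.reversed_vs_first,
    }
    return block


@_stage("de")
def _de_stage(logx, meta, config: PipelineConfig, out: Path) -> dict:
    parts = preprocess.partition_by_group(logx, meta)
    control = parts.get(1)
    cases = [parts[g] for g in sorted(parts) if g != 1]
    if control is None or not cases:
        return {"skipped": "need a control group and at least one case group"}
    case_ids = [s for m in cases for s in m.sample_ids]
    case = logx.subset_samples(case_ids)
    table = diffexpr.screen_genes(case, control, alpha=config.alpha, variant=config.ttest_variant)
    table.to_csv(out / "de.tsv", sep="\t", index=False)
    return {
        "alpha": config.alpha,
        "variant": config.ttest_variant,
        "n_genes": len(table),
        "n_up": int((table["direction"] == "up").sum()),
        "n_down": int((table["direction"] == "down").sum()),
    }


@_stage("modules")
def _modules_stage(logx, meta, config: PipelineConfig, out: Path) -> dict:
    if logx.n_genes < config.min_module_size:
        return {"skipped": f"fewer than {config.min_module_size} genes"}
    corr = modules.spearman_matrix(logx)
    adj = modules.soft_adjacency(corr, beta=config.beta, gene_ids=logx.gene_ids)
    assign = modules.detect_modules(
        adj,
        min_size=config.min_module_size,
        merge_cut=config.merge_cut,
        expression=logx,
    )
    pd.DataFrame({"gene_id": assign.gene_ids, "module": assign.labels}).to_csv(
        out / "modules.tsv", sep="\t", index=False
    )
    block = {"beta": config.beta, "module_sizes": assign.module_sizes}
    mods = assign.modules
    if mods:
        eig = pd.DataFrame(
            {m: modules.module_eigengene(logx.subset_genes(assign.genes_in(m)).values) for m in mods},
            index=logx.sample_ids,
        )
        eig.to_csv(out / "eigengenes.tsv", sep="\t", index_label="sample_id")
        traits = meta.set_index("sample_id")
        numeric = traits.select_dtypes("number")
        if len(numeric.columns):
            mt = modules.module_trait_correlation(eig, numeric)
            mt.correlations.to_csv(out / "module_trait_corr.tsv", sep="\t")
            block["module_trait"] = {
                "correlations": {m: dict(mt.correlations.loc[m]) for m in mt.correlations.index},
                "p_values": {m: dict(mt.p_values.loc[m]) for m in mt.p_values.index},
            }
    return block


@_stage("nn")
def _nn_stage(grouped, meta, config: PipelineConfig, out: Path) -> dict:
    if "mmse" not in meta.columns or meta["mmse"].isna().all():
        return {"skipped": "no MMSE in metadata"}
    X = np.hstack([grouped.matrices[g] for g in sorted(grouped.matrices)]).T
    mmse = pd.Series(meta["mmse"].values, index=meta["sample_id"])
    ids = [s for g in sorted(grouped.matrices) for s in grouped.sample_ids[g]]
    y = mmse.loc[ids].to_numpy(dtype=float)
    keep = np.isfinite(y)
    X, y, ids = X[keep], y[keep], [i for i, k in zip(ids, keep) if k]
    test_size = max(3, int(round(config.nn_test_fraction * len(y))))
    tr, te = nn.split_train_test(len(y), test_size, seed=config.seed_nn)
    fit = nn.nn_train(
        X[tr],
        y[tr],
        nn.TrainConfig(
            learning_rate=config.nn_learning_rate, epochs=config.nn_epochs, seed=config.seed_nn
        ),
    )
    ev = nn.nn_evaluate(fit, X[te], y[te])
    pd.DataFrame(
        {
            "sample_id": [ids[i] for i in te],
            "true_mmse": ev.true,
            "predicted_mmse": ev.predicted_clipped,
        }
    ).to_csv(out / "nn_predictions.tsv", sep="\t", index=False)
    return {
        "n_train": len(tr),
        "n_test": len(te),
        "pearson_r": ev.pearson_r,
        "pearson_p": ev.pearson_p,
        "spearman_r": ev.spearman_r,
        "mse": ev.mse,
        "final_train_mse": float(fit.loss_trace[-1]),
    }


@_stage("svm")
def _svm_stage(grouped, meta, config: PipelineConfig, out: Path) -> dict:
    X = np.hstack([grouped.matrices[g] for g in sorted(grouped.matrices)])
    labels = np.concatenate(
        [np.full(grouped.matrices[g].shape[1], 0 if g == 1 else 1) for g in sorted(grouped.matrices)]
    )
    if len(set(labels)) < 2:
        return {"skipped": "need both control and patient samples"}
    F = svm.extract_features(X)
    rng = np.random.default_rng(config.seed_svm)
    order = rng.permutation(len(labels))
    n_test = max(4, len(labels) // 4)
    te, tr = order[:n_test], order[n_test:]
    if len(set(labels[tr])) < 2 or len(set(labels[te])) < 2:  # fall back to in-sample ROC
        tr = te = np.arange(len(labels))
    clf = svm.RBFMaxMarginClassifier(
        sigma2=config.svm_sigma2, C=config.svm_C, seed=config.seed_svm
    ).fit(F[tr], labels[tr])
    scores = clf.decision(F[te])
    roc = svm.roc_curve(scores, labels[te])
    cc = svm.confusion_counts(scores, labels[te])
    pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr, "threshold": roc.thresholds}).to_csv(
        out / "roc.tsv", sep="\t", index=False
    )
    return {
        "n_train": int(len(tr)),
        "n_test": int(len(te)),
        "auc": roc.auc,
        "sensitivity_at_0": cc.sensitivity,
        "specificity_at_0": cc.specificity,
    }
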