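"""End-to-end pipeline: simulate -> classify -> topology -> predict -> report.

The synthetic cohort run is the package's main integration surface: it
generates one phantom per subject, PRM-classifies the paired HU volumes,
computes windowed V/chi maps for Norm and fSAD, samples multi-channel
patches, trains the per-class dictionaries on the stratified training
partition and evaluates case-level prediction on the held-out partition,
alongside a whole-lung-mean logistic baseline and an mRMR feature ranking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import progression
from .cohort import delta_fev1
from .io import RunConfig, save_model
from .prm import CLASS_CODES, classify_voxels, qc_flag
from .progression import (
    DEFAULT_CHANNELS,
    PatchSet,
    classify_case,
    classify_patches,
    evaluate,
    extract_patches,
    logistic_baseline,
    mrmr_rank,
    stratified_split,
    train_dictionaries,
)
from .synthetic import CohortSpec, PhantomSpec, generate_cohort, generate_phantom
from .topology import compute_tprm

__all__ = ["CaseFeatures", "MLRunResult", "case_features",
           "run_synthetic_ml", "run_pipeline", "boxplot_stats", "report"]


@dataclass
class CaseFeatures:
    """Per-case products of the imaging stages."""

    case_id: str
    means: np.ndarray              # whole-lung means in DEFAULT_CHANNELS order
    patches: PatchSet
    percent_volume: dict[str, float]
    qc_pass: bool = True
    qc_reason: str = "ok"


def case_features(
    spec: PhantomSpec,
    case_id: str,
    config: RunConfig,
    patch_seed: int,
) -> CaseFeatures:
    """Simulate one case and run it through classification and topology."""
    ct, _ = generate_phantom(spec)
    passed, reason = qc_flag(ct) if config.qc else (True, "ok")
    prm = classify_voxels(ct)
    maps = compute_tprm(prm.labels, ct.lung_mask, CLASS_CODES,
                        classes=("Norm", "fSAD"),
                        window_vox=config.window_vox,
                        stride_vox=config.stride_vox)
    patches = extract_patches(
        maps, n_patches=config.patches_per_case,
        patch_edge_vox=config.patch_edge_vox, seed=patch_seed,
        case_id=case_id,
    )
    m = maps.whole_lung_means
    means = np.array([m["Norm"][0], m["fSAD"][0], m["Norm"][1], m["fSAD"][1]])
    return CaseFeatures(case_id=case_id, means=means, patches=patches,
                        percent_volume=prm.percent_volume,
                        qc_pass=passed, qc_reason=reason)


@dataclass
class MLRunResult:
    """Everything the synthetic prediction experiment produces."""

    cohort: pd.DataFrame
    phantoms: list[PhantomSpec]
    features: list[CaseFeatures]
    train_idx: np.ndarray
    test_idx: np.ndarray
    model: object
    scores_test: np.ndarray
    eval_dict: object            # EvalResult of the dictionary model
    eval_baseline: object        # EvalResult of the logistic baseline
    baseline_regularized: bool
    mrmr: list
    patch_labels_test: list[np.ndarray] = field(default_factory=list)


def run_synthetic_ml(spec: CohortSpec, config: RunConfig) -> MLRunResult:
    """Simulate a cohort and evaluate fast/slow progression prediction."""
    cohort, phantoms = generate_cohort(spec)
    rng = np.random.default_rng(config.seed)
    feats = [
        case_features(ph, cid, config, patch_seed=int(rng.integers(0, 2**31 - 1)))
        for ph, cid in zip(phantoms, cohort["case_id"])
    ]
    labels = cohort["progressor"].to_numpy()
    eligible = np.flatnonzero([f.qc_pass for f in feats])
    if len(eligible) < len(feats) and len(np.unique(labels[eligible])) < 2:
        raise ValueError(
            "QC excluded too many cases: fewer than two progression classes remain")
    sub_train, sub_test = stratified_split(labels[eligible],
                                           config.train_fraction,
                                           seed=config.seed)
    train_idx, test_idx = eligible[sub_train], eligible[sub_test]

    train_fast = progression._concat_patchsets(
        [feats[i].patches for i in train_idx if labels[i] == "fast"])
    train_slow = progression._concat_patchsets(
        [feats[i].patches for i in train_idx if labels[i] == "slow"])
    model = train_dictionaries(
        train_fast, train_slow, n_atoms=config.n_atoms, T=config.sparsity,
        n_iter=config.n_iter, seed=config.seed,
        aggregation_threshold=config.aggregation_threshold,
    )

    scores = np.empty(len(test_idx))
    patch_labels_test = []
    for k, i in enumerate(test_idx):
        plab = classify_patches(model, feats[i].patches)
        patch_labels_test.append(plab)
        scores[k], _ = classify_case(model, plab)
    ev = evaluate(labels[test_idx], scores,
                  threshold=config.aggregation_threshold)

    means = np.stack([f.means for f in feats])
    ev_base, _, reg_flag = logistic_baseline(means, labels, train_idx, test_idx)
    ranking = mrmr_rank(means[eligible], labels[eligible],
                        feature_names=DEFAULT_CHANNELS)

    return MLRunResult(
        cohort=cohort, phantoms=phantoms, features=feats,
        train_idx=train_idx, test_idx=test_idx, model=model,
        scores_test=scores, eval_dict=ev, eval_baseline=ev_base,
        baseline_regularized=reg_flag, mrmr=ranking,
        patch_labels_test=patch_labels_test,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic pipeline and write its artifacts to disk.

    Deterministic given the config (including seeds): rerunning with the
    same config reproduces byte-identical CSV outputs.  Returns a summary
    dictionary (also written as ``metrics.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    spec = CohortSpec(n_subjects=config.n_subjects,
                      effect_size=config.effect_size,
                      fast_fraction=config.fast_fraction,
                      seed=config.seed)
    result = run_synthetic_ml(spec, config)

    # QC-failing cases are listed and dropped from every downstream stage
    excluded = [
        {"case_id": f.case_id, "reason": f.qc_reason}
        for f in result.features if not f.qc_pass
    ]
    pd.DataFrame(excluded, columns=["case_id", "reason"]).to_csv(
        out / "exclusions.csv", index=False)

    cohort = result.cohort.copy()
    labels_recomputed = [
        delta_fev1(r.fev1_l, r.fev1_y5_l)[1] for r in cohort.itertuples()
    ]
    cohort["progressor_recomputed"] = labels_recomputed
    means = np.stack([f.means for f in result.features])
    for j, ch in enumerate(DEFAULT_CHANNELS):
        cohort[f"mean_{ch}"] = means[:, j]
    cohort.to_csv(out / "cohort.csv", index=False, float_format="%.8g")

    save_model(result.model, out / "model")

    metrics = {
        "n_subjects": config.n_subjects,
        "n_train": int(len(result.train_idx)),
        "n_test": int(len(result.test_idx)),
        "auc_dictionary": result.eval_dict.auc,
        "accuracy_dictionary": result.eval_dict.accuracy,
        "sensitivity": result.eval_dict.sensitivity,
        "specificity": result.eval_dict.specificity,
        "auc_logistic_baseline": result.eval_baseline.auc,
        "baseline_regularized": result.baseline_regularized,
        "mrmr_ranking": result.mrmr,
        "n_excluded_qc": len(excluded),
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    return metrics


def boxplot_stats(values) -> dict:
    """Quartiles, IQR whisker limits and outliers (linear-interpolated).

    Whiskers are Q1 - 1.5*IQR and Q3 + 1.5*IQR; points beyond them are
    outliers.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty group")
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return {
        "q1": float(q1), "median": float(q2), "q3": float(q3),
        "whisker_lo": float(lo), "whisker_hi": float(hi),
        "n_outliers": int(((v < lo) | (v > hi)).sum()),
        "n": int(v.size),
    }


_GOLD_ORDER = ["GOLD0", "PRISm", "GOLD1", "GOLD2", "GOLD3", "GOLD4"]


def report(run_dir, make_plots: bool = True) -> dict:
    """Summarise a pipeline run: per-GOLD boxplot data, ROC, feature ranks.

    Reads ``cohort.csv`` / ``metrics.json`` from ``run_dir`` and writes
    ``report.json`` (plus PNG figures unless ``make_plots`` is False).
    Empty GOLD groups are omitted with a warning entry.
    """
    run_dir = Path(run_dir)
    cohort = pd.read_csv(run_dir / "cohort.csv")
    metrics = json.loads((run_dir / "metrics.json").read_text())

    by_gold: dict[str, dict] = {}
    warnings_list = []
    metric_cols = [c for c in cohort.columns if c.startswith("mean_")]
    for g in _GOLD_ORDER:
        sub = cohort[cohort["gold_class"] == g]
        if sub.empty:
            warnings_list.append(f"empty GOLD group {g} omitted")
            continue
        by_gold[g] = {c: boxplot_stats(sub[c]) for c in metric_cols}

    rep = {
        "quartile_convention": "linear interpolation of order statistics",
        "whisker_convention": "Q1-1.5*IQR / Q3+1.5*IQR",
        "boxplots_by_gold": by_gold,
        "warnings": warnings_list,
        "auc_dictionary": metrics["auc_dictionary"],
        "auc_logistic_baseline": metrics["auc_logistic_baseline"],
        "mrmr_ranking": metrics["mrmr_ranking"],
    }
    (run_dir / "report.json").write_text(json.dumps(rep, indent=2, sort_keys=True))

    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(metric_cols), figsize=(4 * len(metric_cols), 4))
        for ax, col in zip(np.atleast_1d(axes), metric_cols):
            groups = [g for g in _GOLD_ORDER if g in by_gold]
            ax.boxplot([cohort.loc[cohort["gold_class"] == g, col] for g in groups],
                       tick_labels=groups, whis=1.5)
            ax.set_title(col)
            ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(run_dir / "boxplots_by_gold.png", dpi=100)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"dictionary AUC={metrics['auc_dictionary']:.2f}, "
                     f"baseline AUC={metrics['auc_logistic_baseline']:.2f}")
        fig.savefig(run_dir / "roc.png", dpi=100)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(5, 4))
        names = [r[0] for r in metrics["mrmr_ranking"]]
        vals = [r[1] for r in metrics["mrmr_ranking"]]
        ax.bar(names, vals)
        ax.set_ylabel("mRMR score")
        fig.tight_layout()
        fig.savefig(run_dir / "feature_ranks.png", dpi=100)
        plt.close(fig)
    return rep
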