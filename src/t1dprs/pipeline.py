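"""End-to-end orchestration: simulate, train, stratify, benchmark.

Every stage is a plain function over the library modules — no computation
lives only here — and each run writes a JSON manifest recording the config,
the seeds each stage consumed, input digests and output paths, so
deterministic stages reproduce bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import entropy as entropy_mod
from . import grs as grs_mod
from . import hwe, network, simulate, stratify
from .panel import (
    GenotypeMatrix,
    SNPPanel,
    SubjectTable,
    encode,
    load_panel,
    read_genotypes,
    write_dosage_matrix,
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, stage: str, payload: dict) -> Path:
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path


def load_cohort(
    genotypes_path: str | Path,
    subjects_path: str | Path,
    panel_path: str | Path | None = None,
) -> tuple[GenotypeMatrix, SubjectTable, SNPPanel]:
    panel = load_panel(panel_path)
    genotypes = read_genotypes(genotypes_path, panel)
    subjects = SubjectTable.from_csv(subjects_path)
    missing = set(genotypes.subject_ids) - set(subjects.subject_ids)
    if missing:
        raise ValueError(f"{len(missing)} genotyped subjects absent from subject table")
    subjects = subjects.subset(genotypes.subject_ids)
    return genotypes, subjects, panel


def run_simulate(config: simulate.SimulationConfig, out_dir: str | Path) -> dict:
    """Generate a synthetic cohort and write it in the ingestion formats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    panel = config.panel or load_panel()
    cohort = simulate.simulate_cohort(config, panel)
    geno_path = out_dir / "genotypes.tsv"
    subj_path = out_dir / "subjects.csv"
    truth_path = out_dir / "truth.csv"
    write_dosage_matrix(cohort.genotypes, geno_path)
    cohort.subjects.to_csv(subj_path)
    pd.DataFrame(
        {
            "subject_id": cohort.genotypes.subject_ids,
            "true_linear_score": cohort.true_linear_score,
            "attenuated": cohort.attenuation_mask.astype(int),
        }
    ).to_csv(truth_path, index=False)
    cfg = asdict(config)
    cfg.pop("panel", None)
    cfg["allele_freqs"] = (
        None if config.allele_freqs is None else list(np.asarray(config.allele_freqs))
    )
    manifest = {
        "stage": "simulate",
        "config": cfg,
        "intercept": cohort.intercept,
        "allele_freqs_used": list(cohort.allele_freqs),
        "seeds": {"master": config.seed},
        "outputs": {
            "genotypes": str(geno_path),
            "subjects": str(subj_path),
            "truth": str(truth_path),
        },
        "digests": {p.name: _sha256(p) for p in (geno_path, subj_path, truth_path)},
        "elapsed_s": time.time() - t0,
    }
    _write_manifest(out_dir, "simulate", manifest)
    return manifest


def _encode_with_entropy(
    genotypes: GenotypeMatrix,
    ref: hwe.ReferenceFrequencies,
    encoding: str,
    entropy_config: str,
):
    feats = encode(genotypes, encoding)
    if entropy_config != "none":
        feats = entropy_mod.augment_features(feats, genotypes, ref, entropy_config)
    return feats


def run_train(
    genotypes: GenotypeMatrix,
    subjects: SubjectTable,
    ratios: Sequence[str] = ("1:3",),
    encodings: Sequence[str] = ("count",),
    entropy_config: str = "none",
    grid: bool = False,
    net: network.NetworkConfig | None = None,
    train: network.TrainConfig | None = None,
    reference_prevalence: float = 0.10,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Train over the requested ratio x encoding grid and evaluate on a 1:9 test split.

    Protocol: stratified 80/20 split with a 1:9 test ratio; reference allele
    frequencies built from the training split only; HWE imputation of missing
    dosages; per configuration, control undersampling, 5-fold CV (a full
    optimizer x learning-rate grid search when ``grid`` is set, otherwise the
    documented default SGD/0.001), refit on the whole undersampled training
    set, and held-out test AUC with a DeLong 95% CI.
    """
    t0 = time.time()
    net = net or network.NetworkConfig(seed=seed)
    train = train or network.TrainConfig(seed=seed)
    train_subjects, test_subjects = network.split_train_test(subjects, seed=seed)
    train_geno = genotypes.subset(train_subjects.subject_ids)
    ref = hwe.build_reference(train_geno, train_subjects, reference_prevalence, seed=seed)
    imputed = hwe.impute(genotypes, ref, mode="expected")

    rows = []
    best = None
    for ratio in ratios:
        sel = network.undersample(train_subjects, ratio, seed=seed)
        sub_geno = imputed.subset(sel.subject_ids)
        y_sub = sel.y
        for enc in encodings:
            feats = _encode_with_entropy(sub_geno, ref, enc, entropy_config)
            if grid:
                cv = network.grid_search_cv(feats, y_sub, net=net, train=train, seed=seed)
                chosen = replace(
                    train, optimizer=cv.best_optimizer, learning_rate=cv.best_learning_rate
                )
            else:
                cv = network.grid_search_cv(
                    feats, y_sub, net=net, train=train,
                    optimizers=(train.optimizer,), learning_rates=(train.learning_rate,),
                    seed=seed,
                )
                chosen = train
            model = network.fit(feats, y_sub, net=net, train=chosen)
            test_geno = imputed.subset(test_subjects.subject_ids)
            test_feats = _encode_with_entropy(test_geno, ref, enc, entropy_config)
            test_mask = np.array([l != "aux_control" for l in test_subjects.labels])
            p_test = model.predict_proba(test_feats)
            est = network.auc_with_delong_ci(p_test[test_mask], test_subjects.y[test_mask])
            row = {
                "ratio": ratio,
                "encoding": enc,
                "entropy": entropy_config,
                "optimizer": chosen.optimizer,
                "learning_rate": chosen.learning_rate,
                "cv_mauc": cv.mean_auc,
                "test_auc": est.auc,
                "test_ci_low": est.ci_low,
                "test_ci_high": est.ci_high,
            }
            rows.append(row)
            if best is None or row["cv_mauc"] > best["row"]["cv_mauc"]:
                best = {"row": row, "model": model, "cv": cv}

    report = pd.DataFrame(rows)
    report["best"] = [
        (r["ratio"], r["encoding"]) == (best["row"]["ratio"], best["row"]["encoding"])
        for r in rows
    ]
    result = {
        "report": report,
        "model": best["model"],
        "best_row": best["row"],
        "reference": ref,
        "train_subjects": train_subjects,
        "test_subjects": test_subjects,
        "imputed_genotypes": imputed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report_path = out_dir / "cv_report.csv"
        report.to_csv(report_path, index=False)
        model_prefix = out_dir / "model"
        network.save_model(best["model"], model_prefix)
        ref.to_tsv(out_dir / "reference_frequencies.tsv")
        manifest = {
            "stage": "train",
            "seeds": {"master": seed, "net": net.seed, "train": train.seed},
            "ratios": list(ratios),
            "encodings": list(encodings),
            "entropy": entropy_config,
            "grid": grid,
            "best": best["row"],
            "outputs": {
                "cv_report": str(report_path),
                "model": str(model_prefix) + ".{json,npz}",
                "reference_frequencies": str(out_dir / "reference_frequencies.tsv"),
            },
            "elapsed_s": time.time() - t0,
        }
        _write_manifest(out_dir, "train", manifest)
        result["manifest"] = manifest
    return result


def run_stratify(
    model: network.RiskModel,
    genotypes: GenotypeMatrix,
    subjects: SubjectTable,
    ref: hwe.ReferenceFrequencies,
    encoding: str = "count",
    entropy_config: str = "none",
    thresholds: stratify.RiskThresholds = stratify.DEFAULT_THRESHOLDS,
    prevalence: float = 0.10,
    out_dir: str | Path | None = None,
) -> dict:
    """Apply a trained model and derive category/threshold/predictive-value tables."""
    t0 = time.time()
    imputed = hwe.impute(genotypes, ref, mode="expected")
    feats = _encode_with_entropy(imputed, ref, encoding, entropy_config)
    probs = model.predict_proba(feats)
    groups = [
        l if s is None else s for l, s in zip(subjects.labels, subjects.subgroups)
    ]
    dist = stratify.category_distribution(probs, groups, thresholds)
    cc_mask = np.array([l in ("case", "control") for l in subjects.labels])
    metrics = stratify.metrics_table(
        probs[cc_mask], subjects.y[cc_mask], prevalence,
        thresholds=sorted(set(thresholds.cuts) | {0.50}),
    )
    est = network.auc_with_delong_ci(probs[cc_mask], subjects.y[cc_mask])
    summary = stratify.distribution_summary(probs, groups)
    report = {
        "auc": est.auc,
        "auc_ci": [est.ci_low, est.ci_high],
        "prevalence": prevalence,
        "thresholds": list(thresholds.cuts),
        "n_subjects": len(subjects),
        "quantiles": {g: s["quantiles"] for g, s in summary.items()},
    }
    result = {
        "probabilities": probs,
        "category_distribution": dist,
        "metrics": metrics,
        "auc": est,
        "density_summary": summary,
        "report": report,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        dist.to_csv(out_dir / "category_distribution.csv")
        metrics.to_csv(out_dir / "threshold_metrics.csv", index=False)
        (out_dir / "stratification_report.json").write_text(
            json.dumps(report, indent=2, default=float)
        )
        pd.DataFrame(
            {"subject_id": subjects.subject_ids, "probability": probs, "group": groups}
        ).to_csv(out_dir / "probabilities.csv", index=False)
        manifest = {
            "stage": "stratify",
            "elapsed_s": time.time() - t0,
            "outputs": {
                "category_distribution": str(out_dir / "category_distribution.csv"),
                "threshold_metrics": str(out_dir / "threshold_metrics.csv"),
                "report": str(out_dir / "stratification_report.json"),
            },
        }
        _write_manifest(out_dir, "stratify", manifest)
    return result


def run_grs_benchmark(
    genotypes: GenotypeMatrix,
    subjects: SubjectTable,
    ref: hwe.ReferenceFrequencies,
    thresholds: stratify.RiskThresholds = stratify.DEFAULT_THRESHOLDS,
    prevalence: float | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Linear beta-weighted score benchmark: min-max normalised, same metric layout."""
    t0 = time.time()
    imputed = hwe.impute(genotypes, ref, mode="expected")
    result = grs_mod.compute_grs(imputed)
    cc_ids = [
        s for s, l in zip(subjects.subject_ids, subjects.labels) if l in ("case", "control")
    ]
    result = grs_mod.normalize_scores(result, cohort=cc_ids)
    idx = {s: i for i, s in enumerate(result.subject_ids)}
    cc_rows = [idx[s] for s in cc_ids]
    y = subjects.subset(cc_ids).y
    scores = result.normalized[cc_rows]
    if prevalence is None:
        prevalence = float(y.mean())
    metrics = stratify.metrics_table(
        scores, y, prevalence, thresholds=sorted(set(thresholds.cuts) | {0.50})
    )
    est = network.auc_with_delong_ci(scores, y)
    out = {"grs": result, "metrics": metrics, "auc": est, "prevalence": prevalence}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.to_csv(out_dir / "grs_scores.csv")
        metrics.to_csv(out_dir / "grs_metrics.csv", index=False)
        manifest = {
            "stage": "grs",
            "auc": est.auc,
            "auc_ci": [est.ci_low, est.ci_high],
            "prevalence": prevalence,
            "elapsed_s": time.time() - t0,
            "outputs": {
                "scores": str(out_dir / "grs_scores.csv"),
                "metrics": str(out_dir / "grs_metrics.csv"),
            },
        }
        _write_manifest(out_dir, "grs", manifest)
    return out
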