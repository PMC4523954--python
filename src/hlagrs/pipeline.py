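"""End-to-end DQ2.5-targeted risk-score workflow.

Stages: (1) simulate or load a training and an external-validation
cohort; (2) QC the training data; (3) HLA heterodimer typing; (4)
restrict both cohorts to DQ2.5 carriers; (5) cross-validated penalty
grid on the training data; (6) consensus GRS extraction; (7) score the
external cohort with the consensus GRS, the DQ2.5 zygosity, and the
3-level haplotype risk code; (8) AUC with DeLong CIs, paired AUC tests,
implications-ratio curves at an assumed prevalence, and a stratified
bootstrap of the ratio reduction against the implicate-everyone
baseline.  The training and validation cohorts are disjoint by
construction (cohort-level split with allele-frequency drift), and the
report is byte-identical for identical config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cv as cvmod
from . import evaluation as ev
from .hla import type_cohort
from .qc import QCThresholds, run_qc
from .scoring import apply_risk_score
from .simdata import SimParams, simulate_cohort_pair

__all__ = ["WorkflowConfig", "run_dq25_workflow", "validate_report", "REPORT_SCHEMA"]

logger = logging.getLogger(__name__)

SCORE_NAMES = ("grs_dq25", "haplotype_risk", "zygosity")

# Minimal structural schema for the JSON report (required key -> type).
REPORT_SCHEMA = {
    "seed": int,
    "n_train": int,
    "n_validation": int,
    "n_train_dq25": int,
    "n_validation_dq25": int,
    "consensus_n_variants": int,
    "selected_lambda1_index": int,
    "selected_lambda2": float,
    "cv_best_auc": float,
    "auc": dict,  # score name -> {auc, ci_low, ci_high}
    "paired_tests": dict,  # "a_vs_b" -> {delta_auc, p}
    "ratio_at_target": dict,  # score name -> r
    "bootstrap_vs_baseline": dict,  # score name -> {mean_diff, ci_low, ci_high}
    "prev": float,
    "sens_target": float,
}


@dataclass
class WorkflowConfig:
    sim: SimParams = field(default_factory=lambda: SimParams(n_individuals=1000, n_snps=2000))
    n_validation: int | None = None
    drift_fst: float = 0.01
    qc: QCThresholds = field(default_factory=lambda: QCThresholds(pca_k=10))
    n_folds: int = 10
    n_reps: int = 10
    lambda2_grid: tuple = (1.0,)
    n_lambda1: int = 8
    lambda1_min_ratio: float = 0.05
    freq_threshold: float = 0.6
    prev: float = 0.10
    sens_target: float = 0.90
    B: int = 2000
    seed: int = 0
    out_dir: str | Path | None = None
    make_plots: bool = False
    run_qc_stage: bool = True


def _round_floats(obj, ndigits=10):
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def validate_report(report: dict, schema: dict = REPORT_SCHEMA) -> None:
    """Structural validation of the report against the bundled schema."""
    for key, typ in schema.items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report[{key!r}] has type {type(report[key]).__name__}, expected {typ.__name__}")
    for name in SCORE_NAMES:
        if name not in report["auc"]:
            raise ValueError(f"report['auc'] missing score {name!r}")


def run_dq25_workflow(cfg: WorkflowConfig) -> dict:
    """Run the full workflow; returns the report dict (and writes files
    when ``cfg.out_dir`` is set)."""
    t0 = time.time()

    def stage(name):
        logger.info("[%6.1fs] stage: %s", time.time() - t0, name)

    # (1) cohorts
    stage("simulate cohorts")
    train, valid = simulate_cohort_pair(
        cfg.sim, n_validation=cfg.n_validation, seed=cfg.seed, drift_fst=cfg.drift_fst
    )

    # (2) QC on training data
    g_train = train.genotypes
    if cfg.run_qc_stage:
        stage("quality control")
        try:
            g_train, qc_report = run_qc(g_train, train.phenotype, cfg.qc)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"QC stage failed: {exc}") from exc
    else:
        qc_report = None

    # (3) HLA typing
    stage("HLA typing")
    hla_train = type_cohort(train.dq_alleles).set_index("iid")
    hla_valid = type_cohort(valid.dq_alleles).set_index("iid")

    # (4) restrict to DQ2.5 carriers
    stage("restrict to DQ2.5+")
    train_dq25_ids = [i for i in g_train.iids if hla_train.loc[i, "dq25_copies"] >= 1]
    valid_dq25_ids = [i for i in valid.genotypes.iids if hla_valid.loc[i, "dq25_copies"] >= 1]
    g_tr = g_train.select_individuals(train_dq25_ids)
    g_va = valid.genotypes.select_individuals(valid_dq25_ids)
    assert not (set(g_tr.iids) & set(g_va.iids)), "training/validation overlap"

    y_tr = g_tr.phenotype_array()
    y_va = g_va.phenotype_array()
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_va)) < 2:
        raise RuntimeError("DQ2.5+ restriction left a single-class cohort; enlarge the simulation")

    # (5) eligibility: only variants present in the validation panel
    shared = [v for v in g_tr.variant_ids if v in set(g_va.variant_ids)]
    g_tr = g_tr.select_variants(shared)

    # (6) CV grid + consensus
    stage("cross-validation")
    X_tr = g_tr.dosages
    cv_result = cvmod.cross_validate_grid(
        X_tr,
        y_tr,
        n_folds=cfg.n_folds,
        n_reps=cfg.n_reps,
        lambda2_grid=cfg.lambda2_grid,
        n_lambda1=cfg.n_lambda1,
        lambda1_min_ratio=cfg.lambda1_min_ratio,
        seed=cfg.seed,
    )
    lam1_idx, lam2 = cvmod.select_best_penalty(cv_result)
    curve = cvmod.smoothed_auc_curve(cv_result, lam2)
    stage("consensus extraction")
    # fall back to denser grid points if the selected penalty leaves an
    # empty consensus (possible under weak signal at sparse penalties)
    consensus = rsf = None
    candidate_indices = list(range(lam1_idx, cfg.n_lambda1)) + list(range(lam1_idx - 1, -1, -1))
    for idx in candidate_indices:
        try:
            consensus, rsf = cvmod.build_consensus(
                cv_result,
                idx,
                lam2,
                freq_threshold=cfg.freq_threshold,
                variants=g_tr.variants,
                name="GRS-DQ2.5",
            )
        except ValueError:
            continue
        if idx != lam1_idx:
            logger.warning("empty consensus at lambda1 index %d; using index %d", lam1_idx, idx)
            lam1_idx = idx
        break
    if consensus is None:
        raise RuntimeError(
            "consensus extraction failed at every penalty; lower freq_threshold"
        )

    # (7) score the external validation set
    stage("external scoring")
    grs_scores, coverage = apply_risk_score(rsf, g_va)
    scores = {
        "grs_dq25": grs_scores["score"].to_numpy(),
        "haplotype_risk": hla_valid.loc[g_va.iids, "risk_code"].to_numpy(dtype=float),
        "zygosity": hla_valid.loc[g_va.iids, "zygosity"].to_numpy(dtype=float),
    }

    # (8) evaluation
    stage("evaluation")
    auc_block = {}
    for name, s in scores.items():
        a, (lo, hi) = ev.auc_with_ci(s, y_va)
        auc_block[name] = {"auc": a, "ci_low": lo, "ci_high": hi}

    paired = {}
    for other in ("haplotype_risk", "zygosity"):
        d, p = ev.paired_auc_test(scores["grs_dq25"], scores[other], y_va)
        paired[f"grs_dq25_vs_{other}"] = {"delta_auc": d, "p": p, "test": "paired-delong"}

    ratio_block = {}
    curves = {}
    for name, s in scores.items():
        curves[name] = ev.implication_ratio_curve(s, y_va, cfg.prev)
        ratio_block[name] = ev.ratio_at_sensitivity(s, y_va, cfg.prev, cfg.sens_target)

    baseline = np.zeros_like(scores["grs_dq25"])  # implicate everyone
    boot_block = {}
    for name, s in scores.items():
        bd = ev.bootstrap_ratio_difference(
            baseline, s, y_va, cfg.prev, cfg.sens_target, B=cfg.B, seed=cfg.seed
        )
        boot_block[name] = {"mean_diff": bd.mean_diff, "ci_low": bd.ci_low, "ci_high": bd.ci_high}

    report = {
        "seed": cfg.seed,
        "n_train": int(train.genotypes.n_individuals),
        "n_validation": int(valid.genotypes.n_individuals),
        "n_train_dq25": int(g_tr.n_individuals),
        "n_validation_dq25": int(g_va.n_individuals),
        "consensus_n_variants": int(consensus.n_variants),
        "selected_lambda1_index": int(lam1_idx),
        "selected_lambda2": float(lam2),
        "cv_best_auc": float(curve.best_auc),
        "auc": auc_block,
        "paired_tests": paired,
        "ratio_at_target": ratio_block,
        "bootstrap_vs_baseline": boot_block,
        "prev": float(cfg.prev),
        "sens_target": float(cfg.sens_target),
        "score_coverage": {"n_entries": coverage.n_entries, "n_used": coverage.n_used},
    }
    report = _round_floats(report)
    validate_report(report)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        rsf.save(out / "grs_dq25.score.tsv")
        grs_scores.to_csv(out / "validation_scores.tsv", sep="\t", index=False)
        cv_result.records.to_csv(out / "cv_records.tsv", sep="\t", index=False)
        for name, rc in curves.items():
            pd.DataFrame({"sens": rc.sens, "r": rc.r, "threshold": rc.thresholds}).to_csv(
                out / f"ratio_curve_{name}.tsv", sep="\t", index=False
            )
        if qc_report is not None:
            qc_report.variant_stats.to_csv(out / "qc_variant_stats.tsv", sep="\t", index=False)
            with open(out / "qc_summary.json", "w") as fh:
                json.dump(qc_report.removal_counts, fh, indent=2, sort_keys=True)
        if cfg.make_plots:
            _plot(out, scores, y_va, curves)

    stage("done")
    return report


def _plot(out: Path, scores: dict, y: np.ndarray, curves: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    for name, s in scores.items():
        roc = ev.roc_curve(s, y)
        axes[0].plot(1 - roc.spec, roc.sens, label=name)
    axes[0].plot([0, 1], [0, 1], "k:", lw=0.8)
    axes[0].set_xlabel("1 - specificity")
    axes[0].set_ylabel("sensitivity")
    axes[0].set_title("External validation ROC (DQ2.5+)")
    axes[0].legend()
    for name, rc in curves.items():
        finite = np.isfinite(rc.r)
        axes[1].plot(rc.sens[finite], rc.r[finite], label=name)
    axes[1].axhline((1 - curves["grs_dq25"].prev) / curves["grs_dq25"].prev, color="k", ls=":", lw=0.8)
    axes[1].set_xlabel("sensitivity")
    axes[1].set_ylabel("non-cases implicated per case")
    axes[1].set_title("Implications ratio")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(out / "evaluation.png", dpi=120)
    plt.close(fig)
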