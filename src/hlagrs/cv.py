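"""Repeated stratified cross-validation, smoothed AUC curves, consensus GRS.

The training protocol is 10 repetitions of stratified 10-fold
cross-validation.  Within each training fold, columns are standardized
(constants frozen for the test fold), a warm-started L1 path is fitted
per L2 penalty, and the test-fold AUC and number of nonzero weights are
recorded for every grid point — 100 fitted models per grid point in
total.

Model selection smooths AUC against log10(1 + n_nonzero) with LOESS
(local linear, tricube weights) and picks the penalty pair maximizing
the smoothed curve, breaking ties towards sparser models.  The final
consensus model keeps variants selected (nonzero) in more than a fixed
fraction (default 60%) of the 100 replications, with weights averaged
over replications on the original dosage scale (weight / training-fold
SD), so the exported score file is portable to unstandardized data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import sparse_svm
from .evaluation import auc
from .scoring import RiskScoreFile

__all__ = [
    "CVGridResult",
    "ConsensusModel",
    "SmoothedCurve",
    "cross_validate_grid",
    "smoothed_auc_curve",
    "select_best_penalty",
    "build_consensus",
]


@dataclass
class CVGridResult:
    """Per-(repetition, fold, lambda2, lambda1-index) fit records.

    ``records``: DataFrame with columns rep, fold, lambda2, lambda1_index,
    lambda1, auc, n_nonzero.  ``weights[(rep, fold, lambda2)]`` holds the
    de-standardized weight matrix (n_lambda1 x n_variants).
    ``fold_assignments[rep]`` maps each individual to its test fold.
    """

    records: pd.DataFrame
    weights: dict
    fold_assignments: dict
    n_folds: int
    n_reps: int
    lambda2_grid: tuple
    n_lambda1: int
    seed: int


@dataclass
class ConsensusModel:
    selection_frequency: np.ndarray
    averaged_weights: np.ndarray
    freq_threshold: float
    included_index: np.ndarray
    lambda1_index: int
    lambda2: float
    averaging: str = "all"

    @property
    def n_variants(self) -> int:
        return int(self.included_index.size)


@dataclass
class SmoothedCurve:
    n_nonzero: np.ndarray
    auc_smoothed: np.ndarray
    best_n_nonzero: float
    best_auc: float
    smoothed: bool = True


def cross_validate_grid(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    n_reps: int = 10,
    lambda2_grid: tuple = (1.0,),
    n_lambda1: int = 10,
    lambda1_min_ratio: float = 0.05,
    tol: float = 1e-5,
    max_iter: int = 500,
    seed: int = 0,
) -> CVGridResult:
    """Repeated stratified k-fold CV of the penalized SVM over the grid.

    ``y`` is 0/1; internally mapped to -1/+1.  Deterministic given
    ``seed``.  Standardization is fitted on each training fold only.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y, dtype=int)
    if set(np.unique(y01)) != {0, 1}:
        raise ValueError("y must contain both classes, coded 0/1")
    ypm = np.where(y01 == 1, 1.0, -1.0)
    n, m = X.shape

    records = []
    weights: dict = {}
    fold_assignments: dict = {}
    rng = np.random.default_rng(seed)
    for rep in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
        assignment = np.empty(n, dtype=int)
        for fold, (train_ix, test_ix) in enumerate(skf.split(X, y01)):
            assignment[test_ix] = fold
            if len(np.unique(y01[train_ix])) < 2:  # pragma: no cover
                raise RuntimeError("a training fold lost a class despite stratification")
            std = sparse_svm.Standardizer().fit(X[train_ix])
            Xtr = std.transform(X[train_ix])
            Xte = std.transform(X[test_ix])
            for lam2 in lambda2_grid:
                path = sparse_svm.fit_path(
                    Xtr,
                    ypm[train_ix],
                    lambda2=lam2,
                    n_lambda1=n_lambda1,
                    lambda1_min_ratio=lambda1_min_ratio,
                    tol=tol,
                    max_iter=max_iter,
                )
                wmat = np.empty((n_lambda1, m), dtype=np.float32)
                for li, model in enumerate(path.models):
                    scores = sparse_svm.decision_scores(model, Xte)
                    records.append(
                        {
                            "rep": rep,
                            "fold": fold,
                            "lambda2": lam2,
                            "lambda1_index": li,
                            "lambda1": path.lambda1_grid[li],
                            "auc": auc(scores, y01[test_ix]),
                            "n_nonzero": model.n_nonzero,
                        }
                    )
                    wmat[li] = (model.coef / std.scale_).astype(np.float32)
                weights[(rep, fold, lam2)] = wmat
        fold_assignments[rep] = assignment

    return CVGridResult(
        records=pd.DataFrame(records),
        weights=weights,
        fold_assignments=fold_assignments,
        n_folds=n_folds,
        n_reps=n_reps,
        lambda2_grid=tuple(lambda2_grid),
        n_lambda1=n_lambda1,
        seed=seed,
    )


def smoothed_auc_curve(result: CVGridResult, lambda2: float, span: float = 0.75) -> SmoothedCurve:
    """LOESS-smoothed test AUC against log10(1 + n_nonzero) at one lambda2.

    With fewer than 10 points the raw (unsmoothed) means per sparsity
    level are returned instead.  Smoothed values are clipped to the range
    of the raw AUCs so the curve never leaves the data envelope.
    """
    sub = result.records[result.records["lambda2"] == lambda2]
    if sub.empty:
        raise ValueError(f"lambda2={lambda2} not in the CV grid")
    xs = np.log10(1.0 + sub["n_nonzero"].to_numpy(dtype=float))
    ys = sub["auc"].to_numpy(dtype=float)
    if len(xs) < 10:
        import warnings

        warnings.warn("fewer than 10 CV points: returning unsmoothed means", stacklevel=2)
        df = pd.DataFrame({"n": sub["n_nonzero"], "auc": ys}).groupby("n")["auc"].mean()
        nz = df.index.to_numpy(dtype=float)
        sm = df.to_numpy()
        best = int(np.argmax(sm))
        return SmoothedCurve(nz, sm, float(nz[best]), float(sm[best]), smoothed=False)

    fitted = lowess(ys, xs, frac=span, it=0, return_sorted=True)
    sm = np.clip(fitted[:, 1], ys.min(), ys.max())
    nz = 10.0 ** fitted[:, 0] - 1.0
    best = int(np.argmax(sm))
    return SmoothedCurve(nz, sm, float(nz[best]), float(sm[best]))


def select_best_penalty(result: CVGridResult, span: float = 0.75) -> tuple[int, float]:
    """(lambda1_index, lambda2) maximizing the smoothed AUC; ties -> sparser.

    For each grid point the smoothed curve at its lambda2 is evaluated at
    the point's mean sparsity; the winning point is the one whose raw
    mean AUC-at-index tracks the smoothed maximum most closely.
    """
    best = None
    for lam2 in result.lambda2_grid:
        sub = result.records[result.records["lambda2"] == lam2]
        curve = smoothed_auc_curve(result, lam2, span=span)
        # mean AUC and sparsity per lambda1 index, smoothed along the curve
        per_idx = sub.groupby("lambda1_index").agg(auc=("auc", "mean"), n_nonzero=("n_nonzero", "mean"))
        xs = np.log10(1.0 + per_idx["n_nonzero"].to_numpy(dtype=float))
        curve_x = np.log10(1.0 + curve.n_nonzero)
        sm_at_idx = np.interp(xs, curve_x, curve.auc_smoothed)
        for (idx, row), sm in zip(per_idx.iterrows(), sm_at_idx):
            key = (sm, -row["n_nonzero"])  # maximize AUC, tie -> sparser
            if best is None or key > best[0]:
                best = (key, (int(idx), float(lam2)))
    assert best is not None
    return best[1]


def build_consensus(
    result: CVGridResult,
    lambda1_index: int,
    lambda2: float,
    freq_threshold: float = 0.6,
    averaging: str = "all",
    variants: pd.DataFrame | None = None,
    name: str = "consensus-GRS",
) -> ConsensusModel | tuple[ConsensusModel, RiskScoreFile]:
    """Consensus model over the 100 replications at a chosen penalty.

    A variant enters the consensus when its selection frequency (the
    fraction of replications giving it a nonzero weight) strictly
    exceeds ``freq_threshold``.  Its weight is the mean de-standardized
    weight over all replications (``averaging="all"``, zeros included)
    or over the selecting replications only (``averaging="selected"``).

    When ``variants`` (DataFrame with ``id`` and ``a1`` columns, aligned
    with the CV design matrix) is given, also returns a portable
    :class:`RiskScoreFile` on the original dosage scale.
    """
    if averaging not in ("all", "selected"):
        raise ValueError("averaging must be 'all' or 'selected'")
    keys = [(rep, fold, lambda2) for rep in range(result.n_reps) for fold in range(result.n_folds)]
    missing = [k for k in keys if k not in result.weights]
    if missing:
        raise ValueError(f"lambda2={lambda2} has no fitted models")
    wstack = np.stack([result.weights[k][lambda1_index] for k in keys]).astype(float)
    n_models = wstack.shape[0]
    nonzero = wstack != 0.0
    freq = nonzero.sum(axis=0) / n_models
    included = np.flatnonzero(freq > freq_threshold)
    if included.size == 0:
        raise ValueError(
            "empty consensus: no variant exceeds the selection-frequency "
            f"threshold {freq_threshold}; lower the threshold or the penalty"
        )
    if averaging == "all":
        avg = wstack.mean(axis=0)
    else:
        counts = np.maximum(nonzero.sum(axis=0), 1)
        avg = wstack.sum(axis=0) / counts
    model = ConsensusModel(
        selection_frequency=freq,
        averaged_weights=avg,
        freq_threshold=freq_threshold,
        included_index=included,
        lambda1_index=lambda1_index,
        lambda2=lambda2,
        averaging=averaging,
    )
    if variants is None:
        return model
    entries = pd.DataFrame(
        {
            "variant_id": variants["id"].to_numpy()[included],
            "effect_allele": variants["a1"].to_numpy()[included],
            "weight": avg[included],
        }
    )
    return model, RiskScoreFile(entries=entries, name=name)
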