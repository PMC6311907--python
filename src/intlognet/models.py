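"""User-facing estimators: integrated, merged and single-dataset fits.

Three ways of handling M case/control cohorts that measure the same p
features:

- ``fit_integrated`` — the joint model: one shared coefficient vector, a
  per-sample intercept shrunk toward dataset-wise constancy by the
  sample-relation Laplacian penalty (strength mu).
- ``fit_merged``    — pool all samples and fit one common intercept (the
  mu -> infinity limit with a single pseudo-dataset); ignores
  heterogeneity.
- ``fit_single``    — ordinary penalized logistic regression on one cohort
  (scalar unpenalized intercept).

``cross_validate_lambda`` selects lambda on a grid by mean validation AUC
over stratified folds drawn within each dataset, then refits on the full
training data at the winning lambda (ties go to the larger, sparser
lambda).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .data_model import (
    FeatureNetwork,
    FitResult,
    PenaltyConfig,
    SampleRelationLaplacian,
    StackedDesign,
)
from . import solver
from .solver import SolverOptions

logger = logging.getLogger("intlognet")

Dataset = tuple[np.ndarray, np.ndarray]  # (X^m, Y^m)


def default_lambda_grid(n: int = 10) -> np.ndarray:
    """Log-spaced lambda grid spanning the sparse and dense regimes."""
    return np.logspace(-3.0, 0.0, n)


def _stack(
    datasets: Sequence[Dataset], feature_names: Optional[Sequence[str]] = None
) -> StackedDesign:
    if not datasets:
        raise ValueError("at least one dataset is required")
    p = np.asarray(datasets[0][0]).shape[1]
    for m, (Xm, _) in enumerate(datasets, start=1):
        if np.asarray(Xm).shape[1] != p:
            raise ValueError(
                f"dataset {m} has {np.asarray(Xm).shape[1]} features, "
                f"dataset 1 has {p}; all datasets must share feature columns"
            )
    X = np.vstack([np.asarray(Xm, dtype=np.float64) for Xm, _ in datasets])
    Y = np.concatenate([np.asarray(Ym, dtype=np.float64).ravel() for _, Ym in datasets])
    ids = np.concatenate(
        [
            np.full(np.asarray(Xm).shape[0], m, dtype=np.int64)
            for m, (Xm, _) in enumerate(datasets, start=1)
        ]
    )
    return StackedDesign(
        X=X, Y=Y, dataset_ids=ids,
        feature_names=list(feature_names) if feature_names else [],
    )


def fit_integrated(
    datasets: Sequence[Dataset],
    config: PenaltyConfig,
    net: Optional[FeatureNetwork] = None,
    options: Optional[SolverOptions] = None,
    feature_names: Optional[Sequence[str]] = None,
    beta_init: Optional[np.ndarray] = None,
) -> FitResult:
    """Joint fit across datasets with the sample-relation intercept penalty."""
    data = _stack(datasets, feature_names)
    return solver.fit(
        data, config, net=net, options=options, beta_init=beta_init
    )


def fit_merged(
    datasets: Sequence[Dataset],
    config: PenaltyConfig,
    net: Optional[FeatureNetwork] = None,
    options: Optional[SolverOptions] = None,
    feature_names: Optional[Sequence[str]] = None,
    beta_init: Optional[np.ndarray] = None,
) -> FitResult:
    """Pool all datasets and fit one common (unpenalized) intercept."""
    data = _stack(datasets, feature_names)
    merged = StackedDesign(
        X=data.X, Y=data.Y,
        dataset_ids=np.ones(data.n_samples, dtype=np.int64),
        feature_names=data.feature_names,
    )
    return solver.fit(
        merged, config, net=net, options=options,
        constant_intercept=True, beta_init=beta_init,
    )


def fit_single(
    dataset: Dataset,
    config: PenaltyConfig,
    net: Optional[FeatureNetwork] = None,
    options: Optional[SolverOptions] = None,
    feature_names: Optional[Sequence[str]] = None,
    beta_init: Optional[np.ndarray] = None,
) -> FitResult:
    """Penalized logistic regression on one cohort (scalar intercept)."""
    return fit_merged(
        [dataset], config, net=net, options=options,
        feature_names=feature_names, beta_init=beta_init,
    )


def predict_proba(
    fit: FitResult,
    X_new: np.ndarray,
    dataset_of_origin: Optional[np.ndarray] = None,
    allow_mean_intercept: bool = False,
) -> np.ndarray:
    """Predicted P(Y=1) using the averaged per-dataset intercepts.

    Samples must come from a dataset seen in training — the model has no
    intercept for an unseen source.  ``allow_mean_intercept=True`` opts in
    to using the mean of all dataset intercepts for unseen (or
    unspecified) origins instead.
    """
    X_new = np.asarray(X_new, dtype=np.float64)
    eta = X_new @ fit.beta
    if fit.intercept_mode == "constant":
        b0 = float(fit.dataset_intercepts[0])
        eta = eta + b0
    else:
        if dataset_of_origin is None:
            if not allow_mean_intercept:
                raise ValueError(
                    "dataset_of_origin is required for a per-dataset model; "
                    "pass allow_mean_intercept=True to use the average intercept"
                )
            eta = eta + float(fit.dataset_intercepts.mean())
        else:
            origin = np.asarray(dataset_of_origin, dtype=np.int64).ravel()
            if origin.size == 1:
                origin = np.full(X_new.shape[0], origin[0], dtype=np.int64)
            unseen = ~np.isin(origin, fit.dataset_labels)
            if unseen.any():
                if not allow_mean_intercept:
                    raise ValueError(
                        f"dataset ids {sorted(set(origin[unseen].tolist()))} were not "
                        "seen in training; the model assumes test sources are among "
                        "the training sources (pass allow_mean_intercept=True to "
                        "fall back to the average intercept)"
                    )
                b0 = np.full(origin.size, float(fit.dataset_intercepts.mean()))
                seen = ~unseen
                lookup = {
                    int(m): float(v)
                    for m, v in zip(fit.dataset_labels, fit.dataset_intercepts)
                }
                b0[seen] = [lookup[int(m)] for m in origin[seen]]
            else:
                lookup = {
                    int(m): float(v)
                    for m, v in zip(fit.dataset_labels, fit.dataset_intercepts)
                }
                b0 = np.array([lookup[int(m)] for m in origin])
            eta = eta + b0
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class CVSpec:
    """Cross-validation protocol for lambda selection."""

    n_folds: int = 5
    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    score: str = "auc"
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=np.float64).ravel()
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.lambda_grid.size == 0 or (self.lambda_grid <= 0).any():
            raise ValueError("lambda grid must be non-empty and positive")
        if self.score != "auc":
            raise ValueError("only AUC scoring is supported")


@dataclass
class CVResult:
    best_lambda: float
    table: pd.DataFrame      # columns: lam, mean_auc, sd_auc, fold aucs
    fit: FitResult           # refit on the full training data at best_lambda


def _draw_folds(
    datasets: Sequence[Dataset], n_folds: int, seed: int, stratified: bool
) -> list[list[np.ndarray]]:
    """Per-dataset fold assignment: folds[m][f] = sample indices (within m).

    Stratified by outcome within each dataset so every fold preserves the
    dataset's class composition as closely as integer counts allow.
    """
    rng = np.random.default_rng(seed)
    folds: list[list[np.ndarray]] = []
    for Xm, Ym in datasets:
        Ym = np.asarray(Ym).ravel()
        n = Ym.size
        assignment = np.empty(n, dtype=np.int64)
        if stratified:
            for cls in (0, 1):
                idx = np.flatnonzero(Ym == cls)
                rng.shuffle(idx)
                assignment[idx] = np.arange(idx.size) % n_folds
        else:
            idx = rng.permutation(n)
            assignment[idx] = np.arange(n) % n_folds
        folds.append([np.flatnonzero(assignment == f) for f in range(n_folds)])
    return folds


def _valid_folds(
    datasets: Sequence[Dataset], folds: list[list[np.ndarray]], n_folds: int
) -> bool:
    """Every pooled validation fold must contain both classes (for AUC)."""
    for f in range(n_folds):
        yv = np.concatenate(
            [np.asarray(Ym).ravel()[folds[m][f]] for m, (_, Ym) in enumerate(datasets)]
        )
        if yv.size == 0 or len(np.unique(yv)) < 2:
            return False
    return True


def cross_validate_lambda(
    datasets: Sequence[Dataset],
    config_template: PenaltyConfig,
    net: Optional[FeatureNetwork] = None,
    cv: Optional[CVSpec] = None,
    fit_kind: str = "int",
    options: Optional[SolverOptions] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> CVResult:
    """Select lambda by mean validation AUC, then refit on all data.

    ``fit_kind`` is one of ``"int"``, ``"merge"``, ``"single"`` (single
    requires exactly one dataset).  The grid is traversed from the largest
    lambda down with warm starts within each fold.
    """
    cv = cv or CVSpec()
    if fit_kind not in ("int", "merge", "single"):
        raise ValueError(f"unknown fit_kind {fit_kind!r}")
    if fit_kind == "single" and len(datasets) != 1:
        raise ValueError("fit_kind='single' requires exactly one dataset")

    folds = None
    for attempt in range(10):
        cand = _draw_folds(datasets, cv.n_folds, cv.seed + attempt, cv.stratified)
        if _valid_folds(datasets, cand, cv.n_folds):
            folds = cand
            break
        logger.warning("one-class validation fold at seed %d; redrawing", cv.seed + attempt)
    if folds is None:
        raise RuntimeError(
            "could not draw folds with both classes in every validation fold "
            "after 10 attempts; a dataset's minority class is too small"
        )

    grid = np.sort(cv.lambda_grid)[::-1]
    fitters = {"int": fit_integrated, "merge": fit_merged}
    aucs = np.zeros((grid.size, cv.n_folds))
    warm: list[Optional[np.ndarray]] = [None] * cv.n_folds
    for f in range(cv.n_folds):
        train_parts = []
        val_X, val_y, val_origin = [], [], []
        for m, (Xm, Ym) in enumerate(datasets):
            Xm = np.asarray(Xm, dtype=np.float64)
            Ym = np.asarray(Ym, dtype=np.float64).ravel()
            vidx = folds[m][f]
            tmask = np.ones(Ym.size, dtype=bool)
            tmask[vidx] = False
            train_parts.append((Xm[tmask], Ym[tmask]))
            val_X.append(Xm[vidx])
            val_y.append(Ym[vidx])
            val_origin.append(np.full(vidx.size, m + 1, dtype=np.int64))
        Xv = np.vstack(val_X)
        yv = np.concatenate(val_y)
        origin_v = np.concatenate(val_origin)
        for g, lam in enumerate(grid):
            cfg = config_template.with_lam(float(lam))
            if fit_kind == "single":
                fr = fit_single(
                    train_parts[0], cfg, net=net, options=options,
                    beta_init=warm[f],
                )
            else:
                fr = fitters[fit_kind](
                    train_parts, cfg, net=net, options=options,
                    beta_init=warm[f],
                )
            warm[f] = fr.beta
            p_hat = predict_proba(fr, Xv, dataset_of_origin=origin_v)
            aucs[g, f] = roc_auc_score(yv, p_hat)

    mean_auc = aucs.mean(axis=1)
    # argmax with ties broken toward the larger (sparser) lambda; the grid
    # is descending so the first index attaining the max wins
    best_idx = int(np.argmax(mean_auc))
    best_lambda = float(grid[best_idx])

    table = pd.DataFrame({"lam": grid, "mean_auc": mean_auc, "sd_auc": aucs.std(axis=1)})
    for f in range(cv.n_folds):
        table[f"fold{f}_auc"] = aucs[:, f]
    table = table.sort_values("lam").reset_index(drop=True)

    cfg = config_template.with_lam(best_lambda)
    n_total = sum(np.asarray(Ym).ravel().size for _, Ym in datasets)
    logger.info(
        "refit at lambda=%.6g on all %d training samples", best_lambda, n_total
    )
    if fit_kind == "single":
        final = fit_single(
            datasets[0], cfg, net=net, options=options, feature_names=feature_names
        )
    else:
        final = fitters[fit_kind](
            datasets, cfg, net=net, options=options, feature_names=feature_names
        )
    return CVResult(best_lambda=best_lambda, table=table, fit=final)


def write_model(fit: FitResult, features_path, datasets_path) -> None:
    """Serialize a fit as two TSVs: (feature, beta) and (dataset, intercept)."""
    pd.DataFrame({"feature": fit.feature_names, "beta": fit.beta}).to_csv(
        features_path, sep="\t", index=False, float_format="%.12g"
    )
    pd.DataFrame(
        {
            "dataset": fit.dataset_labels,
            "intercept": fit.dataset_intercepts,
            "intercept_mode": fit.intercept_mode,
        }
    ).to_csv(datasets_path, sep="\t", index=False, float_format="%.12g")


def read_model(features_path, datasets_path) -> FitResult:
    """Load a serialized model (sufficient for prediction)."""
    feat = pd.read_csv(features_path, sep="\t")
    ds = pd.read_csv(datasets_path, sep="\t")
    return FitResult(
        beta=feat["beta"].to_numpy(dtype=np.float64),
        beta0=np.zeros(0),
        dataset_labels=ds["dataset"].to_numpy(dtype=np.int64),
        dataset_intercepts=ds["intercept"].to_numpy(dtype=np.float64),
        objective_trace=[],
        converged=True,
        n_outer_iter=0,
        feature_names=feat["feature"].astype(str).tolist(),
        intercept_mode=str(ds["intercept_mode"].iloc[0]),
    )
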