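"""Prediction/selection metrics, the replication harness, and subnetworks.

``run_experiment`` reproduces the simulation-study protocol: per replicate,
generate the cohorts, run each requested method (a fitting scheme crossed
with a penalty), select lambda by within-dataset-stratified 5-fold CV on
AUC, refit on the full training data, predict the pooled test sets, and
score both prediction (sensitivity, specificity, accuracy, AUC at the 0.5
threshold) and variable selection (precision, recall, F1 against the
generative support).  The no-integration baseline fits each cohort
separately and reports the model with the best pooled-test AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .data_model import (
    ZERO_TOL,
    FeatureNetwork,
    FitResult,
    PenaltyConfig,
    PenaltyKind,
)
from .models import CVSpec, cross_validate_lambda, predict_proba
from .simulation import SimulationConfig, simulate
from .solver import SolverOptions

logger = logging.getLogger("intlognet")

METRIC_NAMES = (
    "sensitivity", "specificity", "accuracy", "auc",
    "precision", "recall", "f1",
)

#: the twelve simulation-study methods: scheme x penalty
ALL_METHODS = [
    (scheme, kind)
    for scheme in ("single", "merge", "int")
    for kind in PenaltyKind
]


@dataclass
class MetricsReport:
    """Prediction and/or selection metrics; unset fields stay NaN."""

    sensitivity: float = np.nan
    specificity: float = np.nan
    accuracy: float = np.nan
    auc: float = np.nan
    precision: float = np.nan
    recall: float = np.nan
    f1: float = np.nan
    n_selected: int = 0
    empty_support: bool = False

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES} | {
            "n_selected": self.n_selected
        }

    def update(self, other: "MetricsReport") -> "MetricsReport":
        for name in METRIC_NAMES + ("n_selected", "empty_support"):
            val = getattr(other, name)
            if isinstance(val, float) and np.isnan(val):
                continue
            setattr(self, name, val)
        return self


def prediction_metrics(
    y_true: np.ndarray, p_hat: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Sensitivity, specificity, accuracy at ``threshold``; rank-based AUC."""
    y = np.asarray(y_true, dtype=np.float64).ravel()
    p = np.asarray(p_hat, dtype=np.float64).ravel()
    if y.size != p.size:
        raise ValueError("y_true and p_hat must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC is undefined when y_true has a single class")
    pred = (p >= threshold).astype(np.float64)
    tp = float(np.sum((pred == 1) & (y == 1)))
    tn = float(np.sum((pred == 0) & (y == 0)))
    fp = float(np.sum((pred == 1) & (y == 0)))
    fn = float(np.sum((pred == 0) & (y == 1)))
    return MetricsReport(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / y.size,
        auc=float(roc_auc_score(y, p)),
    )


def selection_metrics(
    beta_hat: np.ndarray, beta_true: np.ndarray, zero_tol: float = ZERO_TOL
) -> MetricsReport:
    """Precision/recall/F1 of the estimated support against the truth."""
    bh = np.asarray(beta_hat, dtype=np.float64).ravel()
    bt = np.asarray(beta_true, dtype=np.float64).ravel()
    if bh.size != bt.size:
        raise ValueError("beta_hat and beta_true must have equal length")
    sel = np.abs(bh) > zero_tol
    true = np.abs(bt) > zero_tol
    n_sel = int(sel.sum())
    n_true = int(true.sum())
    inter = int((sel & true).sum())
    empty = n_sel == 0
    precision = 0.0 if empty else inter / n_sel
    recall = 0.0 if n_true == 0 else inter / n_true
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return MetricsReport(
        precision=precision, recall=recall, f1=f1,
        n_selected=n_sel, empty_support=empty,
    )


def _method_config(kind: PenaltyKind, mu: float = 1.0, alpha: float = 0.5):
    """Study-protocol penalty config: mu=1 and alpha=0.5 except LASSO."""
    return PenaltyConfig(kind=kind, alpha=alpha, mu=mu)


def method_label(scheme: str, kind: PenaltyKind) -> str:
    pretty = {
        PenaltyKind.LASSO: "LASSO",
        PenaltyKind.ENET: "Enet",
        PenaltyKind.NETWORK: "Network",
        PenaltyKind.ABS_NETWORK: "Abs-Network",
    }[kind]
    prefix = {"single": "", "merge": "Merge-", "int": "Int-"}[scheme]
    return prefix + pretty


def evaluate_method(
    scheme: str,
    kind: PenaltyKind,
    train: Sequence[tuple],
    test: Sequence[tuple],
    beta_true: np.ndarray,
    net: Optional[FeatureNetwork],
    cv: CVSpec,
    options: Optional[SolverOptions] = None,
    mu: float = 1.0,
    alpha: float = 0.5,
) -> MetricsReport:
    """Run one method on one replicate and score it on the pooled test sets."""
    config = _method_config(kind, mu=mu, alpha=alpha)
    use_net = net if config.needs_network else None
    X_test = np.vstack([X for X, _ in test])
    y_test = np.concatenate([np.asarray(Y).ravel() for _, Y in test])
    origin = np.concatenate(
        [np.full(np.asarray(Y).ravel().size, m + 1) for m, (_, Y) in enumerate(test)]
    )
    if scheme == "single":
        # fit each cohort separately, keep the best pooled-test AUC
        best: Optional[MetricsReport] = None
        best_fit: Optional[FitResult] = None
        for m, dataset in enumerate(train):
            res = cross_validate_lambda(
                [dataset], config, net=use_net, cv=cv,
                fit_kind="single", options=options,
            )
            p_hat = predict_proba(res.fit, X_test)
            rep = prediction_metrics(y_test, p_hat)
            if best is None or rep.auc > best.auc:
                best, best_fit = rep, res.fit
        return best.update(selection_metrics(best_fit.beta, beta_true))
    fit_kind = {"merge": "merge", "int": "int"}[scheme]
    res = cross_validate_lambda(
        train, config, net=use_net, cv=cv, fit_kind=fit_kind, options=options
    )
    p_hat = predict_proba(res.fit, X_test, dataset_of_origin=origin)
    rep = prediction_metrics(y_test, p_hat)
    return rep.update(selection_metrics(res.fit.beta, beta_true))


@dataclass
class ExperimentResult:
    replicates: pd.DataFrame  # one row per (replicate, method)
    summary: pd.DataFrame     # mean and sd per method

    def to_markdown(self) -> str:
        return self.summary.to_markdown(index=False, floatfmt=".2f")


def summarize_replicates(replicates: pd.DataFrame) -> pd.DataFrame:
    """Mean(sd) per method over replicates, shaped like the study tables."""
    rows = []
    for method, grp in replicates.groupby("method", sort=False):
        row = {"method": method, "n_replicates": len(grp)}
        for name in METRIC_NAMES:
            row[f"{name}_mean"] = grp[name].mean()
            row[f"{name}_sd"] = grp[name].std(ddof=1) if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def run_experiment(
    setting: int,
    methods: Optional[Sequence[tuple]] = None,
    n_replicates: int = 30,
    config: Optional[SimulationConfig] = None,
    seeds: Optional[Sequence[int]] = None,
    n_folds: int = 5,
    lambda_grid: Optional[np.ndarray] = None,
    options: Optional[SolverOptions] = None,
) -> ExperimentResult:
    """Replicate the simulation study for the requested methods.

    ``methods`` is a list of (scheme, penalty) pairs, defaulting to the
    full 3 x 4 grid.  ``seeds`` gives one generator seed per replicate
    (defaults to ``config.seed + replicate index``).  A failed replicate is
    re-seeded and retried at most twice, never silently dropped.
    """
    config = config or SimulationConfig(setting=setting)
    if config.setting != setting:
        raise ValueError("config.setting disagrees with the setting argument")
    if methods is None:
        methods = ALL_METHODS
    methods = [(scheme, PenaltyKind(kind)) for scheme, kind in methods]
    if seeds is None:
        seeds = [config.seed + r for r in range(n_replicates)]
    if len(seeds) != n_replicates:
        raise ValueError("need exactly one seed per replicate")

    rows = []
    for r, seed in enumerate(seeds):
        for attempt in range(3):
            try:
                rep_seed = int(seed) + attempt * 104729
                rep_config = SimulationConfig(
                    **{**config.__dict__, "seed": rep_seed}
                )
                train, test, beta_true, net = simulate(rep_config)
                for scheme, kind in methods:
                    cv = CVSpec(
                        n_folds=n_folds,
                        lambda_grid=(
                            lambda_grid
                            if lambda_grid is not None
                            else CVSpec().lambda_grid
                        ),
                        seed=rep_seed,
                    )
                    rep = evaluate_method(
                        scheme, kind, train, test, beta_true, net, cv,
                        options=options,
                    )
                    rows.append(
                        {
                            "replicate": r,
                            "seed": rep_seed,
                            "method": method_label(scheme, kind),
                            "scheme": scheme,
                            "penalty": kind.value,
                            **rep.as_dict(),
                        }
                    )
                break
            except Exception:  # noqa: BLE001 — replicate-level retry, then raise
                logger.exception("replicate %d failed (attempt %d)", r, attempt + 1)
                if attempt == 2:
                    raise
    replicates = pd.DataFrame(rows)
    return ExperimentResult(
        replicates=replicates, summary=summarize_replicates(replicates)
    )


def extract_selected_subnetworks(
    fit: FitResult,
    net: FeatureNetwork,
    zero_tol: float = ZERO_TOL,
) -> list[dict]:
    """Connected components of the feature network induced on the support.

    Returns a list of ``{"nodes": [...], "edges": [...], "size": int}``
    sorted by size descending (ties by first node name); singleton selected
    features appear as size-1 components.
    """
    if net.n_nodes != fit.beta.size:
        raise ValueError("network does not cover the fitted features")
    support = fit.selected_support(zero_tol)
    names = net.node_names or [f"f{j}" for j in range(net.n_nodes)]
    G = nx.Graph()
    G.add_nodes_from(int(j) for j in support)
    A = net.adjacency
    sel = set(int(j) for j in support)
    for j in support:
        row = A.indices[A.indptr[j] : A.indptr[j + 1]]
        for k in row:
            if int(k) in sel and j < k:
                G.add_edge(int(j), int(k))
    comps = []
    for nodes in nx.connected_components(G):
        nodes = sorted(nodes)
        comps.append(
            {
                "nodes": [names[j] for j in nodes],
                "edges": [
                    (names[a], names[b])
                    for a, b in sorted(G.subgraph(nodes).edges())
                ],
                "size": len(nodes),
            }
        )
    comps.sort(key=lambda c: (-c["size"], c["nodes"][0]))
    return comps


def write_subnetworks(components: list[dict], outdir) -> None:
    """Summary TSV plus one edge-list TSV per non-singleton component."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = pd.DataFrame(
        {
            "component": np.arange(1, len(components) + 1),
            "size": [c["size"] for c in components],
            "members": [";".join(c["nodes"]) for c in components],
        }
    )
    summary.to_csv(outdir / "subnetworks_summary.tsv", sep="\t", index=False)
    for i, c in enumerate(components, start=1):
        if c["edges"]:
            pd.DataFrame(c["edges"], columns=["nodeA", "nodeB"]).to_csv(
                outdir / f"subnetwork_{i}.tsv", sep="\t", index=False
            )
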