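"""Proximal Newton solver for the integrated penalized logistic model.

The objective over per-sample intercepts beta0 and shared coefficients beta
is

    (1/N) sum_i [ -Y_i eta_i + log(1 + exp(eta_i)) ]
        + lam * P_alpha(beta) + mu * beta0' Ltilde beta0,

with eta_i = beta0_i + X_i beta.  Each outer iteration linearizes the
log-likelihood at the current iterate (IRLS working response Z and weights
W_ii = p_i (1 - p_i)) and solves the penalized weighted least-squares
subproblem

    (1/2N) sum_i W_ii (Z_i - beta0_i - X_i beta)^2
        + lam * P_alpha(beta) + mu * beta0' Ltilde beta0

by alternating an exact blockwise linear solve in beta0 with cyclic
coordinate descent in beta.  A step-halving safeguard keeps the outer
objective trace non-increasing (plain proximal Newton can overshoot on
separable data).

The beta0 stationarity condition is ((1/N) W + 2 mu Ltilde) beta0 =
(1/N) W (Z - X beta).  Because Ltilde restricted to a dataset block of
size n is c (n I - J) (J the all-ones matrix), each block is a diagonal
matrix minus a rank-one term and is solved in O(n) by the Woodbury
identity, with the Woodbury denominator rearranged into a sum of positive
terms so the solve stays accurate for arbitrarily large mu.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import (
    FeatureNetwork,
    FitResult,
    PenaltyConfig,
    SampleRelationLaplacian,
    StackedDesign,
    compute_dataset_intercepts,
)
from .penalties import KIND_CODES, _cd_sweep, _network_arrays, penalty_value

logger = logging.getLogger("intlognet")


@dataclass
class SolverOptions:
    """Iteration limits and tolerances for the proximal Newton loop."""

    max_outer: int = 50
    max_inner_sweeps: int = 200
    tol_outer: float = 1e-6       # relative objective change
    tol_inner: float = 1e-5       # max abs coefficient change
    probability_clip: float = 1e-5
    step_halving: bool = True

    def __post_init__(self) -> None:
        if self.tol_outer <= 0 or self.tol_inner <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.probability_clip <= 0.01:
            raise ValueError("probability_clip must be in (0, 0.01]")


@dataclass
class SolverState:
    """Mutable iterate of the outer loop (mainly for introspection/tests)."""

    beta: np.ndarray
    beta0: np.ndarray
    probabilities: np.ndarray = field(default=None)
    weights: np.ndarray = field(default=None)
    working_response: np.ndarray = field(default=None)
    n_outer: int = 0
    objective: float = np.inf


def _log1pexp(eta: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, eta)


def objective(
    beta0: np.ndarray,
    beta: np.ndarray,
    data: StackedDesign,
    config: PenaltyConfig,
    net: Optional[FeatureNetwork] = None,
    Ltilde: Optional[SampleRelationLaplacian] = None,
) -> float:
    """Penalized negative log-likelihood (the quantity the solver descends)."""
    eta = beta0 + data.X @ beta
    nll = float(np.mean(-data.Y * eta + _log1pexp(eta)))
    val = nll + config.lam * penalty_value(config, beta, net)
    if Ltilde is not None and config.mu > 0:
        val += config.mu * Ltilde.quadform(beta0)
    if not np.isfinite(val):
        raise FloatingPointError("objective is non-finite; check inputs/scaling")
    return val


def working_response(
    beta0: np.ndarray,
    beta: np.ndarray,
    data: StackedDesign,
    probability_clip: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """IRLS working response Z and weights W_ii at the current iterate.

    Z_i = eta_i + (Y_i - p_i)/W_ii with W_ii = p_i (1 - p_i); probabilities
    are clipped into [eps, 1-eps] so the weights never vanish.
    """
    eta = beta0 + data.X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = probability_clip
    p = np.clip(p, eps, 1.0 - eps)
    w = p * (1.0 - p)
    z = eta + (data.Y - p) / w
    return z, w


def solve_beta0(
    w: np.ndarray,
    z: np.ndarray,
    xbeta: np.ndarray,
    Ltilde: SampleRelationLaplacian,
    mu: float,
    constant: bool = False,
) -> np.ndarray:
    """Exact minimizer of the quadratic subproblem in beta0 given beta.

    Solves ((1/N) W + 2 mu Ltilde) beta0 = (1/N) W (Z - X beta) blockwise.
    With ``constant=True`` the intercept is forced exactly constant within
    each block (the mu -> infinity limit): the W-weighted block mean of
    Z - X beta.
    """
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    N = w.size
    s = z - xbeta
    beta0 = np.empty(N)
    for idx in Ltilde.blocks:
        wb, sb = w[idx], s[idx]
        nb = idx.size
        if constant:
            beta0[idx] = float(wb @ sb) / float(wb.sum())
            continue
        c = 2.0 * mu * Ltilde.block_scale(nb)
        D = wb / N + c * nb          # diagonal of the block system
        rhs = wb * sb / N
        x0 = rhs / D
        if c > 0.0:
            # Woodbury for D - c 11'; the denominator 1 - c sum(1/D) is
            # rewritten as sum_i (w_i/N) / (n D_i) — all positive, no
            # cancellation even as mu -> infinity.
            denom = float(np.sum((wb / N) / (nb * D)))
            coef = c * float(np.sum(x0)) / denom
            x0 = x0 + coef / D
        beta0[idx] = x0
    return beta0


def _quadratic_objective(w, r, beta, beta0, config, net, Ltilde, constant):
    val = 0.5 * float(np.mean(w * r * r)) + config.lam * penalty_value(
        config, beta, net
    )
    if not constant and Ltilde is not None and config.mu > 0:
        val += config.mu * Ltilde.quadform(beta0)
    return val


def inner_quadratic_solve(
    XF: np.ndarray,
    w: np.ndarray,
    z: np.ndarray,
    beta: np.ndarray,
    beta0: np.ndarray,
    config: PenaltyConfig,
    net: Optional[FeatureNetwork],
    Ltilde: SampleRelationLaplacian,
    options: SolverOptions,
    constant_intercept: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating minimization of the quadratic subproblem.

    Each alternation solves beta0 exactly, then runs one full coordinate
    sweep followed by active-set sweeps over the current nonzero support.
    Stops when the largest coefficient/intercept change in an alternation
    falls below ``tol_inner`` or the sweep budget is spent.  For the convex
    kinds the subproblem value is verified non-increasing across
    alternations (a bug trap, not a numerical tolerance issue).
    """
    N, p = XF.shape
    beta = beta.copy()
    beta0 = beta0.copy()
    q = (w[:, None] * XF**2).sum(axis=0) / N
    indptr, indices, avals, dinvsqrt, has_degree = _network_arrays(net, p)
    kind = KIND_CODES[config.kind]
    lam, alpha = float(config.lam), float(config.alpha)
    full_order = np.arange(p, dtype=np.int64)
    r = z - beta0 - XF @ beta

    convex = config.kind.value != "abs_network"
    prev_quad = np.inf
    sweeps_used = 0
    warned_skip = False
    for _ in range(options.max_inner_sweeps):
        old0 = beta0
        beta0 = solve_beta0(
            w, z, z - r - old0, Ltilde, config.mu, constant=constant_intercept
        )
        r = r + (old0 - beta0)
        delta0 = float(np.max(np.abs(beta0 - old0))) if N else 0.0

        maxd, skipped = _cd_sweep(
            XF, w, r, beta, q, lam, alpha, kind,
            indptr, indices, avals, dinvsqrt, has_degree, full_order,
        )
        if skipped and not warned_skip:
            logger.warning(
                "%d coordinate updates skipped (zero curvature and no ridge term)",
                skipped,
            )
            warned_skip = True
        sweeps_used += 1
        # active-set refinement: iterate the nonzero support to convergence
        while maxd >= options.tol_inner and sweeps_used < options.max_inner_sweeps:
            active = np.flatnonzero(beta).astype(np.int64)
            if active.size == 0 or active.size == p:
                break
            d_act, _ = _cd_sweep(
                XF, w, r, beta, q, lam, alpha, kind,
                indptr, indices, avals, dinvsqrt, has_degree, active,
            )
            sweeps_used += 1
            if d_act < options.tol_inner:
                break

        if convex:
            quad = _quadratic_objective(
                w, r, beta, beta0, config, net, Ltilde, constant_intercept
            )
            if quad > prev_quad + 1e-8 * (1.0 + abs(prev_quad)):
                raise RuntimeError(
                    "quadratic subproblem objective increased for a convex "
                    f"penalty ({prev_quad} -> {quad}); solver bug"
                )
            prev_quad = quad

        if max(maxd, delta0) < options.tol_inner:
            break
        if sweeps_used >= options.max_inner_sweeps:
            break
    return beta, beta0


def _initial_intercepts(data: StackedDesign, eps: float) -> np.ndarray:
    """Per-dataset log-odds of outcome prevalence (clipped), constant within."""
    beta0 = np.empty(data.n_samples)
    for m in data.dataset_labels:
        mask = data.dataset_ids == m
        ybar = float(np.clip(data.Y[mask].mean(), eps, 1.0 - eps))
        beta0[mask] = np.log(ybar / (1.0 - ybar))
    return beta0


def fit(
    data: StackedDesign,
    config: PenaltyConfig,
    net: Optional[FeatureNetwork] = None,
    options: Optional[SolverOptions] = None,
    Ltilde: Optional[SampleRelationLaplacian] = None,
    constant_intercept: bool = False,
    beta_init: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit the integrated model by proximal Newton with step halving.

    ``constant_intercept=True`` forces the intercept exactly constant
    within each dataset block (used for merged/single-dataset baselines);
    the mu penalty term then contributes nothing and is dropped from the
    objective.
    """
    options = options or SolverOptions()
    if config.needs_network:
        if net is None:
            raise ValueError(
                f"penalty kind {config.kind.value!r} requires a feature network"
            )
        if net.n_nodes != data.n_features:
            raise ValueError("feature network size must match the design matrix")
    if Ltilde is None:
        Ltilde = SampleRelationLaplacian(data.dataset_ids)
    XF = np.asfortranarray(data.X)
    zero_var = np.flatnonzero(data.X.std(axis=0) == 0)
    if zero_var.size:
        logger.warning(
            "%d zero-variance feature columns; their coefficients stay 0",
            zero_var.size,
        )

    eps = options.probability_clip
    beta = (
        np.zeros(data.n_features)
        if beta_init is None
        else np.asarray(beta_init, dtype=np.float64).copy()
    )
    beta0 = _initial_intercepts(data, eps)
    pen_Lt = None if constant_intercept else Ltilde
    obj = objective(beta0, beta, data, config, net, pen_Lt)
    trace = [obj]
    change_trace: list[float] = []
    converged = False
    n_outer = 0
    for n_outer in range(1, options.max_outer + 1):
        z, w = working_response(beta0, beta, data, eps)
        cand_beta, cand_beta0 = inner_quadratic_solve(
            XF, w, z, beta, beta0, config, net, Ltilde, options,
            constant_intercept=constant_intercept,
        )
        cand_obj = objective(cand_beta0, cand_beta, data, config, net, pen_Lt)
        if options.step_halving and cand_obj > obj:
            t = 1.0
            accepted = False
            for _ in range(20):
                t *= 0.5
                try_beta = beta + t * (cand_beta - beta)
                try_beta0 = beta0 + t * (cand_beta0 - beta0)
                try_obj = objective(try_beta0, try_beta, data, config, net, pen_Lt)
                if try_obj <= obj:
                    cand_beta, cand_beta0, cand_obj = try_beta, try_beta0, try_obj
                    accepted = True
                    break
            if not accepted:
                # no step length decreases the objective: stationary point
                converged = True
                break
        rel_change = abs(obj - cand_obj) / (1.0 + abs(obj))
        change_trace.append(float(np.max(np.abs(cand_beta - beta))) if beta.size else 0.0)
        beta, beta0, obj = cand_beta, cand_beta0, cand_obj
        trace.append(obj)
        if rel_change < options.tol_outer:
            converged = True
            break

    labels, intercepts = compute_dataset_intercepts(beta0, data.dataset_ids)
    return FitResult(
        beta=beta,
        beta0=beta0,
        dataset_labels=labels,
        dataset_intercepts=intercepts,
        objective_trace=trace,
        converged=converged,
        n_outer_iter=n_outer,
        feature_names=list(data.feature_names),
        intercept_mode=(
            "constant"
            if constant_intercept and labels.size == 1
            else "per_sample"
        ),
        max_change_trace=change_trace,
    )


def write_trace_tsv(result: FitResult, path) -> None:
    """Convergence log: outer iteration, objective, max coefficient change."""
    import pandas as pd

    n = len(result.objective_trace)
    changes = [np.nan] + list(result.max_change_trace)
    changes += [np.nan] * (n - len(changes))
    pd.DataFrame(
        {
            "iteration": range(n),
            "objective": result.objective_trace,
            "max_coef_change": changes[:n],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
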