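"""Synthetic multi-cohort expression data with TF-module structure.

The generator emulates case/control gene-expression studies built on a
transcription-factor (TF) regulatory network: ``n_TF`` TFs each regulate
``n_RG`` genes (a star forest), a TF and each of its targets are bivariate
normal with correlation ``rho`` (so conditionally the target is
``N(rho * x_TF, 1 - rho^2)`` and marginally standard normal), and only the
first four TF modules carry signal.

Two coefficient settings are provided:

- setting 1: a fixed block vector — TF weight +-sqrt(5) (modules 1-2) or
  +-sqrt(3) (modules 3-4), seven targets sharing the TF's sign at
  +-5/sqrt(10) (resp. 3/sqrt(10)) and three targets of the opposite sign;
- setting 2: the same 44-slot support with a fixed sign pattern
  (11+, 11-, 7+, 4-, 7-, 4+) and magnitudes drawn uniformly on [0, 3],
  redrawn each replicate.

Heterogeneity across the M cohorts enters through the intercepts: sample
intercepts in cohort m are N(mean_m, spread) around cohort-level means
(default -3, -1, 1, 3), and the spread 0.5 is interpreted as a VARIANCE
(sd ~ 0.707), matching the variance convention of the expression noise
term N(rho x, 0.51).  Outcomes are Bernoulli(logistic(beta0_i + X_i beta)).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import FeatureNetwork, build_normalized_laplacian

logger = logging.getLogger("intlognet")

N_SIGNAL = 44  # four signal modules of 1 TF + 10 targets each

# sign pattern of the 44 signal coefficients in setting 2
SETTING2_SIGNS = np.concatenate(
    [
        np.ones(11), -np.ones(11),
        np.ones(7), -np.ones(4),
        -np.ones(7), np.ones(4),
    ]
)


@dataclass
class SimulationConfig:
    """Study conditions for the simulation.

    ``intercept_spread`` is the variance of the per-sample intercepts
    around their cohort mean when ``spread_is_variance`` (the default);
    set ``spread_is_variance=False`` to interpret it as a standard
    deviation instead.
    """

    n_TF: int = 200
    n_RG: int = 10
    rho: float = 0.7
    setting: int = 1  # 1: fixed block coefficients, 2: signed-uniform
    intercept_means: tuple = (-3.0, -1.0, 1.0, 3.0)
    intercept_spread: float = 0.5
    spread_is_variance: bool = True
    n_train_per_dataset: int = 100
    n_test_per_dataset: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")
        if self.n_RG < 1 or self.n_TF < 1:
            raise ValueError("n_TF and n_RG must be positive")
        if self.setting not in (1, 2):
            raise ValueError("setting must be 1 or 2")
        if len(self.intercept_means) < 1:
            raise ValueError("at least one dataset (intercept mean) required")

    @property
    def n_features(self) -> int:
        return self.n_TF * (1 + self.n_RG)

    @property
    def n_datasets(self) -> int:
        return len(self.intercept_means)

    @property
    def intercept_sd(self) -> float:
        return (
            float(np.sqrt(self.intercept_spread))
            if self.spread_is_variance
            else float(self.intercept_spread)
        )


def build_tf_network(n_TF: int, n_RG: int) -> FeatureNetwork:
    """Star forest: each TF linked to its own n_RG targets.

    Feature order is TF_1, its targets, TF_2, its targets, ... so module j
    occupies the slice [j*(1+n_RG), (j+1)*(1+n_RG)).
    """
    if n_TF < 1 or n_RG < 1:
        raise ValueError("n_TF and n_RG must be positive")
    block = 1 + n_RG
    p = n_TF * block
    tf_idx = np.repeat(np.arange(n_TF) * block, n_RG)
    # target t of TF j sits at j*block + 1 + t
    tg_idx = (
        np.arange(n_TF)[:, None] * block + 1 + np.arange(n_RG)[None, :]
    ).ravel()
    names = []
    for j in range(n_TF):
        names.append(f"TF{j + 1}")
        names.extend(f"TF{j + 1}_RG{t + 1}" for t in range(n_RG))
    rows = np.concatenate([tf_idx, tg_idx])
    cols = np.concatenate([tg_idx, tf_idx])
    A = sp.coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(p, p)
    ).tocsr()
    return build_normalized_laplacian(A, node_names=names)


def draw_expression(
    config: SimulationConfig, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw an n x p expression matrix with TF-target correlation rho.

    TFs are i.i.d. N(0, 1); each target is rho * TF + N(0, 1 - rho^2), so
    targets are marginally N(0, 1) and correlate rho with their TF.
    """
    n_TF, n_RG, rho = config.n_TF, config.n_RG, config.rho
    block = 1 + n_RG
    X = np.empty((n_samples, config.n_features))
    tf_vals = rng.standard_normal((n_samples, n_TF))
    noise_sd = np.sqrt(1.0 - rho**2)
    for j in range(n_TF):
        X[:, j * block] = tf_vals[:, j]
        X[:, j * block + 1 : (j + 1) * block] = (
            rho * tf_vals[:, j][:, None]
            + noise_sd * rng.standard_normal((n_samples, n_RG))
        )
    return X


def coefficients_setting1(p: int) -> np.ndarray:
    """Fixed block coefficient vector; first 44 slots carry the signal.

    Each of the four signal modules holds the TF weight followed by seven
    targets with the TF's sign and three with the opposite sign, scaled by
    5/sqrt(10) (modules 1-2) or 3/sqrt(10) (modules 3-4).
    """
    if p < N_SIGNAL:
        raise ValueError(f"need at least {N_SIGNAL} features, got {p}")
    beta = np.zeros(p)
    blocks = []
    for scale, tf_sign in ((5.0, 1.0), (5.0, -1.0), (3.0, 1.0), (3.0, -1.0)):
        w = scale / np.sqrt(10.0)
        blocks.append(
            [tf_sign * np.sqrt(scale)]
            + [tf_sign * w] * 7
            + [-tf_sign * w] * 3
        )
    beta[:N_SIGNAL] = np.concatenate(blocks)
    return beta


def coefficients_setting2(p: int, rng: np.random.Generator) -> np.ndarray:
    """Signed-uniform coefficients: fixed sign pattern, magnitudes U[0, 3]."""
    if p < N_SIGNAL:
        raise ValueError(f"need at least {N_SIGNAL} features, got {p}")
    beta = np.zeros(p)
    beta[:N_SIGNAL] = SETTING2_SIGNS * rng.uniform(0.0, 3.0, size=N_SIGNAL)
    return beta


def _draw_dataset(
    config: SimulationConfig,
    beta: np.ndarray,
    mean_m: float,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One cohort: expression, outcomes, per-sample intercepts."""
    X = draw_expression(config, n, rng)
    beta0 = mean_m + config.intercept_sd * rng.standard_normal(n)
    prob = 1.0 / (1.0 + np.exp(-(beta0 + X @ beta)))
    Y = (rng.uniform(size=n) < prob).astype(np.float64)
    return X, Y, beta0


def simulate(
    config: SimulationConfig,
) -> tuple[list, list, np.ndarray, FeatureNetwork]:
    """Generate M train and M test cohorts plus ground truth.

    Returns ``(train, test, beta_true, net)`` where train/test are lists of
    (X, Y) pairs in cohort order.  A cohort that comes out all one class is
    redrawn with an incremented seed (at most 10 attempts).
    """
    if config.setting == 1 and config.n_RG != 10:
        raise ValueError("setting 1's fixed coefficient blocks require n_RG = 10")
    net = build_tf_network(config.n_TF, config.n_RG)
    rng = np.random.default_rng(config.seed)
    p = config.n_features
    if config.setting == 1:
        beta_true = coefficients_setting1(p)
    else:
        beta_true = coefficients_setting2(p, rng)

    train, test = [], []
    for m, mean_m in enumerate(config.intercept_means):
        for part, n, out in (
            ("train", config.n_train_per_dataset, train),
            ("test", config.n_test_per_dataset, test),
        ):
            for attempt in range(10):
                X, Y, _ = _draw_dataset(config, beta_true, mean_m, n, rng)
                if len(np.unique(Y)) == 2:
                    break
                logger.warning(
                    "cohort %d %s set drew a single class (attempt %d); redrawing",
                    m + 1, part, attempt + 1,
                )
            else:
                raise RuntimeError(
                    f"cohort {m + 1} {part} set was one-class in 10 draws; "
                    "the intercept mean is too extreme for this sample size"
                )
            out.append((X, Y))
    return train, test, beta_true, net


def write_simulation(
    outdir,
    train: Sequence[tuple],
    test: Sequence[tuple],
    beta_true: np.ndarray,
    net: FeatureNetwork,
    config: SimulationConfig,
) -> None:
    """Write cohorts as TSVs plus an edge list and a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = net.node_names or [f"f{j}" for j in range(beta_true.size)]
    for part, sets in (("train", train), ("test", test)):
        for m, (X, Y) in enumerate(sets, start=1):
            samples = [f"{part}{m}_s{i + 1}" for i in range(X.shape[0])]
            df = pd.DataFrame(X, columns=names, index=samples)
            df.index.name = "sample"
            df.to_csv(outdir / f"{part}_{m}.tsv", sep="\t", float_format="%.10g")
            lab = pd.DataFrame(
                {"sample": samples, "dataset_id": m, "Y": Y.astype(int)}
            )
            lab.to_csv(outdir / f"{part}_{m}_labels.tsv", sep="\t", index=False)
    A = sp.triu(net.adjacency).tocoo()
    edges = pd.DataFrame(
        {"nodeA": [names[i] for i in A.row], "nodeB": [names[j] for j in A.col]}
    )
    edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    pd.DataFrame({"feature": names, "beta_true": beta_true}).to_csv(
        outdir / "beta_true.tsv", sep="\t", index=False, float_format="%.12g"
    )
    manifest = {
        "n_TF": config.n_TF,
        "n_RG": config.n_RG,
        "rho": config.rho,
        "setting": config.setting,
        "intercept_means": list(config.intercept_means),
        "intercept_spread": config.intercept_spread,
        "spread_is_variance": config.spread_is_variance,
        "n_train_per_dataset": config.n_train_per_dataset,
        "n_test_per_dataset": config.n_test_per_dataset,
        "seed": config.seed,
        "n_features": config.n_features,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
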