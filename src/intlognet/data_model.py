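"""Core containers and graph constructions.

The integrative model couples two graphs: a *feature network* (e.g. a
protein-protein interaction network or a transcription-factor regulatory
network) whose normalized Laplacian enters the variable penalty, and a
*sample-relation network* connecting every pair of samples that belong to
the same dataset, whose combinatorial Laplacian shrinks per-sample
intercepts toward dataset-wise constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("intlognet")

ZERO_TOL = 1e-8
"""Coefficients with absolute value above this count as selected."""


class PenaltyKind(str, Enum):
    LASSO = "lasso"
    ENET = "enet"
    NETWORK = "network"
    ABS_NETWORK = "abs_network"


#: kinds whose penalty references the feature network Laplacian
NETWORK_KINDS = (PenaltyKind.NETWORK, PenaltyKind.ABS_NETWORK)


@dataclass
class PenaltyConfig:
    """Variable penalty (kind, alpha, lambda) plus the intercept penalty mu.

    ``alpha`` mixes the L1 part against the quadratic part exactly as in the
    elastic net: ``P_alpha(beta) = (1-alpha)/2 * Q(beta) + alpha * ||beta||_1``
    where Q is ``||beta||_2^2`` (enet), ``beta' L beta`` (network) or
    ``|beta|' L |beta|`` (abs_network). ``kind='lasso'`` forces alpha = 1.
    ``mu`` weights the sample-relation Laplacian term on the intercepts.
    """

    kind: PenaltyKind = PenaltyKind.ENET
    alpha: float = 0.5
    lam: float = 0.1
    mu: float = 1.0

    def __post_init__(self) -> None:
        self.kind = PenaltyKind(self.kind)
        if self.kind is PenaltyKind.LASSO:
            self.alpha = 1.0
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lam < 0 or self.mu < 0:
            raise ValueError("lam and mu must be nonnegative")

    @property
    def needs_network(self) -> bool:
        return self.kind in NETWORK_KINDS

    def with_lam(self, lam: float) -> "PenaltyConfig":
        return PenaltyConfig(kind=self.kind, alpha=self.alpha, lam=lam, mu=self.mu)


@dataclass
class StackedDesign:
    """Concatenated multi-dataset design matrix with dataset membership.

    Rows of ``X`` are samples, columns are features; ``Y`` holds 0/1
    outcomes; ``dataset_ids`` maps each sample to its dataset (1..M).
    """

    X: np.ndarray
    Y: np.ndarray
    dataset_ids: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(np.asarray(self.X, dtype=np.float64))
        self.Y = np.asarray(self.Y, dtype=np.float64).ravel()
        self.dataset_ids = np.asarray(self.dataset_ids, dtype=np.int64).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, p = self.X.shape
        if self.Y.shape[0] != n or self.dataset_ids.shape[0] != n:
            raise ValueError("X, Y and dataset_ids must agree on sample count")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values; impute first")
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise ValueError("Y must contain only 0/1")
        if (self.dataset_ids < 1).any():
            raise ValueError("dataset ids must be positive integers")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(p)]
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal the column count")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature_names must be unique")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def dataset_labels(self) -> np.ndarray:
        """Sorted distinct dataset ids present."""
        return np.unique(self.dataset_ids)

    @property
    def n_datasets(self) -> int:
        return self.dataset_labels.size

    def group_sizes(self) -> np.ndarray:
        """Per-dataset sample counts N^m, in dataset-label order."""
        return np.array(
            [(self.dataset_ids == m).sum() for m in self.dataset_labels]
        )


@dataclass
class FeatureNetwork:
    """Undirected feature graph: adjacency, degrees, normalized Laplacian.

    ``L = I - D^{-1/2} A D^{-1/2}`` with the convention that rows/columns of
    isolated nodes (degree 0) are identically zero, so isolated features
    contribute nothing to the Laplacian quadratic form.
    """

    adjacency: sp.csr_matrix
    degrees: np.ndarray
    laplacian: sp.csr_matrix
    node_names: Optional[list[str]] = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def laplacian_quadform(self, v: np.ndarray) -> float:
        return float(v @ (self.laplacian @ v))


def build_normalized_laplacian(
    A, node_names: Optional[Sequence[str]] = None
) -> FeatureNetwork:
    """Build a :class:`FeatureNetwork` from a symmetric adjacency matrix.

    Accepts a dense array or any scipy sparse matrix. Weights must be
    nonnegative, the diagonal zero, and the matrix symmetric.
    """
    A = sp.csr_matrix(A, dtype=np.float64)
    A.eliminate_zeros()
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if A.diagonal().any():
        raise ValueError("adjacency must have a zero diagonal")
    if A.data.size and A.data.min() < 0:
        raise ValueError("adjacency weights must be nonnegative")
    if (A != A.T).nnz != 0:
        raise ValueError("adjacency must be symmetric")
    d = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dis = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    Dn = sp.diags(dis)
    L = sp.diags((d > 0).astype(np.float64)) - Dn @ A @ Dn
    names = list(node_names) if node_names is not None else None
    if names is not None and len(names) != A.shape[0]:
        raise ValueError("node_names length must match adjacency size")
    return FeatureNetwork(
        adjacency=A, degrees=d, laplacian=sp.csr_matrix(L), node_names=names
    )


def feature_network_from_edges(
    edges: Sequence[tuple],
    feature_names: Sequence[str],
) -> FeatureNetwork:
    """Build a network over ``feature_names`` from (u, v[, weight]) pairs.

    Edge endpoints not among ``feature_names`` are dropped with a warning —
    the standard situation when a genome-wide interaction network is matched
    against a filtered expression matrix.
    """
    names = list(feature_names)
    index = {g: j for j, g in enumerate(names)}
    p = len(names)
    rows, cols, vals = [], [], []
    n_dropped = 0
    for e in edges:
        u, v = e[0], e[1]
        w = float(e[2]) if len(e) > 2 else 1.0
        if u not in index or v not in index:
            n_dropped += 1
            continue
        if u == v:
            continue
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    if n_dropped:
        logger.warning(
            "dropped %d network edges with endpoints outside the feature set",
            n_dropped,
        )
    A = sp.coo_matrix((vals, (rows, cols)), shape=(p, p)).tocsr()
    # parallel edges collapse by summation in COO->CSR; dedupe to max weight
    A.sum_duplicates()
    return build_normalized_laplacian(A, node_names=names)


@dataclass
class SampleRelationLaplacian:
    """Block-diagonal Laplacian of within-dataset complete graphs.

    The quadratic form ``beta0' Ltilde beta0`` equals the sum over datasets
    of all pairwise squared intercept differences, so it vanishes exactly
    when intercepts are constant within every dataset.  ``normalized=True``
    rescales each block by 1/(N^m - 1) (the complete-graph normalized
    Laplacian); the combinatorial form is the default.
    """

    dataset_ids: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.dataset_ids = np.asarray(self.dataset_ids, dtype=np.int64).ravel()
        if self.dataset_ids.size == 0:
            raise ValueError("dataset_ids must be non-empty")
        if (self.dataset_ids < 1).any():
            raise ValueError("dataset ids must be positive integers")
        self.labels = np.unique(self.dataset_ids)
        self.blocks = [np.flatnonzero(self.dataset_ids == m) for m in self.labels]

    @property
    def n_samples(self) -> int:
        return self.dataset_ids.size

    def block_scale(self, block_size: int) -> float:
        """Scale factor relating the block to ``n I - J`` (see matrix())."""
        if self.normalized:
            return 1.0 / (block_size - 1) if block_size > 1 else 0.0
        return 1.0

    def matrix(self) -> np.ndarray:
        """Dense N x N Laplacian (diagnostics / small problems only)."""
        n = self.n_samples
        Lt = np.zeros((n, n))
        for idx in self.blocks:
            nb = idx.size
            c = self.block_scale(nb)
            block = c * (nb * np.eye(nb) - np.ones((nb, nb)))
            Lt[np.ix_(idx, idx)] = block
        return Lt

    def quadform(self, beta0: np.ndarray) -> float:
        """beta0' Ltilde beta0, computed blockwise in O(N)."""
        beta0 = np.asarray(beta0, dtype=np.float64).ravel()
        total = 0.0
        for idx in self.blocks:
            b = beta0[idx]
            nb = idx.size
            # n * sum (b - mean)^2  ==  sum_{i<j} (b_i - b_j)^2
            total += self.block_scale(nb) * nb * float(
                np.sum((b - b.mean()) ** 2)
            )
        return total


def build_sample_laplacian(
    dataset_ids: Sequence[int], normalized: bool = False
) -> SampleRelationLaplacian:
    """Laplacian of the sample-relation network (complete graph per dataset)."""
    return SampleRelationLaplacian(np.asarray(dataset_ids), normalized=normalized)


@dataclass
class FitResult:
    """Fitted model: shared coefficients plus per-sample intercepts.

    ``dataset_intercepts[m]`` is the arithmetic mean of ``beta0`` over the
    samples of dataset m; prediction for new samples from a known dataset
    uses this averaged intercept.
    """

    beta: np.ndarray
    beta0: np.ndarray
    dataset_labels: np.ndarray
    dataset_intercepts: np.ndarray
    objective_trace: list[float]
    converged: bool
    n_outer_iter: int
    feature_names: list[str] = field(default_factory=list)
    intercept_mode: str = "per_sample"  # or "constant"
    max_change_trace: list[float] = field(default_factory=list)

    def selected_support(self, zero_tol: float = ZERO_TOL) -> np.ndarray:
        """Indices of features with |beta_k| > zero_tol."""
        return np.flatnonzero(np.abs(self.beta) > zero_tol)

    def intercept_for(self, dataset_id: int) -> float:
        if self.intercept_mode == "constant":
            return float(self.dataset_intercepts[0])
        pos = np.flatnonzero(self.dataset_labels == dataset_id)
        if pos.size == 0:
            raise KeyError(dataset_id)
        return float(self.dataset_intercepts[pos[0]])


def compute_dataset_intercepts(
    beta0: np.ndarray, dataset_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average per-sample intercepts within each dataset."""
    labels = np.unique(dataset_ids)
    means = np.array([beta0[dataset_ids == m].mean() for m in labels])
    return labels, means
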