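import numpy as np
import pytest

from intlognet.data_model import PenaltyConfig, StackedDesign, build_normalized_laplacian


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_logistic_data(rng, n=60, p=5, beta=None, intercept=0.0):
    """Small single-cohort logistic sample with known coefficients."""
    X = rng.standard_normal((n, p))
    if beta is None:
        beta = np.zeros(p)
        beta[: min(3, p)] = [1.5, -1.0, 0.75][: min(3, p)]
    eta = intercept + X @ beta
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    if len(np.unique(y)) < 2:  # pragma: no cover - guard for extreme draws
        y[0], y[1] = 0.0, 1.0
    return X, y, np.asarray(beta, dtype=float)


@pytest.fixture
def two_cohorts(rng):
    """Two small heterogeneous cohorts sharing coefficients."""
    beta = np.array([1.2, -0.8, 0.0, 0.6, 0.0])
    X1, y1, _ = make_logistic_data(rng, n=50, p=5, beta=beta, intercept=-1.0)
    X2, y2, _ = make_logistic_data(rng, n=60, p=5, beta=beta, intercept=1.0)
    return [(X1, y1), (X2, y2)], beta


@pytest.fixture
def stacked(two_cohorts):
    datasets, _ = two_cohorts
    X = np.vstack([d[0] for d in datasets])
    Y = np.concatenate([d[1] for d in datasets])
    ids = np.concatenate(
        [np.full(len(d[1]), m + 1) for m, d in enumerate(datasets)]
    )
    return StackedDesign(X=X, Y=Y, dataset_ids=ids)


def random_graph(rng, p, density=0.3):
    """Random symmetric 0/1 adjacency with zero diagonal."""
    A = (rng.uniform(size=(p, p)) < density).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    return A


@pytest.fixture
def line_network():
    """Path graph on 4 nodes as a FeatureNetwork."""
    A = np.zeros((4, 4))
    for i in range(3):
        A[i, i + 1] = A[i + 1, i] = 1.0
    return build_normalized_laplacian(A)


def enet_config(lam=0.1, alpha=0.5, mu=1.0):
    return PenaltyConfig(kind="enet", alpha=alpha, lam=lam, mu=mu)
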