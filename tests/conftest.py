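import numpy as np
import pytest

from linprob.model import BINARY_PM1, CONSTANT, CONTINUOUS, BinaryDataset
from linprob.simulate import CovariateSpec, SimulationSpec


def make_data(X, y, meta=None, names=None) -> BinaryDataset:
    """Construct a BinaryDataset directly from arrays (no missingness)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if meta is None:
        meta = []
        for j in range(p):
            col = X[:, j]
            if np.all(col == col[0]):
                meta.append(CONSTANT)
            elif np.all(np.isin(col, (-1.0, 1.0))):
                meta.append(BINARY_PM1)
            else:
                meta.append(CONTINUOUS)
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    return BinaryDataset(
        y=np.asarray(y, dtype=float),
        X=X,
        missing_mask=np.zeros((n, p), dtype=bool),
        column_meta=tuple(meta),
        column_names=tuple(names),
    )


def scaled_spec(n, seed, target, margin=0.01) -> SimulationSpec:
    """Mixed binary/continuous spec whose worst-corner |beta'x| equals target."""
    covs = (
        CovariateSpec("b1", BINARY_PM1, p_success=0.4),
        CovariateSpec("c1", CONTINUOUS, lower=-1.0, upper=1.0),
        CovariateSpec("c2", CONTINUOUS, lower=0.0, upper=1.0),
    )
    beta0 = np.array([0.1, 0.15, 0.5, 0.3])
    probe = SimulationSpec(
        n=n, covariate_specs=covs, beta=tuple(beta0), seed=seed, margin=margin
    )
    beta = beta0 * (target / probe.worst_corner())
    return SimulationSpec(
        n=n, covariate_specs=covs, beta=tuple(beta), seed=seed, margin=margin
    )


def draw_outcomes(delta, n_reps, rng):
    """Outcome matrix (n x n_reps) from pr(Y=+1) = (1+delta)/2."""
    u = rng.random((delta.size, n_reps))
    return np.where(u < ((1.0 + delta) / 2.0)[:, None], 1.0, -1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
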