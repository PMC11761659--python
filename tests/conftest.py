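import numpy as np
import pytest
from scipy.linalg import block_diag
from scipy.stats import multivariate_normal

from hdlmm.data import ClusteredData
from hdlmm.likelihood import ModelParams, VarParams, n_var_params


def random_clustered(
    rng,
    g=3,
    n_i=4,
    p=6,
    q=1,
    structure="scalar",
    sigma2=1.0,
    theta_scale=0.7,
):
    """A small random data set with intercept-first layout and Z = X[:, :q]."""
    N = g * n_i
    X = np.hstack([np.ones((N, 1)), rng.standard_normal((N, p - 1))])
    Z = X[:, :q]
    groups = np.repeat(np.arange(g), n_i)
    qs = n_var_params(structure, q)
    theta = theta_scale * np.abs(rng.standard_normal(qs))
    var = VarParams(structure=structure, theta=theta, sigma2=sigma2, q=q)
    beta = np.zeros(p)
    beta[: min(3, p)] = rng.standard_normal(min(3, p))
    L = var.cholesky()
    b = rng.standard_normal((g, q)) @ L.T
    y = X @ beta + np.einsum("ij,ij->i", Z, b[groups])
    y = y + np.sqrt(sigma2) * rng.standard_normal(N)
    data = ClusteredData(X=X, Z=Z, y=y, groups=groups, nonpen=frozenset(range(q)))
    return data, ModelParams(beta=beta, var=var)


def dense_neg_loglik(params, data):
    """Stacked-system -log density oracle, independent of hdlmm internals."""
    psi = params.var.psi()
    blocks = []
    for idx in data.cluster_indices:
        Zi = data.Z[idx]
        blocks.append(Zi @ psi @ Zi.T + params.var.sigma2 * np.eye(len(idx)))
    V = block_diag(*blocks)
    mean = data.X @ params.beta
    return -multivariate_normal.logpdf(data.y, mean=mean, cov=V)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
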