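"""Synthetic omics data generators for the three study designs.

Three design-matrix families are emulated, each paired with a response
drawn from the linear mixed-effects model y_i = X_i beta + Z_i b_i + eps_i
with b_i ~ N_q(0, Psi) per cluster and i.i.d. N(0, sigma2) errors:

* ``gene_expression`` — rows i.i.d. multivariate normal with AR(1)
  inter-feature correlation Cov(x_j, x_j') = rho^|j-j'|, mimicking
  normalized transcriptome profiles.
* ``gwas`` — minor-allele-count genotypes in {0, 1, 2}: per-SNP minor
  allele frequency f_j ~ Uniform(0.05, 0.5) and counts Binomial(2, f_j),
  with clusters standing in for discrete (sub)populations whose shared
  deviations are carried by the random effects.
* ``microbiome`` — OTU counts with graph-structured inter-OTU dependence:
  a latent Gaussian copula whose correlation derives from a named network
  topology, zero-inflated negative-binomial marginals (sparse and right
  skewed), pseudo-counts of 0.5 on zeros, and a log-ratio transform
  against the last OTU as reference; one additional covariate is constant
  within each cluster.

Column convention: the intercept is the FIRST column of X, the random-slope
features immediately follow, so Z = X[:, :q] and the nonzero entries of the
generating beta occupy the leading positions. All generators are driven by
a single seeded ``numpy.random.Generator``; regeneration from the same
``SimSetting`` is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import networkx as nx
from scipy import stats
from scipy.linalg import cholesky

from .data import ClusteredData
from .likelihood import ModelParams, VarParams, tril_indices_colmajor

__all__ = [
    "SimSetting",
    "SimDataset",
    "simulate",
    "simulate_gene_expression",
    "simulate_gwas",
    "simulate_microbiome",
    "generate_network_precision",
    "generate_response",
    "gene_expression_setting",
    "gwas_setting",
    "microbiome_setting",
    "GENE_EXPRESSION_TABLE",
]

BETA_FIVE = (1.0, 2.0, 4.0, 3.0, 3.0)
BETA_TEN = (1.0, 2.0, 4.0, 3.0, 3.0, -1.0, 5.0, -3.0, 2.0, 2.0)

#: (N, g, p, q, rho, n_effects, structure) for the fourteen named
#: gene-expression settings.
GENE_EXPRESSION_TABLE = {
    1: (180, 30, 500, 1, 0.0, 5, "scalar"),
    2: (180, 30, 500, 1, 0.6, 5, "scalar"),
    3: (250, 50, 1000, 1, 0.0, 5, "scalar"),
    4: (250, 50, 1000, 1, 0.6, 5, "scalar"),
    5: (250, 50, 1000, 1, 0.0, 10, "scalar"),
    6: (250, 50, 1000, 1, 0.6, 10, "scalar"),
    7: (250, 50, 1000, 3, 0.0, 10, "scalar"),
    8: (250, 50, 1000, 3, 0.6, 10, "scalar"),
    9: (250, 50, 1000, 3, 0.0, 10, "diagonal"),
    10: (250, 50, 1000, 3, 0.6, 10, "diagonal"),
    11: (250, 50, 1000, 3, 0.0, 10, "unstructured"),
    12: (250, 50, 1000, 3, 0.6, 10, "unstructured"),
    13: (250, 50, 1000, 5, 0.0, 10, "scalar"),
    14: (250, 50, 1000, 5, 0.6, 10, "scalar"),
}

DEFAULT_PSI_SCALAR = 0.56
DEFAULT_SIGMA2 = 0.5
#: copula-marginal defaults for the microbiome counts: zero-inflation
#: probability range, log-mean range of the negative-binomial component,
#: and its size (dispersion) parameter
DEFAULT_MICROBIOME_MARGINAL = {
    "zi_low": 0.4,
    "zi_high": 0.8,
    "log_mu_low": np.log(5.0),
    "log_mu_high": np.log(200.0),
    "nb_size": 0.5,
}


def _default_psi(cov_structure: str, q: int) -> np.ndarray:
    """Generating random-effect covariance by structure."""
    if cov_structure == "scalar":
        return DEFAULT_PSI_SCALAR * np.eye(q)
    if cov_structure == "diagonal":
        return np.diag(np.full(q, DEFAULT_PSI_SCALAR))
    psi = np.full((q, q), 0.2)
    np.fill_diagonal(psi, DEFAULT_PSI_SCALAR)
    return psi


def _theta_from_psi(psi: np.ndarray, structure: str, q: int) -> np.ndarray:
    L = cholesky(psi, lower=True)
    if structure == "scalar":
        return np.array([L[0, 0]])
    if structure == "diagonal":
        return np.diag(L).copy()
    r, c = tril_indices_colmajor(q)
    return L[r, c]


@dataclass(frozen=True)
class SimSetting:
    """Complete recipe (including the seed) for one synthetic data set."""

    study: str  # gene_expression | gwas | microbiome
    N: int
    g: int
    p: int
    q: int
    rho: float = 0.0
    n_nonzero: int = 5
    beta_nonzero: tuple = BETA_FIVE
    cov_structure: str = "scalar"
    psi: np.ndarray | None = None
    sigma2: float = DEFAULT_SIGMA2
    network: str | None = None  # microbiome only
    group_level_coef: float = -1.0  # microbiome only
    marginal: dict = field(default_factory=lambda: dict(DEFAULT_MICROBIOME_MARGINAL))
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        if self.study not in ("gene_expression", "gwas", "microbiome"):
            raise ValueError(f"unknown study {self.study!r}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.n_nonzero != len(self.beta_nonzero):
            raise ValueError("n_nonzero must equal len(beta_nonzero)")
        if self.N % self.g:
            raise ValueError("N must be divisible by g (equal cluster sizes)")
        psi = self.psi if self.psi is not None else _default_psi(
            self.cov_structure, self.q
        )
        psi = np.atleast_2d(np.asarray(psi, dtype=float))
        if psi.shape != (self.q, self.q):
            raise ValueError(f"psi must be {self.q}x{self.q}")
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "beta_nonzero", tuple(self.beta_nonzero))

    def true_var_params(self) -> VarParams:
        return VarParams(
            structure=self.cov_structure,
            theta=_theta_from_psi(self.psi, self.cov_structure, self.q),
            sigma2=self.sigma2,
            q=self.q,
        )


@dataclass(frozen=True)
class SimDataset:
    """A simulated data set together with its generating truth."""

    data: ClusteredData
    beta_true: np.ndarray
    params_true: ModelParams
    setting: SimSetting
    b_true: np.ndarray  # g x q matrix of drawn random effects
    extras: dict = field(default_factory=dict, repr=False)


def gene_expression_setting(k: int, seed: int = 0, **overrides) -> SimSetting:
    """Named gene-expression setting 1..14."""
    N, g, p, q, rho, n_eff, structure = GENE_EXPRESSION_TABLE[k]
    beta = BETA_FIVE if n_eff == 5 else BETA_TEN
    kw = dict(
        study="gene_expression", N=N, g=g, p=p, q=q, rho=rho,
        n_nonzero=n_eff, beta_nonzero=beta, cov_structure=structure,
        seed=seed, name=f"ge{k}",
    )
    kw.update(overrides)
    return SimSetting(**kw)


def gwas_setting(
    q: int = 3, cov_structure: str = "scalar", seed: int = 0, **overrides
) -> SimSetting:
    """GWAS design: 250 samples, 1000 columns, 10 populations of 25."""
    kw = dict(
        study="gwas", N=250, g=10, p=1000, q=q, n_nonzero=10,
        beta_nonzero=BETA_TEN, cov_structure=cov_structure, seed=seed,
        name=f"gwas_q{q}_{cov_structure}",
    )
    kw.update(overrides)
    return SimSetting(**kw)


def microbiome_setting(
    network: str = "band",
    q: int = 3,
    cov_structure: str = "scalar",
    seed: int = 0,
    n_otu: int = 127,
    **overrides,
) -> SimSetting:
    """Microbiome design: 120 samples, n_otu OTUs, 10 clusters of 12.

    p counts the intercept, the n_otu - 1 log-ratio features and the
    group-level covariate.
    """
    kw = dict(
        study="microbiome", N=120, g=10, p=n_otu + 1, q=q, n_nonzero=10,
        beta_nonzero=BETA_TEN, cov_structure=cov_structure, network=network,
        seed=seed, name=f"otu_{network}_q{q}_{cov_structure}",
    )
    kw.update(overrides)
    return SimSetting(**kw)


def generate_response(
    X: np.ndarray,
    Z: np.ndarray,
    groups: np.ndarray,
    params_true: ModelParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw y = X beta + Z b_i + eps from the mixed model.

    Returns (y, b) where b stacks the per-cluster random-effect draws
    (g x q). A degenerate model (Psi = 0, sigma2 = 0) returns X beta
    exactly.
    """
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    groups = np.asarray(groups)
    codes = np.unique(groups, return_inverse=True)[1]
    g = codes.max() + 1
    q = Z.shape[1]
    psi = params_true.var.psi()
    if not np.all(np.isfinite(psi)):
        raise ValueError("Psi must be finite")
    eig = np.linalg.eigvalsh(psi)
    if eig.min() < -1e-10:
        raise ValueError("Psi must be positive semidefinite")
    L = params_true.var.cholesky()
    b = rng.standard_normal((g, q)) @ L.T
    sigma = np.sqrt(params_true.var.sigma2)
    eps = sigma * rng.standard_normal(X.shape[0]) if sigma > 0 else 0.0
    y = X @ params_true.beta + np.einsum("ij,ij->i", Z, b[codes]) + eps
    return y, b


def _assemble(
    features: np.ndarray, setting: SimSetting, rng: np.random.Generator,
    group_covariate: np.ndarray | None = None, extras: dict | None = None,
) -> SimDataset:
    """Stack [intercept | features (| group covariate)], draw the response."""
    N = setting.N
    cols = [np.ones((N, 1)), features]
    if group_covariate is not None:
        cols.append(group_covariate[:, None])
    X = np.hstack(cols)
    if X.shape[1] != setting.p:
        raise ValueError(
            f"assembled design has {X.shape[1]} columns, expected {setting.p}"
        )
    Z = X[:, : setting.q]
    groups = np.repeat(np.arange(setting.g), N // setting.g)

    beta_true = np.zeros(setting.p)
    beta_true[: setting.n_nonzero] = setting.beta_nonzero
    nonpen = set(range(setting.q))
    if group_covariate is not None:
        beta_true[-1] = setting.group_level_coef
        nonpen.add(setting.p - 1)

    params_true = ModelParams(beta=beta_true, var=setting.true_var_params())
    y, b = generate_response(X, Z, groups, params_true, rng)
    data = ClusteredData(X=X, Z=Z, y=y, groups=groups, nonpen=frozenset(nonpen))
    return SimDataset(
        data=data, beta_true=beta_true, params_true=params_true,
        setting=setting, b_true=b, extras=extras or {},
    )


def simulate_gene_expression(setting: SimSetting) -> SimDataset:
    """AR(1)-correlated Gaussian expression profiles.

    The p-1 feature columns are generated by the stationary recursion
    x_1 ~ N(0,1), x_j = rho x_{j-1} + sqrt(1-rho^2) N(0,1), which yields
    exactly the Cov(x_j, x_j') = rho^|j-j'| law with unit marginals.
    """
    if setting.study != "gene_expression":
        raise ValueError("setting.study must be 'gene_expression'")
    rng = np.random.default_rng(setting.seed)
    N, m = setting.N, setting.p - 1
    rho = setting.rho
    innovations = rng.standard_normal((N, m))
    features = np.empty((N, m))
    features[:, 0] = innovations[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        features[:, j] = rho * features[:, j - 1] + scale * innovations[:, j]
    return _assemble(features, setting, rng)


def simulate_gwas(setting: SimSetting) -> SimDataset:
    """Genotype design: minor-allele counts Binomial(2, f_j), f_j ~ U(.05, .5)."""
    if setting.study != "gwas":
        raise ValueError("setting.study must be 'gwas'")
    rng = np.random.default_rng(setting.seed)
    N, m = setting.N, setting.p - 1
    maf = rng.uniform(0.05, 0.5, size=m)
    genotypes = rng.binomial(2, maf, size=(N, m)).astype(float)
    return _assemble(genotypes, setting, rng, extras={"maf": maf})


def generate_network_precision(
    p_otu: int,
    network: str,
    edge_strength: float = 0.3,
    seed: int = 0,
    bandwidth: int = 2,
    n_blocks: int | None = None,
    edge_prob: float | None = None,
    diag_boost: float = 0.15,
) -> np.ndarray:
    """Graph-structured inter-OTU correlation matrix.

    Builds the adjacency of the named topology, assigns random-signed edge
    weights of magnitude ``edge_strength``, diagonally dominates to a
    positive-definite precision matrix, inverts, and rescales to unit
    diagonal. Returns the p_otu x p_otu correlation matrix.
    """
    if p_otu < 4:
        raise ValueError("p_otu must be at least 4")
    rng = np.random.default_rng(seed)
    p = p_otu
    edges: list[tuple[int, int]] = []
    if network == "band":
        if bandwidth < 1:
            raise ValueError("bandwidth must be >= 1")
        edges = [
            (i, j) for i in range(p) for j in range(i + 1, min(i + bandwidth + 1, p))
        ]
    elif network in ("cluster", "block"):
        k = n_blocks if n_blocks is not None else max(2, p // 25)
        sizes = np.full(k, p // k)
        sizes[: p % k] += 1
        start = 0
        members = []
        for s in sizes:
            members.append(range(start, start + s))
            start += s
        for grp in members:
            grp = list(grp)
            if network == "cluster":
                # dense within-block connectivity
                edges += [(i, j) for a, i in enumerate(grp) for j in grp[a + 1:]]
            else:
                # sparser within-block edges plus rare between-block links
                for a, i in enumerate(grp):
                    for j in grp[a + 1:]:
                        if rng.random() < 0.5:
                            edges.append((i, j))
        if network == "block":
            for _ in range(p // 10):
                i, j = rng.integers(0, p, 2)
                if i != j:
                    edges.append((min(i, j), max(i, j)))
    elif network == "scale_free":
        G = nx.barabasi_albert_graph(p, 2, seed=int(rng.integers(2**31)))
        edges = list(G.edges())
    elif network == "erdos_renyi":
        prob = edge_prob if edge_prob is not None else 4.0 / p
        G = nx.gnp_random_graph(p, prob, seed=int(rng.integers(2**31)))
        edges = list(G.edges())
    elif network == "hub":
        # union of stars: one hub per group of ~20 nodes
        k = max(2, p // 20)
        sizes = np.full(k, p // k)
        sizes[: p % k] += 1
        start = 0
        for s in sizes:
            hub = start
            edges += [(hub, j) for j in range(start + 1, start + s)]
            start += s
    else:
        raise ValueError(f"unknown network topology {network!r}")
    if not edges:
        raise ValueError(f"{network} topology produced no edges for p={p}")

    W = np.zeros((p, p))
    for i, j in edges:
        w = edge_strength * rng.choice([-1.0, 1.0])
        W[i, j] = W[j, i] = w
    # Gershgorin: diagonal strictly dominates the absolute row sums
    omega = W.copy()
    np.fill_diagonal(omega, np.abs(W).sum(axis=1) + diag_boost)
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def _copula_counts(
    latent: np.ndarray, marginal: dict, rng: np.random.Generator
) -> np.ndarray:
    """Map latent standard-normal columns to ZINB counts via their CDF."""
    N, p = latent.shape
    u = stats.norm.cdf(latent)
    pi = rng.uniform(marginal["zi_low"], marginal["zi_high"], size=p)
    mu = np.exp(rng.uniform(marginal["log_mu_low"], marginal["log_mu_high"], size=p))
    size = marginal["nb_size"]
    nb_p = size / (size + mu)  # scipy's success-probability convention
    counts = np.zeros((N, p))
    for j in range(p):
        mask = u[:, j] > pi[j]
        if mask.any():
            uu = (u[mask, j] - pi[j]) / (1.0 - pi[j])
            uu = np.clip(uu, 1e-12, 1.0 - 1e-12)
            counts[mask, j] = stats.nbinom.ppf(uu, size, nb_p[j])
    return counts


def simulate_microbiome(setting: SimSetting) -> SimDataset:
    """OTU counts with network-structured dependence, log-ratio transformed.

    Counts come from a Gaussian copula over the network correlation with
    zero-inflated negative-binomial marginals; zeros get a pseudo-count of
    0.5 before x_ij = log(c_ij / c_i,ref) with the last OTU as reference.
    An extra covariate constant within each cluster carries an unpenalized
    group-level fixed effect.
    """
    if setting.study != "microbiome":
        raise ValueError("setting.study must be 'microbiome'")
    if setting.network is None:
        raise ValueError("microbiome setting requires a network topology")
    rng = np.random.default_rng(setting.seed)
    N = setting.N
    n_otu = setting.p - 1  # intercept and group covariate replace the reference
    corr = generate_network_precision(
        n_otu, setting.network, seed=int(rng.integers(2**31))
    )
    L = cholesky(corr, lower=True)

    counts = np.empty((N, n_otu))
    pending = np.arange(N)
    for _ in range(50):  # resample all-zero rows (bounded retries)
        latent = rng.standard_normal((len(pending), n_otu)) @ L.T
        counts[pending] = _copula_counts(latent, setting.marginal, rng)
        pending = pending[~counts[pending].any(axis=1)]
        if len(pending) == 0:
            break
    else:
        raise RuntimeError("all-zero OTU rows persisted after bounded retries")

    pseudo = np.where(counts == 0, 0.5, counts)
    logratio = np.log(pseudo[:, :-1] / pseudo[:, -1:])  # last OTU is reference

    group_values = rng.standard_normal(setting.g)
    group_covariate = np.repeat(group_values, N // setting.g)
    return _assemble(
        logratio, setting, rng, group_covariate=group_covariate,
        extras={"counts": counts},
    )


_DISPATCH = {
    "gene_expression": simulate_gene_expression,
    "gwas": simulate_gwas,
    "microbiome": simulate_microbiome,
}


def simulate(setting: SimSetting) -> SimDataset:
    """Generate the data set described by ``setting``."""
    return _DISPATCH[setting.study](setting)


def with_seed(setting: SimSetting, seed: int) -> SimSetting:
    return replace(setting, seed=seed)
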