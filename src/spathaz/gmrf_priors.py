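"""Prior models: Gaussian fixed effects, RW1/RW2/ICAR GMRF kernels, the
penalized-complexity prior for the Weibull shape, and log-gamma hyperpriors.

All GMRF priors are intrinsic (rank-deficient). Their log kernels are
returned unnormalized up to the precision-dependent factor
``(rank/2) log tau`` so that the Gibbs full conditionals of the precisions
follow directly from the quadratic forms:

* RW2 on psi (length r):   rank r-2, quadratic form  sum (psi_v - 2 psi_{v+1} + psi_{v+2})^2
* RW1 on c (length K):     rank K-1, quadratic form  sum (c_k - c_{k-1})^2
* ICAR on theta (graph G): rank G - n_components, quadratic form theta' (D - W) theta
                           = sum over edges (theta_i - theta_j)^2

The intrinsic-CAR precision is Q = tau (D - W): symmetric, Q 1 = 0, and the
conditional-independence (Markov) structure matches the adjacency graph.
Sum-to-zero constraints (per connected component for ICAR) remove the
improper null spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import digamma, gammaln

from .core_data import AdjacencyGraph

_RANK_TOL = 1e-9


# ---------------------------------------------------------------------------
# structure matrices and spectral helpers
# ---------------------------------------------------------------------------


def rw1_structure(k: int) -> np.ndarray:
    """K = D1' D1 with D1 the (k-1) x k first-difference operator."""
    if k < 2:
        raise ValueError("RW1 needs length >= 2")
    d1 = np.diff(np.eye(k), axis=0)
    return d1.T @ d1


def rw2_structure(r: int) -> np.ndarray:
    """K = D2' D2 with D2 the (r-2) x r second-difference operator."""
    if r < 3:
        raise ValueError("RW2 needs length >= 3")
    d2 = np.diff(np.eye(r), n=2, axis=0)
    return d2.T @ d2


def icar_structure(graph: AdjacencyGraph) -> np.ndarray:
    """The graph Laplacian D - W (precision structure of the intrinsic CAR)."""
    return graph.D - graph.W.astype(float)


def icar_precision(graph: AdjacencyGraph, tau: float) -> sparse.csr_matrix:
    """Sparse intrinsic-CAR precision Q = tau (D - W).

    Symmetric with Q 1 = 0 per connected component and
    rank G - (#components).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    return sparse.csr_matrix(tau * icar_structure(graph))


@dataclass(frozen=True)
class GMRFSpectrum:
    """Eigendecomposition of an intrinsic structure matrix, split by rank.

    Used for pseudo-determinants, constrained sampling, and structured
    Metropolis proposals. ``vectors`` spans the complement of the null
    space; ``null_vectors`` spans the (improper) null space.
    """

    values: np.ndarray  # positive eigenvalues, ascending
    vectors: np.ndarray  # (dim, rank)
    null_vectors: np.ndarray  # (dim, dim - rank), orthonormal

    @property
    def rank(self) -> int:
        return len(self.values)

    @property
    def dim(self) -> int:
        return self.vectors.shape[0]

    @property
    def log_pdet(self) -> float:
        """log pseudo-determinant of the unit-precision structure matrix."""
        return float(np.sum(np.log(self.values)))

    def sample(self, tau: float, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Draw from the intrinsic GMRF with precision tau * structure,
        restricted to the complement of the null space (covariance equals
        the scaled pseudo-inverse)."""
        if tau <= 0:
            raise ValueError("tau must be positive")
        shape = (self.rank,) if size is None else (size, self.rank)
        z = rng.standard_normal(shape) / np.sqrt(tau * self.values)
        return z @ self.vectors.T

    def project(self, x: np.ndarray) -> np.ndarray:
        """Remove the null-space component (e.g. enforce sum-to-zero)."""
        return x - (x @ self.null_vectors) @ self.null_vectors.T


def gmrf_spectrum(structure: np.ndarray) -> GMRFSpectrum:
    vals, vecs = np.linalg.eigh(np.asarray(structure, dtype=float))
    tol = _RANK_TOL * max(1.0, float(vals.max(initial=1.0)))
    keep = vals > tol
    return GMRFSpectrum(
        values=vals[keep], vectors=vecs[:, keep], null_vectors=vecs[:, ~keep]
    )


def log_pdet(structure: np.ndarray) -> float:
    return gmrf_spectrum(structure).log_pdet


# ---------------------------------------------------------------------------
# log prior kernels
# ---------------------------------------------------------------------------


def beta_log_prior(beta: np.ndarray, variance: float = 100.0) -> float:
    """Weakly informative independent N(0, variance) prior, i.e. N_p(0, 100 I)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    p = beta.size
    return float(
        -0.5 * p * np.log(2 * np.pi * variance) - 0.5 * beta @ beta / variance
    )


def rw2_log_prior(psi: np.ndarray, tau: float) -> float:
    """Second-order random-walk kernel
    ((r-2)/2) log tau - (tau/2) sum_v (psi_v - 2 psi_{v+1} + psi_{v+2})^2.

    Invariant under adding any a + b*v linear trend to psi.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    psi = np.asarray(psi, dtype=float)
    r = psi.size
    if r < 3:
        raise ValueError("RW2 needs length >= 3")
    quad = float(np.sum(np.diff(psi, n=2) ** 2))
    return 0.5 * (r - 2) * np.log(tau) - 0.5 * tau * quad


def rw1_log_prior(c: np.ndarray, tau: float) -> float:
    """First-order random-walk kernel
    ((K-1)/2) log tau - (tau/2) sum_k (c_k - c_{k-1})^2."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    c = np.asarray(c, dtype=float)
    if c.size < 2:
        raise ValueError("RW1 needs length >= 2")
    quad = float(np.sum(np.diff(c) ** 2))
    return 0.5 * (c.size - 1) * np.log(tau) - 0.5 * tau * quad


def icar_log_prior(
    theta: np.ndarray,
    Q: np.ndarray | sparse.spmatrix,
    constraint_tol: float = 1e-8,
    components: list[np.ndarray] | None = None,
) -> float:
    """Intrinsic-CAR log kernel on the constrained subspace:
    (1/2) log pdet(Q) - (1/2) theta' Q theta.

    ``theta`` must satisfy the per-component sum-to-zero constraint.
    """
    theta = np.asarray(theta, dtype=float)
    Qd = Q.toarray() if sparse.issparse(Q) else np.asarray(Q, dtype=float)
    if components is None:
        components = [np.arange(theta.size)]
    for comp in components:
        if abs(theta[comp].sum()) > constraint_tol * max(1.0, np.abs(theta).max()):
            raise ValueError("theta violates the per-component sum-to-zero constraint")
    quad = float(theta @ Qd @ theta)
    return 0.5 * log_pdet(Qd) - 0.5 * quad


# ---------------------------------------------------------------------------
# PC prior for the Weibull shape
# ---------------------------------------------------------------------------

_EULER_GAMMA = float(np.euler_gamma)


def weibull_kld(alpha: float | np.ndarray) -> float | np.ndarray:
    """Kullback-Leibler divergence of a shape-``alpha`` Weibull from the
    exponential base model (alpha = 1):

        KLD(a) = (Gamma((1+a)/2) a + a log a - a g + g - a) / a,

    with g Euler's constant. KLD(1) = 0.
    """
    a = np.asarray(alpha, dtype=float)
    if np.any(a <= 0):
        raise ValueError("alpha must be positive")
    num = (
        np.exp(gammaln((1.0 + a) / 2.0)) * a
        + a * np.log(a)
        - a * _EULER_GAMMA
        + _EULER_GAMMA
        - a
    )
    out = num / a
    return float(out) if np.isscalar(alpha) else out


def pc_distance(alpha: float | np.ndarray) -> float | np.ndarray:
    """d(alpha) = sqrt(2 KLD(alpha)): distance from the exponential base."""
    kld = np.maximum(weibull_kld(alpha), 0.0)
    out = np.sqrt(2.0 * kld)
    return float(out) if np.isscalar(alpha) else out


def _kld_derivative(a: np.ndarray) -> np.ndarray:
    """Analytic d/da of weibull_kld. KLD = N(a)/a with
    N = Gamma((1+a)/2) a + a log a - a g + g - a."""
    half = (1.0 + a) / 2.0
    gam = np.exp(gammaln(half))
    n = gam * a + a * np.log(a) - a * _EULER_GAMMA + _EULER_GAMMA - a
    n_prime = 0.5 * a * gam * digamma(half) + gam + np.log(a) - _EULER_GAMMA
    return n_prime / a - n / a**2


def pc_distance_derivative(alpha: float | np.ndarray) -> float | np.ndarray:
    """|d'(alpha)| = |KLD'(alpha)| / sqrt(2 KLD(alpha)), with the removable
    singularity at alpha = 1 filled by its finite limit sqrt(KLD''(1))."""
    a = np.atleast_1d(np.asarray(alpha, dtype=float))
    if np.any(a <= 0):
        raise ValueError("alpha must be positive")
    out = np.empty_like(a)
    near_one = np.abs(a - 1.0) < 1e-6
    far = ~near_one
    if far.any():
        kld = np.asarray(weibull_kld(a[far]))
        out[far] = np.abs(_kld_derivative(a[far])) / np.sqrt(2.0 * kld)
    if near_one.any():
        h = 1e-5  # KLD''(1) by central second difference; KLD(1) = 0 exactly
        k2 = (weibull_kld(1.0 + h) + weibull_kld(1.0 - h)) / h**2
        out[near_one] = np.sqrt(k2)
    return float(out[0]) if np.isscalar(alpha) else out


def pc_prior_log_density(alpha: float, lambda_pc: float = 5.0) -> float:
    """Penalized-complexity prior on the Weibull shape,

        pi(alpha) = (lambda/2) exp(-lambda d(alpha)) |d'(alpha)|,

    a two-sided exponential penalty on the distance d from the exponential
    base model alpha = 1. Default rate lambda = 5.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if lambda_pc <= 0:
        raise ValueError("lambda_pc must be positive")
    with np.errstate(over="ignore", invalid="ignore"):
        d = pc_distance(alpha)
        dd = pc_distance_derivative(alpha)
        out = np.log(lambda_pc / 2.0) - lambda_pc * d + np.log(dd)
    # far from the base model the distance overflows; the density is 0 there
    return float(out) if np.isfinite(out) else float("-inf")


# ---------------------------------------------------------------------------
# hyperpriors
# ---------------------------------------------------------------------------


def hyperprior_log_density(log_precision: float, shape: float = 1.0, rate: float = 5e-5) -> float:
    """Log-gamma hyperprior: the density of log X with X ~ Gamma(shape, rate),

        log pi(u) = shape log rate - log Gamma(shape) + shape u - rate e^u.

    Equivalently a Gamma(shape, rate) prior on the precision itself with the
    log-scale Jacobian. With shape = 1 the precision is Exponential(rate).
    """
    if shape <= 0 or rate <= 0:
        raise ValueError("shape and rate must be positive")
    u = float(log_precision)
    return shape * np.log(rate) - float(gammaln(shape)) + shape * u - rate * np.exp(u)


# ---------------------------------------------------------------------------
# configuration bundle
# ---------------------------------------------------------------------------


@dataclass
class PriorConfig:
    """Hyperparameters of every prior block, defaulting to the study values.

    ``tau_gamma`` applies to the likelihood precision tau (log-normal), and
    the GMRF precisions tau_psi, tau_theta, tau_c; ``phi_gamma`` to the
    gamma-family shape multiplier phi; ``lambda_pc`` to the PC prior on the
    Weibull shape.
    """

    beta_variance: float = 100.0
    tau_gamma: tuple[float, float] = (1.0, 5e-5)
    phi_gamma: tuple[float, float] = (1.0, 0.01)
    lambda_pc: float = 5.0
    sum_to_zero: bool = True

    def validate(self) -> "PriorConfig":
        if self.beta_variance <= 0:
            raise ValueError("beta_variance must be positive")
        for pair in (self.tau_gamma, self.phi_gamma):
            if pair[0] <= 0 or pair[1] <= 0:
                raise ValueError("gamma hyperparameters must be positive")
        if self.lambda_pc <= 0:
            raise ValueError("lambda_pc must be positive")
        return self


@dataclass(frozen=True)
class ICARSpec:
    graph: AdjacencyGraph
    tau_theta: float = 1.0

    @property
    def Q(self) -> sparse.csr_matrix:
        return icar_precision(self.graph, self.tau_theta)


@dataclass(frozen=True)
class RW2Spec:
    length: int = 35
    tau: float = 1.0


@dataclass(frozen=True)
class RW1Spec:
    length: int = 10
    tau: float = 1.0


@dataclass(frozen=True)
class PCPriorSpec:
    lambda_pc: float = 5.0
    base_alpha: float = 1.0


@dataclass(frozen=True)
class HyperpriorSpec:
    tau: tuple[float, float] = (1.0, 5e-5)
    phi: tuple[float, float] = (1.0, 0.01)
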