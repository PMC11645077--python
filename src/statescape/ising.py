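"""Pairwise maximum-entropy (Ising) model over joint ROI activation states.

The model assigns every activation state ``V_k`` (a spin vector
``sigma in {-1,+1}^N``) the Boltzmann probability

    P(V_k) = exp(-E(V_k)) / Z,
    E(V_k) = - sum_i h_i sigma_i - (1/2) sum_{i != j} J_ij sigma_i sigma_j,

with local fields ``h`` (a region's intrinsic tendency to be active) and
symmetric zero-diagonal couplings ``J`` (pairwise co-activation tendencies).
This is the least-structured distribution matching the empirical first and
second spin moments, so fitting it to a binarized recording is a convex
moment-matching problem solved here by gradient ascent on the exact
log-likelihood with model moments computed by full enumeration of the
``2**N`` states.  Low energy corresponds to high probability; the energy
surface over the hypercube of states is the "energy landscape" analysed in
:mod:`statescape.landscape`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from sklearn.base import BaseEstimator

from .signals import MAX_ROIS, StateDistribution, StateSequence, encode_states

__all__ = [
    "MEMParameters",
    "FitDiagnostics",
    "PairwiseMaxEnt",
    "spin_matrix",
    "energy",
    "energies",
    "log_partition",
    "boltzmann_distribution",
    "sample_ising",
    "fit_mem",
    "fit_many",
    "fit_diagnostics",
]


@dataclass
class MEMParameters:
    """Local fields ``h`` and symmetric couplings ``J`` (dimensionless)."""

    h: np.ndarray
    J: np.ndarray
    roi_names: list[str] | None = None

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        n = self.h.size
        if self.J.shape != (n, n):
            raise ValueError(f"J shape {self.J.shape} does not match h length {n}")
        if not np.isfinite(self.h).all() or not np.isfinite(self.J).all():
            raise ValueError("non-finite parameter entries")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0):
            raise ValueError("J must have zero diagonal")
        if self.roi_names is None:
            self.roi_names = [f"roi{i + 1}" for i in range(n)]

    @property
    def n_rois(self) -> int:
        return self.h.size


@dataclass
class FitDiagnostics:
    log_likelihood_per_sample: float
    kl_empirical_vs_model: float
    max_moment_residual: float
    n_iterations: int
    converged: bool


def spin_matrix(n_rois: int) -> np.ndarray:
    """All ``2**N`` spin vectors, row ``k`` = state ``k`` (ROI 1 = LSB)."""
    if n_rois > MAX_ROIS:
        raise ValueError(f"N={n_rois} exceeds the enumerable limit of {MAX_ROIS}")
    k = np.arange(1 << n_rois, dtype=np.int64)
    bits = (k[:, None] >> np.arange(n_rois)) & 1
    return (2 * bits - 1).astype(np.float64)


def _triu(n: int):
    return np.triu_indices(n, k=1)


def _features(n_rois: int) -> np.ndarray:
    """Sufficient-statistic matrix: [sigma_i, sigma_i*sigma_j (i<j)] per state."""
    S = spin_matrix(n_rois)
    iu, ju = _triu(n_rois)
    return np.hstack([S, S[:, iu] * S[:, ju]])


def _theta_from_params(params: MEMParameters) -> np.ndarray:
    iu, ju = _triu(params.n_rois)
    return np.concatenate([params.h, params.J[iu, ju]])


def _params_from_theta(theta: np.ndarray, n_rois: int, roi_names=None) -> MEMParameters:
    h = theta[:n_rois]
    J = np.zeros((n_rois, n_rois))
    iu, ju = _triu(n_rois)
    J[iu, ju] = theta[n_rois:]
    J += J.T
    return MEMParameters(h=h, J=J, roi_names=roi_names)


def energies(params: MEMParameters) -> np.ndarray:
    """Energy of every state: ``E = -F @ theta`` on the sufficient statistics."""
    return -_features(params.n_rois) @ _theta_from_params(params)


def energy(params: MEMParameters, k: int) -> float:
    """Energy of a single state index."""
    e = energies(params)
    k = int(k)
    if not 0 <= k < e.size:
        raise ValueError(f"state index {k} out of range")
    return float(e[k])


def log_partition(params: MEMParameters) -> float:
    return float(logsumexp(-energies(params)))


def boltzmann_distribution(params: MEMParameters) -> StateDistribution:
    """Normalized Boltzmann probabilities over all ``2**N`` states."""
    e = -energies(params)
    e -= e.max()  # overflow guard
    p = np.exp(e)
    p /= p.sum()
    return StateDistribution(p, n_observations=0)


# ---------------------------------------------------------------------------
# sampling


def sample_ising(
    params: MEMParameters,
    n_samples: int,
    seed=None,
    method: str = "exact",
    burn_in: int = 1000,
    thin: int = 5,
) -> StateSequence:
    """Draw activation states from the model's Boltzmann distribution.

    ``method="exact"`` enumerates all states and draws i.i.d. via inverse
    CDF (requires N <= 20); ``method="gibbs"`` runs a single-site-sweep
    Gibbs chain with ``burn_in`` discarded sweeps and one retained sample
    every ``thin`` sweeps, usable without enumeration.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    n = params.n_rois
    if method == "exact":
        probs = boltzmann_distribution(params).probs
        cdf = np.cumsum(probs)
        cdf[-1] = 1.0
        ks = np.searchsorted(cdf, rng.random(n_samples), side="right")
        bits = (ks[:, None] >> np.arange(n)) & 1
        spins = (2 * bits - 1).astype(np.int8)
    elif method == "gibbs":
        spins = np.empty((n_samples, n), dtype=np.int8)
        s = rng.choice([-1, 1], size=n).astype(np.int8)
        h, J = params.h, params.J
        n_sweeps = burn_in + n_samples * thin
        u = rng.random((n_sweeps, n))
        kept = 0
        for t in range(n_sweeps):
            for i in range(n):
                field = h[i] + J[i] @ s
                p_up = 1.0 / (1.0 + np.exp(-2.0 * field))
                s[i] = 1 if u[t, i] < p_up else -1
            if t >= burn_in and (t - burn_in) % thin == 0:
                spins[kept] = s
                kept += 1
                if kept == n_samples:
                    break
        spins = spins[:n_samples]
    else:
        raise ValueError(f"unknown method {method!r}")
    return StateSequence(spins, roi_names=list(params.roi_names))


# ---------------------------------------------------------------------------
# fitting


def _fit_theta_batch(mu_data, n_rois, lr, tol, max_iter, l2=0.0, theta0=None):
    """Gradient ascent on the exact log-likelihood for a batch of targets.

    ``mu_data``: (B, D) data moments; returns (theta, n_iter, max_residuals).
    The update ``theta += lr * (mu_data - mu_model)`` is the classic
    Boltzmann-learning rule; the likelihood is concave so the fixed point is
    the global maximum-likelihood solution.
    """
    F = _features(n_rois)  # (K, D)
    mu_data = np.atleast_2d(np.asarray(mu_data, dtype=float))
    B, D = mu_data.shape
    theta = np.zeros((B, D)) if theta0 is None else np.array(theta0, dtype=float)
    it = 0
    resid = np.full(B, np.inf)
    for it in range(1, int(max_iter) + 1):
        logits = F @ theta.T  # (K, B)
        logits -= logits.max(axis=0)
        p = np.exp(logits)
        p /= p.sum(axis=0)
        mu_model = p.T @ F  # (B, D)
        grad = mu_data - mu_model - l2 * theta
        resid = np.abs(mu_data - mu_model).max(axis=1)
        if resid.max() <= tol:
            break
        theta += lr * grad
    return theta, it, resid


def fit_mem(
    dist: StateDistribution,
    lr: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 500_000,
    l2: float = 0.0,
    roi_names=None,
) -> tuple[MEMParameters, FitDiagnostics]:
    """Fit the pairwise MEM to a state distribution by moment matching.

    Deterministic (zero initialization).  Non-convergence within
    ``max_iter`` is reported through ``FitDiagnostics.converged``, never
    silently.  ``l2`` adds optional ridge shrinkage on all parameters for
    short recordings (off by default).
    """
    n = dist.n_rois
    F = _features(n)
    mu_data = dist.probs @ F
    theta, n_iter, resid = _fit_theta_batch(mu_data[None, :], n, lr, tol, max_iter, l2=l2)
    params = _params_from_theta(theta[0], n, roi_names=roi_names)
    diag = fit_diagnostics(params, dist)
    diag.n_iterations = n_iter
    diag.converged = bool(resid[0] <= tol)
    return params, diag


def fit_many(
    dists: list[StateDistribution],
    lr: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 500_000,
    l2: float = 0.0,
) -> list[MEMParameters]:
    """Vectorized per-subject fits sharing one gradient-ascent loop.

    Equivalent to calling :func:`fit_mem` per distribution (same update
    rule, zero init) but batched across subjects, which is what makes
    cohort-scale simulation studies tractable.
    """
    if not dists:
        return []
    n = dists[0].n_rois
    if any(d.n_rois != n for d in dists):
        raise ValueError("all distributions must share N")
    F = _features(n)
    mu = np.stack([d.probs @ F for d in dists])
    theta, _, resid = _fit_theta_batch(mu, n, lr, tol, max_iter, l2=l2)
    if resid.max() > tol:
        raise RuntimeError(
            f"batched MEM fit did not converge (max residual {resid.max():.3g} > tol {tol:g})"
        )
    return [_params_from_theta(t, n) for t in theta]


def fit_diagnostics(params: MEMParameters, dist: StateDistribution) -> FitDiagnostics:
    """Likelihood, KL and moment-residual diagnostics of a model vs data."""
    if params.n_rois != dist.n_rois:
        raise ValueError("parameter and distribution N differ")
    F = _features(params.n_rois)
    model = boltzmann_distribution(params).probs
    p = dist.probs
    nz = p > 0
    ll = float(p[nz] @ np.log(model[nz]))
    kl = float(p[nz] @ (np.log(p[nz]) - np.log(model[nz])))
    resid = float(np.abs(p @ F - model @ F).max())
    return FitDiagnostics(
        log_likelihood_per_sample=ll,
        kl_empirical_vs_model=max(kl, 0.0),
        max_moment_residual=resid,
        n_iterations=0,
        converged=resid <= 1e-8,
    )


class PairwiseMaxEnt(BaseEstimator):
    """Scikit-learn style estimator for the pairwise maximum-entropy model.

    ``fit`` takes a T x N spin matrix (entries in {-1,+1}; booleans / {0,1}
    are promoted) or a :class:`StateSequence`, forms the empirical state
    distribution and matches its first and second moments.

    Parameters
    ----------
    learning_rate : float, default 0.1
        Step size on the moment residual (Boltzmann learning rule).
    tol : float, default 1e-8
        Convergence threshold on the max absolute moment residual.
    max_iter : int, default 500_000
    l2 : float, default 0.0
        Optional ridge penalty on (h, J) for short recordings.

    Attributes
    ----------
    h_ : ndarray (N,)            fitted local fields
    J_ : ndarray (N, N)          fitted symmetric couplings, zero diagonal
    energies_ : ndarray (2**N,)  per-state energies
    log_partition_ : float
    n_iter_ : int
    converged_ : bool
    diagnostics_ : FitDiagnostics
    """

    def __init__(self, learning_rate: float = 0.1, tol: float = 1e-8,
                 max_iter: int = 500_000, l2: float = 0.0):
        self.learning_rate = learning_rate
        self.tol = tol
        self.max_iter = max_iter
        self.l2 = l2

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y=None):
        if isinstance(X, StateSequence):
            seq = X
        else:
            arr = np.asarray(X)
            if arr.ndim != 2:
                raise ValueError("X must be T x N")
            if set(np.unique(arr)) <= {0, 1}:
                arr = 2 * arr.astype(np.int8) - 1
            seq = StateSequence(arr)
        counts = np.bincount(seq.state_index, minlength=1 << seq.n_rois)
        dist = StateDistribution.from_counts(counts)
        return self.fit_distribution(dist, roi_names=seq.roi_names)

    def fit_distribution(self, dist: StateDistribution, roi_names=None):
        """Fit directly from a (possibly model-derived) state distribution."""
        params, diag = fit_mem(
            dist, lr=self.learning_rate, tol=self.tol,
            max_iter=self.max_iter, l2=self.l2, roi_names=roi_names,
        )
        self.h_ = params.h
        self.J_ = params.J
        self.roi_names_ = params.roi_names
        self.n_rois_ = params.n_rois
        self.energies_ = energies(params)
        self.log_partition_ = log_partition(params)
        self.n_iter_ = diag.n_iterations
        self.converged_ = diag.converged
        self.diagnostics_ = diag
        return self

    # -- fitted-model queries ---------------------------------------------
    @property
    def params_(self) -> MEMParameters:
        self._check_fitted()
        return MEMParameters(h=self.h_, J=self.J_, roi_names=self.roi_names_)

    def _check_fitted(self):
        if not hasattr(self, "h_"):
            raise RuntimeError("PairwiseMaxEnt is not fitted")

    def state_probabilities(self) -> StateDistribution:
        self._check_fitted()
        return boltzmann_distribution(self.params_)

    def energy(self, k: int) -> float:
        self._check_fitted()
        return energy(self.params_, k)

    def sample(self, n_samples: int, method: str = "exact", random_state=None,
               burn_in: int = 1000, thin: int = 5) -> StateSequence:
        self._check_fitted()
        return sample_ising(self.params_, n_samples, seed=random_state,
                            method=method, burn_in=burn_in, thin=thin)

    def score(self, X, y=None) -> float:
        """Mean log-likelihood per time point of a spin matrix under the model."""
        self._check_fitted()
        arr = X.spins if isinstance(X, StateSequence) else np.asarray(X)
        if set(np.unique(arr)) <= {0, 1}:
            arr = 2 * np.asarray(arr, dtype=np.int8) - 1
        ks = encode_states(arr)
        logp = np.log(self.state_probabilities().probs)
        return float(logp[ks].mean())
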