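"""Emission model: combinatorial enrichment patterns and NB densities.

The three hidden states share a single four-parameter negative-binomial GLM:

    log mu_background = beta1 + u        log phi_background = lambda1
    log mu_enriched   = beta1 + beta3 + u    log phi_enriched = lambda1 + lambda3

Consensus background and consensus enrichment apply one level to every
sample.  The differential state is an L-component finite mixture whose
component ``l`` applies the enriched level exactly to the conditions in the
subset ``S_l`` (encoded by a binary G x L design matrix).  With G conditions
there are ``L = 2**G - 2`` non-empty, non-full subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp

if TYPE_CHECKING:
    from .data_model import CountDataset

__all__ = [
    "PatternDesign",
    "GLMParameters",
    "enumerate_patterns",
    "nb_log_pmf",
    "consensus_loglik",
    "differential_loglik",
    "fit_weighted_nb_glm",
]


@dataclass(frozen=True)
class PatternDesign:
    """All combinatorial differential patterns for G conditions.

    ``x`` is the G x L binary matrix with ``x[h, l] = 1`` iff condition ``h``
    is enriched in pattern ``l``; ``sets[l]`` is the corresponding subset of
    enriched conditions (0-based).  Columns are ordered canonically by
    (cardinality, lexicographic), so for G = 3 the patterns are
    {0}, {1}, {2}, {0,1}, {0,2}, {1,2}.
    """

    G: int
    x: np.ndarray
    sets: tuple[tuple[int, ...], ...]

    @property
    def L(self) -> int:
        return self.x.shape[1]

    def subset(self, keep: np.ndarray) -> "PatternDesign":
        """Design restricted to the pattern columns in `keep` (for pruning)."""
        keep = np.asarray(keep)
        return PatternDesign(self.G, self.x[:, keep], tuple(self.sets[int(k)] for k in keep))

    def labels(self) -> list[str]:
        return ["+".join(str(h + 1) for h in s) for s in self.sets]


def enumerate_patterns(G: int) -> PatternDesign:
    """Enumerate all 2**G - 2 differential enrichment patterns.

    Raises for G < 2 (a differential state needs at least two conditions)
    and for G > 8 (the mixture would have >254 components).
    """
    if G < 2:
        raise ValueError("differential patterns require G >= 2 conditions")
    if G > 8:
        raise ValueError("G > 8 not supported (2**G - 2 mixture components)")
    sets = []
    for k in range(1, G):
        sets.extend(combinations(range(G), k))
    x = np.zeros((G, len(sets)), dtype=np.int8)
    for l, s in enumerate(sets):
        x[list(s), l] = 1
    return PatternDesign(G=G, x=x, sets=tuple(sets))


@dataclass(frozen=True)
class GLMParameters:
    """Shared NB-GLM parameters (log background mean, log fold-change,
    log background dispersion, log dispersion shift under enrichment)."""

    beta1: float
    beta3: float
    lambda1: float
    lambda3: float

    def __post_init__(self) -> None:
        vals = (self.beta1, self.beta3, self.lambda1, self.lambda3)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("GLM parameters must be finite")
        if self.beta3 <= 0:
            raise ValueError("beta3 must be positive (enrichment above background)")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta1, self.beta3, self.lambda1, self.lambda3])

    def mean(self, enriched, offset=0.0) -> np.ndarray:
        return np.exp(self.beta1 + self.beta3 * np.asarray(enriched) + offset)

    def dispersion(self, enriched) -> np.ndarray:
        return np.exp(self.lambda1 + self.lambda3 * np.asarray(enriched))

    @property
    def mean_ratio(self) -> float:
        """Consensus enrichment / background mean ratio (the SNR)."""
        return float(np.exp(self.beta3))


def nb_log_pmf(y, mu, phi):
    """Log NB pmf in mean/dispersion form; variance = mu * (1 + mu / phi)."""
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be a non-negative integer")
    if np.any(mu <= 0) or np.any(phi <= 0) or not (np.all(np.isfinite(mu)) and np.all(np.isfinite(phi))):
        raise ValueError("mu and phi must be positive and finite")
    return (
        gammaln(y + phi)
        - gammaln(y + 1.0)
        - gammaln(phi)
        + phi * (np.log(phi) - np.log(mu + phi))
        + y * (np.log(mu) - np.log(mu + phi))
    )


def consensus_loglik(dataset: "CountDataset", params: GLMParameters, state: str) -> np.ndarray:
    """Per-window log emission density of a consensus state.

    `state` is ``"background"`` or ``"enrichment"``; counts are independent
    across samples given the state, so the window density is the product over
    all N samples.
    """
    if state == "background":
        enriched = 0.0
    elif state == "enrichment":
        enriched = 1.0
    else:
        raise ValueError(f"unknown consensus state {state!r}")
    mu = params.mean(enriched, dataset.offsets)  # (N, M)
    phi = params.dispersion(enriched)
    return nb_log_pmf(dataset.counts, mu, phi).sum(axis=0)


def differential_loglik(
    dataset: "CountDataset",
    params: GLMParameters,
    design: PatternDesign,
    delta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Log density of the mixture differential state.

    Returns ``(per_window, components)`` where ``components[j, l]`` is the
    log density of mixture component ``l`` at window ``j`` and ``per_window``
    is ``logsumexp_l(log delta_l + components[:, l])``.
    """
    delta = np.asarray(delta, dtype=np.float64)
    if delta.shape != (design.L,) or np.any(delta < 0) or abs(delta.sum() - 1.0) > 1e-8:
        raise ValueError("delta must be a probability vector of length L")
    if design.G != dataset.n_conditions:
        raise ValueError("design G does not match dataset conditions")
    enriched = design.x[dataset.condition_of_sample, :]  # (N, L)
    comp = np.empty((dataset.n_windows, design.L))
    for l in range(design.L):
        e = enriched[:, l].astype(np.float64)[:, None]  # (N, 1)
        mu = params.mean(e, dataset.offsets)
        phi = params.dispersion(e)
        comp[:, l] = nb_log_pmf(dataset.counts, mu, phi).sum(axis=0)
    with np.errstate(divide="ignore"):
        log_delta = np.log(delta)
    per_window = logsumexp(comp + log_delta[None, :], axis=1)
    return per_window, comp


# ---------------------------------------------------------------------------
# weighted NB regression (the GLM part of the M-step)


def _nb_obj_grad(theta, y, u, cov, w):
    """Negative weighted log-likelihood and gradient in (beta1, eta, lambda1,
    lambda3) with beta3 = exp(eta) enforcing beta3 > 0."""
    beta1, eta, lam1, lam3 = theta
    beta3 = np.exp(eta)
    log_mu = beta1 + beta3 * cov + u
    log_phi = lam1 + lam3 * cov
    mu = np.exp(log_mu)
    phi = np.exp(log_phi)
    ll = (
        gammaln(y + phi)
        - gammaln(y + 1.0)
        - gammaln(phi)
        + phi * (log_phi - np.log(mu + phi))
        + y * (log_mu - np.log(mu + phi))
    )
    obj = -np.dot(w, ll)
    # d ll / d log mu and d ll / d log phi
    dl_dlogmu = y - mu * (y + phi) / (mu + phi)
    dl_dlogphi = phi * (
        digamma(y + phi) - digamma(phi) + log_phi - np.log(mu + phi) + (mu - y) / (mu + phi)
    )
    g_beta1 = -np.dot(w, dl_dlogmu)
    g_eta = -np.dot(w, dl_dlogmu * cov) * beta3
    g_lam1 = -np.dot(w, dl_dlogphi)
    g_lam3 = -np.dot(w, dl_dlogphi * cov)
    return obj, np.array([g_beta1, g_eta, g_lam1, g_lam3])


def weighted_nb_objective(params: GLMParameters, y, u, cov, w) -> float:
    """Weighted NB log-likelihood at `params` (the M-step objective)."""
    theta = np.array([params.beta1, np.log(params.beta3), params.lambda1, params.lambda3])
    obj, _ = _nb_obj_grad(theta, np.asarray(y, float), np.asarray(u, float),
                          np.asarray(cov, float), np.asarray(w, float))
    return -obj


def fit_weighted_nb_glm(
    y,
    u,
    cov,
    w,
    init: GLMParameters,
    gtol: float = 1e-6,
    maxiter: int = 200,
) -> GLMParameters:
    """Maximize the weighted NB log-likelihood over (beta1, beta3, lambda1,
    lambda3).

    ``y`` are counts, ``u`` log offsets, ``cov`` the binary enrichment
    covariate and ``w`` non-negative weights (posterior masses).  Optimized
    by L-BFGS with the analytic gradient, with beta3 kept positive through a
    log reparameterization.  The returned objective never falls below the
    objective at ``init``.
    """
    y = np.asarray(y, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    cov = np.asarray(cov, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")
    w_on = w[cov > 0].sum()
    w_off = w[cov == 0].sum()
    if w_on <= 0 or w_off <= 0:
        raise ValueError("both covariate levels need positive total weight "
                         "(beta3/lambda3 unidentifiable otherwise)")
    theta0 = np.array([init.beta1, np.log(init.beta3), init.lambda1, init.lambda3])
    res = minimize(
        _nb_obj_grad,
        theta0,
        args=(y, u, cov, w),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
    )
    obj0, _ = _nb_obj_grad(theta0, y, u, cov, w)
    if not res.success and res.fun > obj0 + 1e-8:
        raise RuntimeError(
            f"weighted NB fit did not converge: {res.message}; "
            f"last iterate {res.x}, |grad| {np.abs(res.jac).max():.3e}"
        )
    theta = res.x if res.fun <= obj0 else theta0
    return GLMParameters(
        beta1=float(theta[0]),
        beta3=float(np.exp(theta[1])),
        lambda1=float(theta[2]),
        lambda3=float(theta[3]),
    )
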