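"""Latent-chain machinery: forward-backward, Viterbi, EM, RCEM, BIC pruning.

The model is a stationary 3-state hidden Markov chain over genomic windows
(consensus background, differential, consensus enrichment) with negative
binomial emissions.  The differential state is a finite mixture over all
combinatorial enrichment patterns.  All states share the four GLM
parameters (beta1, beta3, lambda1, lambda3), so the M-step reduces to
closed-form updates for the chain parameters plus a single pooled weighted
NB regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.special import logsumexp

from ._kernels import forward_backward_kernel, viterbi_kernel
from .data_model import CountDataset, GenomicWindows
from .emissions import (
    GLMParameters,
    PatternDesign,
    consensus_loglik,
    differential_loglik,
    enumerate_patterns,
    fit_weighted_nb_glm,
    weighted_nb_objective,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ChainParameters",
    "ModelParameters",
    "PosteriorSet",
    "FitResult",
    "MStepObservations",
    "forward_backward",
    "viterbi",
    "mixture_posteriors",
    "update_chain",
    "build_mstep_observations",
    "aggregate_observations",
    "rejection_control",
    "em_fit",
    "bic",
    "prune_components",
    "save_fit",
    "write_parameters",
    "read_parameters",
]

BACKGROUND, DIFFERENTIAL, ENRICHMENT = 0, 1, 2


def _check_simplex(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if np.any(v < -1e-12) or np.any(np.abs(v.sum(axis=-1) - 1.0) > 1e-8):
        raise ValueError(f"{name} must be a probability vector (rows summing to 1)")
    v = np.clip(v, 0.0, None)
    return v / v.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class ChainParameters:
    """Initial distribution pi (3), transition matrix gamma (3x3) and
    mixture proportions delta (L) of the differential state."""

    pi: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        pi = _check_simplex(self.pi, "pi")
        gamma = np.asarray(self.gamma, dtype=np.float64)
        if gamma.shape != (3, 3):
            raise ValueError("gamma must be 3x3")
        gamma = _check_simplex(gamma, "gamma rows")
        delta = _check_simplex(self.delta, "delta")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "delta", delta)

    @property
    def L(self) -> int:
        return len(self.delta)


@dataclass(frozen=True)
class ModelParameters:
    chain: ChainParameters
    glm: GLMParameters
    design: PatternDesign

    def __post_init__(self) -> None:
        if self.chain.L != self.design.L:
            raise ValueError("delta length must match the number of patterns")

    def as_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.chain.pi, self.chain.gamma.ravel(), self.chain.delta, self.glm.as_array()]
        )


@dataclass
class PosteriorSet:
    """E-step posteriors: rho[j, r] = Pr(Z_j = r | y), xi[j-1, r, s] =
    Pr(Z_{j-1} = r, Z_j = s | y), w[j, l] = Pr(W_jl = 1 | Z_j = 2, y_j),
    and the observed-data log-likelihood."""

    rho: np.ndarray
    xi: np.ndarray
    loglik: float
    w: np.ndarray | None = None


@dataclass
class FitResult:
    params: ModelParameters
    posteriors: PosteriorSet
    iterations: int
    converged: bool
    loglik_trace: np.ndarray
    bic: float = np.nan


# ---------------------------------------------------------------------------
# exact inference


def _prep_emissions(emission_loglik: np.ndarray) -> np.ndarray:
    e = np.asarray(emission_loglik, dtype=np.float64)
    if e.ndim != 2 or e.shape[1] != 3 or e.shape[0] == 0:
        raise ValueError("emission_loglik must be a non-empty (M, 3) matrix")
    if np.any(np.isnan(e)) or np.any(e == np.inf):
        raise ValueError("emission log-likelihoods must be finite or -inf")
    dead = np.flatnonzero(np.max(e, axis=1) == -np.inf)
    if len(dead):
        raise ValueError(f"all states have zero likelihood at window {int(dead[0])}")
    return e


def _log_chain(chain: ChainParameters) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore"):
        return np.log(chain.pi), np.log(chain.gamma)


def forward_backward(emission_loglik: np.ndarray, chain: ChainParameters) -> PosteriorSet:
    """Exact smoothed posteriors and observed-data log-likelihood.

    Uses the scaled forward-backward recursions; rows of rho and each xi
    slice sum to one, and the pairwise posteriors are marginally consistent
    with rho.
    """
    e = _prep_emissions(emission_loglik)
    log_pi, log_gamma = _log_chain(chain)
    rho, xi, loglik = forward_backward_kernel(e, log_pi, log_gamma)
    return PosteriorSet(rho=rho, xi=xi, loglik=float(loglik))


def viterbi(emission_loglik: np.ndarray, chain: ChainParameters) -> np.ndarray:
    """Most probable hidden-state path (ties go to the lower state index)."""
    e = _prep_emissions(emission_loglik)
    log_pi, log_gamma = _log_chain(chain)
    path, _ = viterbi_kernel(e, log_pi, log_gamma)
    return path


def mixture_posteriors(component_loglik: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Posterior pattern membership within the differential state.

    ``w[j, l] = softmax_l(log delta_l + component_loglik[j, l])``.
    """
    delta = _check_simplex(delta, "delta")
    c = np.asarray(component_loglik, dtype=np.float64)
    with np.errstate(divide="ignore"):
        a = c + np.log(delta)[None, :]
    norm = logsumexp(a, axis=1)
    if np.any(norm == -np.inf):
        j = int(np.flatnonzero(norm == -np.inf)[0])
        raise ValueError(f"all mixture components have zero likelihood at window {j}")
    return np.exp(a - norm[:, None])


# ---------------------------------------------------------------------------
# M-step pieces


def update_chain(posteriors: PosteriorSet, prev: ChainParameters | None = None) -> ChainParameters:
    """Closed-form updates of pi, gamma, delta from the E-step posteriors.

    pi_r = rho_1r; gamma_rs = sum_j xi_j(r,s) / sum_j rho_{j-1,r};
    delta_l = sum_j rho_j2 w_jl / sum_j rho_j2.  A state with zero total
    occupancy keeps its previous transition row (or delta), with a warning.
    """
    rho, xi, w = posteriors.rho, posteriors.xi, posteriors.w
    pi = rho[0].copy()
    denom = rho[:-1].sum(axis=0)
    gamma = np.empty((3, 3))
    for r in range(3):
        if denom[r] > 1e-12:
            num = xi[:, r, :].sum(axis=0)
            gamma[r] = num / num.sum()  # == num / denom[r] for consistent posteriors
        else:
            logger.warning("state %d never occupied; keeping its transition row", r)
            gamma[r] = prev.gamma[r] if prev is not None else np.full(3, 1.0 / 3.0)
    occ2 = rho[:, DIFFERENTIAL].sum()
    if w is None:
        delta = prev.delta if prev is not None else np.array([1.0])
    elif occ2 > 1e-12:
        delta = rho[:, DIFFERENTIAL] @ w / occ2
    else:
        logger.warning("differential state never occupied; keeping delta")
        delta = prev.delta if prev is not None else np.full(w.shape[1], 1.0 / w.shape[1])
    return ChainParameters(pi=pi, gamma=gamma, delta=delta)


def rejection_control(
    weights: np.ndarray, threshold: float = 0.05, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Stochastically sparsify small posterior weights, unbiasedly.

    A weight p >= threshold is kept; p < threshold becomes `threshold` with
    probability p / threshold and 0 otherwise, so the expectation of the
    output equals the input.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    w = np.asarray(weights, dtype=np.float64)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("weights must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    out = w.copy()
    small = w < threshold
    keep = rng.random(small.sum()) < w[small] / threshold
    out[small] = np.where(keep, threshold, 0.0)
    return out


@dataclass
class MStepObservations:
    """Weighted pseudo-observations for the pooled NB regression.

    One record per (window, sample, state/component) with the count, the
    log offset, the binary enrichment covariate, and the posterior weight.
    """

    y: np.ndarray
    u: np.ndarray
    cov: np.ndarray
    weight: np.ndarray

    def __len__(self) -> int:
        return len(self.y)


def build_mstep_observations(
    dataset: CountDataset, posteriors: PosteriorSet, design: PatternDesign
) -> MStepObservations:
    """Expand posteriors into the weighted regression observations.

    Per window j and sample (h, i): covariate 0 with weight rho_j1
    (background), covariate 1 with weight rho_j3 (enrichment), and for each
    mixture component l covariate x_hl with weight rho_j2 * w_jl.  The total
    weight emitted per (window, sample) is 1 when posteriors are unadjusted.
    """
    if posteriors.w is None:
        raise ValueError("posteriors must carry mixture posteriors w")
    rho, w = posteriors.rho, posteriors.w
    N, M = dataset.counts.shape
    y_flat = dataset.counts.ravel().astype(np.float64)  # sample-major
    u_flat = dataset.offsets.ravel()
    x_sample = design.x[dataset.condition_of_sample, :]  # (N, L)
    ys, us, covs, ws = [], [], [], []
    # consensus blocks
    for state, cov in ((BACKGROUND, 0.0), (ENRICHMENT, 1.0)):
        ys.append(y_flat)
        us.append(u_flat)
        covs.append(np.full(N * M, cov))
        ws.append(np.tile(rho[:, state], N))
    # one block per mixture component
    for l in range(design.L):
        ys.append(y_flat)
        us.append(u_flat)
        covs.append(np.repeat(x_sample[:, l].astype(np.float64), M))
        ws.append(np.tile(rho[:, DIFFERENTIAL] * w[:, l], N))
    return MStepObservations(
        y=np.concatenate(ys),
        u=np.concatenate(us),
        cov=np.concatenate(covs),
        weight=np.concatenate(ws),
    )


def aggregate_observations(obs: MStepObservations) -> MStepObservations:
    """Merge observations with identical (count, offset, covariate).

    Weights are summed; the weighted NB objective is unchanged.  This is
    what makes the M-step cheap: windows with the same count configuration
    share one record.
    """
    key = np.rec.fromarrays([obs.y, obs.u, obs.cov], names=["y", "u", "cov"])
    uniq, inverse = np.unique(key, return_inverse=True)
    weight = np.bincount(inverse, weights=obs.weight, minlength=len(uniq))
    return MStepObservations(
        y=uniq["y"].astype(np.float64),
        u=uniq["u"],
        cov=uniq["cov"],
        weight=weight,
    )


# ---------------------------------------------------------------------------
# EM


def _emission_logliks(
    dataset: CountDataset, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """(M, 3) state emission log-densities and (M, L) component log-densities."""
    l1 = consensus_loglik(dataset, params.glm, "background")
    l3 = consensus_loglik(dataset, params.glm, "enrichment")
    l2, comp = differential_loglik(dataset, params.glm, params.design, params.chain.delta)
    return np.column_stack([l1, l2, l3]), comp


class DegenerateInitialization(RuntimeError):
    pass


def _moment_match(counts: np.ndarray) -> tuple[float, float]:
    """Method-of-moments NB (mean, dispersion) with guards for underdispersion."""
    m = max(float(counts.mean()), 0.05)
    v = float(counts.var())
    phi = m * m / (v - m) if v > m * 1.001 else 100.0
    return m, float(np.clip(phi, 0.05, 1e4))


def initialize(
    dataset: CountDataset, design: PatternDesign, perturb: bool = False
) -> ModelParameters:
    """Data-driven starting values.

    Windows ranked by total count seed the states: the bottom 40% seed
    consensus background, the top 10% consensus enrichment (30% / 20% on the
    perturbed retry), and the NB parameters are moment-matched on the two
    seed groups.
    """
    totals = dataset.counts.sum(axis=0)
    order = np.argsort(totals, kind="stable")
    M = dataset.n_windows
    lo_frac, hi_frac = (0.30, 0.20) if perturb else (0.40, 0.10)
    n_lo = max(int(M * lo_frac), 1)
    n_hi = max(int(M * hi_frac), 1)
    bg = dataset.counts[:, order[:n_lo]].ravel()
    top = dataset.counts[:, order[M - n_hi:]].ravel()
    m1, phi1 = _moment_match(bg)
    m3, phi3 = _moment_match(top)
    m3 = max(m3, m1 * 1.5)
    # the top-count group mixes fully and partially enriched windows, which
    # inflates its variance; a moment-matched dispersion shift would start
    # strongly negative and can trap EM, so the shift starts neutral
    glm = GLMParameters(
        beta1=float(np.log(m1)),
        beta3=float(np.log(m3 / m1)),
        lambda1=float(np.log(phi1)),
        lambda3=0.0,
    )
    chain = ChainParameters(
        pi=np.array([0.8, 0.1, 0.1]),
        gamma=np.full((3, 3), 0.01) + np.eye(3) * 0.97,
        delta=np.full(design.L, 1.0 / design.L),
    )
    return ModelParameters(chain=chain, glm=glm, design=design)


def _converged(history: list[np.ndarray], tol: float) -> bool:
    """Max absolute relative change in all parameters three iterations apart
    below `tol` for three consecutive checks."""
    if len(history) < 6:
        return False
    for k in (1, 2, 3):
        new, old = history[-k], history[-k - 3]
        rel = np.abs(new - old) / (np.abs(old) + 1e-8)
        if rel.max() >= tol:
            return False
    return True


def em_fit(
    dataset: CountDataset,
    init: ModelParameters | None = None,
    rcem: bool = True,
    threshold: float = 0.05,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-3,
) -> FitResult:
    """Fit the 3-state HMM by (rejection-controlled) EM.

    The E-step computes exact state and mixture posteriors; the M-step
    updates pi/gamma/delta in closed form and refits the shared NB-GLM by a
    pooled weighted regression on aggregated observations.  With ``rcem``
    on, per-window state occupancies below ``threshold`` are stochastically
    zeroed (unbiasedly) before the regression; chain updates always use the
    unadjusted posteriors.  Stops when the maximum absolute relative change
    of any parameter three iterations apart stays below ``tol`` for three
    consecutive iterations.
    """
    G = dataset.n_conditions
    if G < 2:
        raise ValueError("differential analysis requires G >= 2 conditions")
    design = init.design if init is not None else enumerate_patterns(G)
    rng = np.random.default_rng(seed)
    params = init if init is not None else initialize(dataset, design)
    try:
        return _em_loop(dataset, params, rcem, threshold, rng, max_iter, tol)
    except DegenerateInitialization:
        if init is not None:
            raise
        logger.warning("degenerate initialization; retrying with perturbed seed groups")
        params = initialize(dataset, design, perturb=True)
        return _em_loop(dataset, params, rcem, threshold, rng, max_iter, tol)


def _precompute_groups(dataset: CountDataset, design: PatternDesign):
    """Group index for M-step aggregation.

    The (count, offset, covariate) triples of the pseudo-observations are
    fixed across iterations; only the weights change, so the expensive
    unique() runs once and each M-step is a bincount.
    """
    N, M = dataset.counts.shape
    y_flat = dataset.counts.ravel().astype(np.float64)
    u_flat = dataset.offsets.ravel()
    x_sample = design.x[dataset.condition_of_sample, :]
    ys, us, covs = [], [], []
    for cov in (0.0, 1.0):
        ys.append(y_flat)
        us.append(u_flat)
        covs.append(np.full(N * M, cov))
    for l in range(design.L):
        ys.append(y_flat)
        us.append(u_flat)
        covs.append(np.repeat(x_sample[:, l].astype(np.float64), M))
    key = np.rec.fromarrays(
        [np.concatenate(ys), np.concatenate(us), np.concatenate(covs)],
        names=["y", "u", "cov"],
    )
    uniq, inverse = np.unique(key, return_inverse=True)
    return uniq, inverse


def _mstep_weights(
    rho_adj: np.ndarray, w: np.ndarray, N: int
) -> np.ndarray:
    blocks = [np.tile(rho_adj[:, BACKGROUND], N), np.tile(rho_adj[:, ENRICHMENT], N)]
    for l in range(w.shape[1]):
        blocks.append(np.tile(rho_adj[:, DIFFERENTIAL] * w[:, l], N))
    return np.concatenate(blocks)


def _rc_fixed_uniforms(p: np.ndarray, threshold: float, u: np.ndarray) -> np.ndarray:
    """Rejection control driven by pre-drawn uniforms.

    The EM loop reuses one uniform per (window, state) across iterations
    (common random numbers): each iteration's adjustment is still unbiased,
    but accept/reject decisions stabilize as the posteriors converge, so the
    parameter trajectory is not dominated by resampling noise.
    """
    keep = u < p / threshold
    return np.where(p >= threshold, p, np.where(keep, threshold, 0.0))


def _em_loop(dataset, params, rcem, threshold, rng, max_iter, tol) -> FitResult:
    N = dataset.n_samples
    uniq, inverse = _precompute_groups(dataset, params.design)
    rc_uniforms = rng.random((dataset.n_windows, 3)) if rcem else None
    history: list[np.ndarray] = [params.as_vector()]
    trace: list[float] = []
    posteriors = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        emis, comp = _emission_logliks(dataset, params)
        posteriors = forward_backward(emis, params.chain)
        posteriors.w = mixture_posteriors(comp, params.chain.delta)
        if not np.isfinite(posteriors.loglik):
            raise RuntimeError(f"non-finite likelihood at EM iteration {it}")
        trace.append(posteriors.loglik)
        if it == 1 and posteriors.rho.sum(axis=0).min() < 1e-10:
            raise DegenerateInitialization("a state has essentially zero occupancy")
        chain = update_chain(posteriors, prev=params.chain)
        rho_use = posteriors.rho
        if rcem:
            rho_use = np.column_stack(
                [
                    _rc_fixed_uniforms(posteriors.rho[:, r], threshold, rc_uniforms[:, r])
                    for r in range(3)
                ]
            )
        weights = np.bincount(
            inverse, weights=_mstep_weights(rho_use, posteriors.w, N), minlength=len(uniq)
        )
        live = weights > 0
        try:
            glm = fit_weighted_nb_glm(
                uniq["y"][live], uniq["u"][live], uniq["cov"][live], weights[live], init=params.glm
            )
        except ValueError:
            # rejection control zeroed out a covariate level; fall back to
            # the unadjusted posteriors for this iteration
            weights = np.bincount(
                inverse, weights=_mstep_weights(posteriors.rho, posteriors.w, N), minlength=len(uniq)
            )
            live = weights > 0
            glm = fit_weighted_nb_glm(
                uniq["y"][live], uniq["u"][live], uniq["cov"][live], weights[live], init=params.glm
            )
        params = ModelParameters(chain=chain, glm=glm, design=params.design)
        history.append(params.as_vector())
        if _converged(history, tol):
            converged = True
            break
    # final E-step so posteriors match the returned parameters
    emis, comp = _emission_logliks(dataset, params)
    posteriors = forward_backward(emis, params.chain)
    posteriors.w = mixture_posteriors(comp, params.chain.delta)
    fit = FitResult(
        params=params,
        posteriors=posteriors,
        iterations=it,
        converged=converged,
        loglik_trace=np.asarray(trace),
    )
    fit.bic = bic(fit, dataset.n_windows)
    return fit


def bic(fit: FitResult, M: int) -> float:
    """BIC = -2 loglik + p log M with p = 2 (pi) + 6 (gamma) + (L - 1)
    (delta) + 4 (GLM)."""
    p = 2 + 6 + (fit.params.chain.L - 1) + 4
    return float(-2.0 * fit.posteriors.loglik + p * np.log(M))


def prune_components(
    dataset: CountDataset,
    fit: FitResult,
    delta_floor: float = 0.05,
    **em_options,
) -> FitResult:
    """Prune rare mixture components by BIC.

    While any estimated mixture proportion is below ``delta_floor``, the
    smallest component is removed, delta renormalized, and the model refit;
    the model with the smallest BIC is returned (never pruning below one
    component).
    """
    best = fit
    current = fit
    while current.params.chain.L > 1 and current.params.chain.delta.min() < delta_floor:
        drop = int(np.argmin(current.params.chain.delta))
        keep = np.array([l for l in range(current.params.chain.L) if l != drop])
        design = current.params.design.subset(keep)
        delta = current.params.chain.delta[keep]
        delta = delta / delta.sum()
        chain = replace(current.params.chain, delta=delta)
        init = ModelParameters(chain=chain, glm=current.params.glm, design=design)
        current = em_fit(dataset, init=init, **em_options)
        if current.bic < best.bic:
            best = current
    return best


# ---------------------------------------------------------------------------
# serialization


def write_parameters(params: ModelParameters, path) -> None:
    """Plain-text key-value dump of all model parameters."""
    doc = {
        "pi": [float(v) for v in params.chain.pi],
        "gamma": [[float(v) for v in row] for row in params.chain.gamma],
        "delta": [float(v) for v in params.chain.delta],
        "beta1": float(params.glm.beta1),
        "beta3": float(params.glm.beta3),
        "lambda1": float(params.glm.lambda1),
        "lambda3": float(params.glm.lambda3),
        "G": int(params.design.G),
        "patterns": [list(map(int, s)) for s in params.design.sets],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_parameters(path) -> ModelParameters:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    full = enumerate_patterns(int(doc["G"]))
    sets = [tuple(s) for s in doc["patterns"]]
    keep = np.array([full.sets.index(s) for s in sets])
    design = full.subset(keep)
    chain = ChainParameters(
        pi=np.asarray(doc["pi"]), gamma=np.asarray(doc["gamma"]), delta=np.asarray(doc["delta"])
    )
    glm = GLMParameters(doc["beta1"], doc["beta3"], doc["lambda1"], doc["lambda3"])
    return ModelParameters(chain=chain, glm=glm, design=design)


def save_fit(fit: FitResult, windows: GenomicWindows, prefix) -> None:
    """Write the parameter file plus a per-window posterior table (TSV)."""
    import pandas as pd

    prefix = str(prefix)
    write_parameters(fit.params, prefix + ".params.yaml")
    labels = fit.params.design.labels()
    w = fit.posteriors.w
    best = np.argmax(w, axis=1)
    df = windows.to_frame()
    for r, name in enumerate(("rho_background", "rho_differential", "rho_enrichment")):
        df[name] = fit.posteriors.rho[:, r]
    df["pattern"] = [labels[b] for b in best]
    df["pattern_posterior"] = w[np.arange(len(best)), best]
    df.to_csv(prefix + ".posteriors.tsv", sep="\t", index=False)
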