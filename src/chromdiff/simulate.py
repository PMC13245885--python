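"""Count-level simulator for multi-condition differential enrichment.

Windows follow a first-order Markov chain over all 2**G background /
enrichment configurations across G conditions.  Given its configuration, a
window emits independent NB counts per sample: background samples draw from
NB(exp(beta1), exp(lambda1)), enriched samples from
NB(exp(beta1 + beta3), exp(lambda1 + lambda3)) (mean/dispersion form, so
variance = mu * (1 + mu / phi)).  Collapsing configurations gives the
3-state truth used to benchmark the HMM: all-background -> consensus
background, all-enriched -> consensus enrichment, anything else ->
differential.

The default GLM truth is the ENCODE-derived H3K27me3 parameterization
(beta1 = 1.116, beta3 = 1.165, lambda1 = 1.281, lambda3 = 0.124), whose
enrichment/background mean ratio is exp(1.165) ~= 3.21.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import CountDataset, GenomicWindows, make_windows
from .emissions import GLMParameters
from .hmm import em_fit

__all__ = [
    "H3K27ME3_TRUTH",
    "SimulationConfig",
    "SimulatedDataset",
    "default_config_chain",
    "simulate",
    "snr_adjust",
    "recovery_experiment",
]

# ENCODE-estimated H3K27me3 NB-GLM parameters
H3K27ME3_TRUTH = GLMParameters(beta1=1.116, beta3=1.165, lambda1=1.281, lambda3=0.124)


def _configurations(G: int) -> np.ndarray:
    """(2**G, G) binary matrix; row c is the enrichment status per condition.

    Row 0 is all-background, row 2**G - 1 all-enriched; condition 0 is the
    lowest bit.
    """
    c = np.arange(2**G)
    return ((c[:, None] >> np.arange(G)[None, :]) & 1).astype(np.int8)


def collapse_to_state(config_index: np.ndarray, G: int) -> np.ndarray:
    """Map configuration indices to HMM states 0/1/2 (background /
    differential / enrichment)."""
    config_index = np.asarray(config_index)
    state = np.ones(config_index.shape, dtype=np.int64)
    state[config_index == 0] = 0
    state[config_index == 2**G - 1] = 2
    return state


def default_config_chain(
    G: int,
    persistence: float = 0.95,
    stationary_background: float = 0.85,
    stationary_enrichment: float = 0.05,
) -> np.ndarray:
    """Persistent transition matrix over the 2**G configurations.

    Built as ``P = s * I + (1 - s) * 1 nu'`` with ``s = persistence`` and a
    target stationary distribution nu, so nu is exactly stationary, every
    configuration has self-transition at least ``s``, and runs of identical
    configurations have mean length >= 1 / (1 - s) = 20 windows by default.
    The differential mass (1 - background - enrichment, 10% by default) is
    split evenly among the 2**G - 2 differential configurations.
    """
    n = 2**G
    diff_mass = 1.0 - stationary_background - stationary_enrichment
    if diff_mass <= 0:
        raise ValueError("background + enrichment stationary mass must be < 1")
    nu = np.full(n, diff_mass / (n - 2))
    nu[0] = stationary_background
    nu[-1] = stationary_enrichment
    return persistence * np.eye(n) + (1.0 - persistence) * nu[None, :]


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for a count-level simulation.

    Defaults mirror the two-condition, one-replicate H3K27me3 design:
    100 000 windows of 500 bp, ENCODE-derived GLM truth, and a persistent
    configuration chain in which ~10% of windows are differential.
    """

    G: int = 2
    n: int = 1
    M: int = 100_000
    glm_truth: GLMParameters = H3K27ME3_TRUTH
    config_chain: np.ndarray | None = None
    window_width: int = 500
    seed: int = 0

    def chain(self) -> np.ndarray:
        chain = self.config_chain if self.config_chain is not None else default_config_chain(self.G)
        chain = np.asarray(chain, dtype=np.float64)
        if chain.shape != (2**self.G, 2**self.G) or np.any(chain < 0) or np.any(
            np.abs(chain.sum(axis=1) - 1.0) > 1e-8
        ):
            raise ValueError("config_chain must be a (2**G, 2**G) stochastic matrix")
        return chain

    def stationary(self) -> np.ndarray:
        chain = self.chain()
        vals, vecs = np.linalg.eig(chain.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        nu = np.real(vecs[:, k])
        nu = np.abs(nu)
        return nu / nu.sum()


@dataclass
class SimulatedDataset:
    """A simulated dataset together with its generating truth."""

    dataset: CountDataset
    true_config: np.ndarray  # per-window configuration index in 0..2**G-1
    true_state: np.ndarray  # per-window collapsed HMM state 0/1/2
    truth: SimulationConfig

    def truth_bed(self, path) -> None:
        """Write per-window true states as BED (name = state)."""
        names = np.array(["background", "differential", "enrichment"])[self.true_state]
        pd.DataFrame(
            {
                "chrom": self.dataset.windows.chrom,
                "start": self.dataset.windows.start,
                "end": self.dataset.windows.end,
                "name": names,
                "config": self.true_config,
            }
        ).to_csv(path, sep="\t", index=False, header=False)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset from the configuration chain + NB emission model.

    The configuration path starts from the stationary distribution; counts
    are reproducible bit-for-bit from ``config.seed``.
    """
    if config.M < 1 or config.n < 1 or config.G < 1:
        raise ValueError("M, n, G must be positive")
    rng = np.random.default_rng(config.seed)
    chain = config.chain()
    n_cfg = 2**config.G
    # draw the configuration path
    cum = np.cumsum(chain, axis=1)
    path = np.empty(config.M, dtype=np.int64)
    path[0] = rng.choice(n_cfg, p=config.stationary())
    u = rng.random(config.M - 1)
    for j in range(1, config.M):
        path[j] = np.searchsorted(cum[path[j - 1]], u[j - 1], side="right")
    # emit counts: sample (h, i) is enriched wherever its condition is
    enriched_by_cfg = _configurations(config.G)  # (2**G, G)
    cond = np.repeat(np.arange(config.G), config.n)
    glm = config.glm_truth
    N = config.G * config.n
    enr = enriched_by_cfg[path][:, cond].T.astype(np.float64)  # (N, M)
    mu = glm.mean(enr)
    phi = glm.dispersion(enr)
    # numpy's negative_binomial uses (n=phi, p=phi/(phi+mu))
    counts = rng.negative_binomial(phi, phi / (phi + mu), size=(N, config.M))
    windows = make_windows({"chrSim": config.M * config.window_width}, config.window_width)
    dataset = CountDataset(
        counts=counts.astype(np.int64),
        condition_of_sample=cond,
        windows=windows,
        sample_names=[f"c{h}r{i}" for h in range(config.G) for i in range(config.n)],
    )
    return SimulatedDataset(
        dataset=dataset,
        true_config=path,
        true_state=collapse_to_state(path, config.G),
        truth=config,
    )


def snr_adjust(glm_truth: GLMParameters, target_ratio: float) -> GLMParameters:
    """Rescale the truth to a different signal-to-noise (mean) ratio.

    Sets beta3 = log(target_ratio) and re-solves the enriched dispersion so
    the enriched variance-to-mean ratio 1 + mu/phi is unchanged (phi scales
    proportionally with the mean); the background level is untouched.
    """
    if target_ratio <= 1.0:
        raise ValueError("target_ratio must exceed 1 (enrichment above background)")
    beta3 = float(np.log(target_ratio))
    # phi3' = phi3 * mu3' / mu3  =>  lambda3' = lambda3 + (beta3' - beta3)
    lambda3 = glm_truth.lambda3 + (beta3 - glm_truth.beta3)
    return replace(glm_truth, beta3=beta3, lambda3=float(lambda3))


def recovery_experiment(
    config: SimulationConfig,
    n_datasets: int = 5,
    fit_options: dict | None = None,
) -> pd.DataFrame:
    """Simulate-and-refit study of parameter recovery.

    For each of ``n_datasets`` seeds (derived deterministically from
    ``config.seed``) a dataset is simulated and refit with :func:`em_fit`;
    the per-parameter relative bias (estimate - truth) / truth is summarized
    by its mean and 2.5th / 97.5th percentiles.  Failed fits are excluded
    with a logged count (column attrs carry ``n_failed``).
    """
    if n_datasets < 2:
        raise ValueError("need at least 2 datasets to summarize recovery")
    fit_options = dict(fit_options or {})
    truth = config.glm_truth.as_array()
    names = ["beta1", "beta3", "lambda1", "lambda3"]
    biases = []
    n_failed = 0
    seed_rng = np.random.default_rng(config.seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=n_datasets)
    for s in seeds:
        sim = simulate(replace(config, seed=int(s)))
        try:
            fit = em_fit(sim.dataset, seed=int(s) + 1, **fit_options)
        except Exception:  # noqa: BLE001 - mirror exclusion of failed runs
            n_failed += 1
            continue
        est = fit.params.glm.as_array()
        biases.append((est - truth) / truth)
    if not biases:
        raise RuntimeError("all fits failed")
    b = np.asarray(biases)
    out = pd.DataFrame(
        {
            "parameter": names,
            "truth": truth,
            "mean_bias": b.mean(axis=0),
            "sd_bias": b.std(axis=0, ddof=1),
            "p2.5": np.percentile(b, 2.5, axis=0),
            "p97.5": np.percentile(b, 97.5, axis=0),
        }
    )
    out.attrs["n_failed"] = n_failed
    out.attrs["n_datasets"] = len(biases)
    return out
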