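import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromdiff import (
    ChainParameters,
    CountDataset,
    GLMParameters,
    bic,
    em_fit,
    enumerate_patterns,
    forward_backward,
    mixture_posteriors,
    prune_components,
    rejection_control,
    simulate,
    viterbi,
    SimulationConfig,
    default_config_chain,
)
from chromdiff.emissions import weighted_nb_objective
from chromdiff.hmm import (
    FitResult,
    MStepObservations,
    PosteriorSet,
    aggregate_observations,
    build_mstep_observations,
    update_chain,
)

from conftest import grid_windows, random_chain


# ---------------------------------------------------------------------------
# brute-force oracles


def enumerate_paths(logb, chain):
    """Exact joint probabilities of every state path (tiny M only)."""
    M = logb.shape[0]
    with np.errstate(divide="ignore"):
        log_pi, log_gamma = np.log(chain.pi), np.log(chain.gamma)
    paths = list(itertools.product(range(3), repeat=M))
    logp = np.empty(len(paths))
    for k, z in enumerate(paths):
        lp = log_pi[z[0]] + logb[0, z[0]]
        for j in range(1, M):
            lp += log_gamma[z[j - 1], z[j]] + logb[j, z[j]]
        logp[k] = lp
    return np.array(paths), logp


def brute_posteriors(logb, chain):
    paths, logp = enumerate_paths(logb, chain)
    M = logb.shape[0]
    from scipy.special import logsumexp

    loglik = logsumexp(logp)
    p = np.exp(logp - loglik)
    rho = np.zeros((M, 3))
    for j in range(M):
        for r in range(3):
            rho[j, r] = p[paths[:, j] == r].sum()
    xi = np.zeros((M - 1, 3, 3))
    for j in range(1, M):
        for r in range(3):
            for s in range(3):
                xi[j - 1, r, s] = p[(paths[:, j - 1] == r) & (paths[:, j] == s)].sum()
    return rho, xi, loglik


class TestForwardBackward:
    def test_symmetric_single_window(self):
        chain = ChainParameters(np.full(3, 1 / 3), np.full((3, 3), 1 / 3), np.array([1.0]))
        post = forward_backward(np.array([[-1.0, -1.0, -1.0]]), chain)
        assert np.allclose(post.rho, 1 / 3)

    @pytest.mark.parametrize("trial", range(6))
    def test_matches_exhaustive_path_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        M = int(rng.integers(2, 5))
        logb = rng.normal(-2, 1.5, size=(M, 3))
        chain = random_chain(rng)
        post = forward_backward(logb, chain)
        rho, xi, loglik = brute_posteriors(logb, chain)
        assert abs(post.loglik - loglik) < 1e-10
        assert np.allclose(post.rho, rho, atol=1e-10)
        assert np.allclose(post.xi, xi, atol=1e-10)

    def test_absorbing_chain_pins_state(self):
        chain = ChainParameters(np.array([1.0, 0.0, 0.0]), np.eye(3), np.array([1.0]))
        rng = np.random.default_rng(0)
        post = forward_backward(rng.normal(-3, 1, size=(6, 3)), chain)
        assert np.allclose(post.rho[:, 0], 1.0)

    def test_marginal_consistency(self, rng):
        logb = rng.normal(-2, 1, size=(50, 3))
        chain = random_chain(rng)
        post = forward_backward(logb, chain)
        assert np.allclose(post.rho.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(post.xi.sum(axis=(1, 2)), 1.0, atol=1e-8)
        assert np.allclose(post.xi.sum(axis=2), post.rho[:-1], atol=1e-8)
        assert np.allclose(post.xi.sum(axis=1), post.rho[1:], atol=1e-8)

    def test_rejects_empty_and_dead_windows(self):
        chain = ChainParameters(np.full(3, 1 / 3), np.full((3, 3), 1 / 3), np.array([1.0]))
        with pytest.raises(ValueError):
            forward_backward(np.empty((0, 3)), chain)
        logb = np.array([[-1.0, -1.0, -1.0], [-np.inf, -np.inf, -np.inf]])
        with pytest.raises(ValueError, match="window 1"):
            forward_backward(logb, chain)


class TestViterbi:
    def test_single_window_argmax(self):
        chain = ChainParameters(np.array([0.5, 0.3, 0.2]), np.full((3, 3), 1 / 3), np.array([1.0]))
        path = viterbi(np.array([[-5.0, -1.0, -4.0]]), chain)
        assert path.tolist() == [1]

    @pytest.mark.parametrize("trial", range(6))
    def test_matches_exhaustive_argmax(self, trial):
        rng = np.random.default_rng(200 + trial)
        M = 5
        logb = rng.normal(-2, 1.5, size=(M, 3))
        chain = random_chain(rng)
        path = viterbi(logb, chain)
        paths, logp = enumerate_paths(logb, chain)
        # a maximum-probability path: joint prob equals the exhaustive max
        got = logp[np.flatnonzero((paths == path).all(axis=1))[0]]
        assert abs(got - logp.max()) < 1e-10

    def test_tie_breaks_to_lower_state(self):
        chain = ChainParameters(np.full(3, 1 / 3), np.full((3, 3), 1 / 3), np.array([1.0]))
        path = viterbi(np.zeros((4, 3)), chain)
        assert path.tolist() == [0, 0, 0, 0]


class TestMixturePosteriors:
    def test_symmetry(self):
        w = mixture_posteriors(np.full((3, 2), -4.0), np.array([0.5, 0.5]))
        assert np.allclose(w, 0.5)

    def test_degenerate_mixture(self):
        w = mixture_posteriors(np.array([[-1.0, -0.5]]), np.array([1.0, 0.0]))
        assert np.allclose(w, [[1.0, 0.0]])

    def test_matches_direct_ratio(self, rng):
        c = rng.normal(-5, 2, size=(5, 3))
        delta = rng.dirichlet(np.ones(3))
        w = mixture_posteriors(c, delta)
        direct = delta * np.exp(c)
        direct /= direct.sum(axis=1, keepdims=True)
        assert np.allclose(w, direct, atol=1e-12)


class TestUpdateChain:
    def test_pi_is_first_window_posterior(self, rng):
        rho = np.array([[0.2, 0.5, 0.3], [0.6, 0.2, 0.2], [0.1, 0.8, 0.1]])
        xi = rng.dirichlet(np.ones(9), size=2).reshape(2, 3, 3)
        w = rng.dirichlet(np.ones(2), size=3)
        chain = update_chain(PosteriorSet(rho=rho, xi=xi, loglik=0.0, w=w))
        assert np.allclose(chain.pi, [0.2, 0.5, 0.3])

    def test_gamma_matches_hand_ratio(self, rng):
        rho = np.array([[0.2, 0.5, 0.3], [0.6, 0.2, 0.2], [0.1, 0.8, 0.1]])
        xi = rng.dirichlet(np.ones(9), size=2).reshape(2, 3, 3)
        # make xi marginally consistent with rho by construction of the test:
        # only the ratio formula is checked
        w = rng.dirichlet(np.ones(2), size=3)
        chain = update_chain(PosteriorSet(rho=rho, xi=xi, loglik=0.0, w=w))
        for r in range(3):
            denom = rho[:-1, r].sum()
            num = xi[:, r, :].sum(axis=0)
            assert np.allclose(chain.gamma[r], num / num.sum())
            assert np.allclose(chain.delta, (rho[:, 1] @ w) / rho[:, 1].sum())

    def test_unoccupied_differential_state_keeps_delta(self, rng):
        rho = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        xi = np.zeros((1, 3, 3))
        xi[0, 0, 0] = 1.0
        prev = random_chain(rng)
        chain = update_chain(
            PosteriorSet(rho=rho, xi=xi, loglik=0.0, w=np.full((2, prev.L), 0.5)), prev=prev
        )
        assert np.allclose(chain.delta, prev.delta)


class TestMStepObservations:
    def make(self, rho, w, counts=None, rng=None):
        n = 2
        counts = counts if counts is not None else rng.integers(0, 10, size=(n, rho.shape[0]))
        ds = CountDataset(counts, np.array([0, 1]), grid_windows(rho.shape[0]))
        post = PosteriorSet(rho=rho, xi=np.zeros((rho.shape[0] - 1, 3, 3)), loglik=0.0, w=w)
        return ds, post

    def test_pure_background_window(self):
        ds, post = self.make(np.array([[1.0, 0.0, 0.0]]), np.array([[0.5, 0.5]]),
                             counts=np.array([[3], [4]]))
        obs = build_mstep_observations(ds, post, enumerate_patterns(2))
        live = obs.weight > 0
        assert np.all(obs.cov[live] == 0.0)
        assert obs.weight[live].sum() == pytest.approx(2.0)

    def test_pattern_assigns_covariates_by_condition(self):
        # all mass on pattern S_1 = {condition 0}
        ds, post = self.make(np.array([[0.0, 1.0, 0.0]]), np.array([[1.0, 0.0]]),
                             counts=np.array([[7], [2]]))
        obs = build_mstep_observations(ds, post, enumerate_patterns(2))
        live = obs.weight > 0
        assert sorted(zip(obs.y[live], obs.cov[live])) == [(2.0, 0.0), (7.0, 1.0)]
        assert np.allclose(obs.weight[live], 1.0)

    def test_weight_conservation(self, rng):
        M = 7
        rho = rng.dirichlet(np.ones(3), size=M)
        w = rng.dirichlet(np.ones(2), size=M)
        ds, post = self.make(rho, w, rng=rng)
        obs = build_mstep_observations(ds, post, enumerate_patterns(2))
        assert abs(obs.weight.sum() - M * 2) < 1e-10


class TestRejectionControl:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(weights=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_output_support_is_zero_floor_or_original(self, weights):
        rng = np.random.default_rng(1)
        w = np.asarray(weights)
        out = rejection_control(w, 0.05, rng)
        big = w >= 0.05
        assert np.array_equal(out[big], w[big])
        assert set(np.unique(out[~big])) <= {0.0, 0.05}

    def test_above_threshold_unchanged(self, rng):
        w = np.array([0.5, 0.05, 1.0])
        assert np.array_equal(rejection_control(w, 0.05, rng), w)

    def test_zero_stays_zero(self, rng):
        assert rejection_control(np.zeros(100), 0.05, rng).sum() == 0.0

    def test_unbiased_with_binary_support(self):
        rng = np.random.default_rng(42)
        w = np.full(100_000, 0.02)
        out = rejection_control(w, 0.05, rng)
        assert set(np.unique(out)) <= {0.0, 0.05}
        se = np.sqrt(0.02 * (0.05 - 0.02) / len(w))
        assert abs(out.mean() - 0.02) < 3 * se

    def test_invalid_threshold(self, rng):
        with pytest.raises(ValueError):
            rejection_control(np.array([0.5]), 0.0, rng)
        with pytest.raises(ValueError):
            rejection_control(np.array([0.5]), 1.5, rng)


class TestAggregation:
    def test_identical_columns_collapse(self):
        ds = CountDataset(np.array([[1, 1, 3, 1], [2, 2, 0, 2]]),
                          np.array([0, 1]), grid_windows(4))
        rho = np.tile([1.0, 0.0, 0.0], (4, 1))
        post = PosteriorSet(rho=rho, xi=np.zeros((3, 3, 3)), loglik=0.0,
                            w=np.full((4, 2), 0.5))
        agg = aggregate_observations(build_mstep_observations(ds, post, enumerate_patterns(2)))
        live = agg.weight > 0
        # background block: y=1 seen 3x, y=2 seen 3x, y=3 and y=0 once each
        got = {(y, c): wt for y, c, wt in zip(agg.y[live], agg.cov[live], agg.weight[live])}
        assert got[(1.0, 0.0)] == pytest.approx(3.0)
        assert got[(2.0, 0.0)] == pytest.approx(3.0)
        assert got[(0.0, 0.0)] == pytest.approx(1.0)
        assert got[(3.0, 0.0)] == pytest.approx(1.0)

    def test_distinct_observations_pass_through(self):
        obs = MStepObservations(
            y=np.array([1.0, 2.0]), u=np.zeros(2), cov=np.array([0.0, 1.0]),
            weight=np.array([0.3, 0.7]),
        )
        agg = aggregate_observations(obs)
        assert len(agg) == 2 and agg.weight.sum() == pytest.approx(1.0)

    def test_objective_unchanged_by_aggregation(self, rng, glm):
        obs = MStepObservations(
            y=rng.integers(0, 5, size=300).astype(float),
            u=np.zeros(300),
            cov=(rng.random(300) < 0.5).astype(float),
            weight=rng.random(300),
        )
        agg = aggregate_observations(obs)
        before = weighted_nb_objective(glm, obs.y, obs.u, obs.cov, obs.weight)
        after = weighted_nb_objective(glm, agg.y, agg.u, agg.cov, agg.weight)
        assert abs(before - after) < 1e-10
        assert len(agg) < len(obs)


@pytest.fixture(scope="module")
def sim_small():
    return simulate(SimulationConfig(G=2, n=2, M=8000, seed=11))


class TestEMFit:
    def test_monotone_loglik_without_rejection_control(self, sim_small):
        fit = em_fit(sim_small.dataset, rcem=False, max_iter=25)
        assert np.all(np.diff(fit.loglik_trace) > -1e-6)

    def test_truth_initialization_is_stable(self):
        sim = simulate(SimulationConfig(G=2, n=2, M=50_000, seed=5))
        from chromdiff.hmm import ModelParameters, initialize

        design = enumerate_patterns(2)
        start = initialize(sim.dataset, design)
        init = ModelParameters(
            chain=start.chain, glm=sim.truth.glm_truth, design=design
        )
        fit = em_fit(sim.dataset, init=init, seed=1)
        truth = sim.truth.glm_truth.as_array()
        rel = np.abs(fit.params.glm.as_array() - truth) / np.abs(truth)
        assert np.all(rel[:3] < 0.01)  # beta1, beta3, lambda1
        assert rel[3] < 0.3  # lambda3 is weakly identified at this scale

    def test_rcem_matches_plain_em(self, sim_small):
        on = em_fit(sim_small.dataset, rcem=True, seed=3)
        off = em_fit(sim_small.dataset, rcem=False, seed=3)
        rel = np.abs(on.params.glm.as_array() - off.params.glm.as_array()) / np.abs(
            off.params.glm.as_array()
        )
        assert np.all(rel[:3] < 0.02) and rel[3] < 0.3

    def test_posterior_invariants_at_solution(self, sim_small):
        fit = em_fit(sim_small.dataset, seed=2)
        post = fit.posteriors
        assert np.allclose(post.rho.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(post.w.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(post.xi.sum(axis=2), post.rho[:-1], atol=1e-8)

    def test_single_condition_rejected(self):
        ds = CountDataset(np.array([[1, 2, 3]]), np.array([0]), grid_windows(3))
        with pytest.raises(ValueError):
            em_fit(ds)


class TestBIC:
    def make_fit(self, loglik, L):
        design = enumerate_patterns(3).subset(np.arange(L))
        chain = ChainParameters(np.array([0.8, 0.1, 0.1]),
                                np.full((3, 3), 0.01) + np.eye(3) * 0.97,
                                np.full(L, 1 / L))
        params_ = None
        from chromdiff.hmm import ModelParameters

        params_ = ModelParameters(chain=chain,
                                  glm=GLMParameters(1.0, 1.0, 1.0, 0.1),
                                  design=design)
        post = PosteriorSet(rho=np.ones((1, 3)) / 3, xi=np.zeros((0, 3, 3)), loglik=loglik)
        return FitResult(params=params_, posteriors=post, iterations=1,
                         converged=True, loglik_trace=np.array([loglik]))

    def test_direct_formula(self):
        fit = self.make_fit(-1000.0, 2)
        assert bic(fit, 100) == pytest.approx(2000.0 + 13 * np.log(100))

    def test_penalty_monotone_in_components(self):
        assert bic(self.make_fit(-500.0, 5), 100) > bic(self.make_fit(-500.0, 2), 100)


class TestPruning:
    def test_retains_only_populated_patterns(self):
        # G=3 truth populates only {1} and {2,3} (0-based {0} and {1,2})
        nu = np.zeros(8)
        nu[0], nu[-1] = 0.80, 0.05
        nu[1] = 0.075   # condition 0 enriched
        nu[6] = 0.075   # conditions 1 and 2 enriched (bits 110)
        chain = 0.95 * np.eye(8) + 0.05 * nu[None, :]
        sim = simulate(SimulationConfig(G=3, n=1, M=20_000, config_chain=chain, seed=8))
        fit = em_fit(sim.dataset, seed=8, max_iter=100)
        pruned = prune_components(sim.dataset, fit, seed=8, max_iter=100)
        assert set(pruned.params.design.sets) == {(0,), (1, 2)}
        assert pruned.bic < fit.bic

    def test_no_pruning_when_all_above_floor(self, rng):
        sim = simulate(SimulationConfig(G=2, n=1, M=5000, seed=9))
        fit = em_fit(sim.dataset, seed=9)
        if fit.params.chain.delta.min() >= 0.05:
            pruned = prune_components(sim.dataset, fit, seed=9)
            assert pruned is fit
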