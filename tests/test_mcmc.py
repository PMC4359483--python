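"""Tests of the posterior sampler, trace summaries and MAP selection."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from clonetree.mcmc import (McmcConfig, Sample, Trace, TreeSampler,
                            estimate_equilibrium, mpear_summary,
                            pear_index, posterior_similarity, run_mcmc,
                            select_map_tree)
from clonetree.models import (MarkerMatrix, local_loglik, root_log_prior,
                              transition_logpdf)
from clonetree.evaluate import v_measure
from clonetree.simulate import make_fixture, sample_observations
from clonetree.tssb import clone_weights

from conftest import cached_chain


def _mm(rows, mask=None):
    rows = np.asarray(rows, dtype=np.int8)
    mask = (np.zeros_like(rows, dtype=bool) if mask is None
            else np.asarray(mask, dtype=bool))
    return MarkerMatrix(rows, mask)


class TestEstimateEquilibrium:
    def test_balanced(self):
        assert estimate_equilibrium(_mm([[1, 1], [0, 0]])) == (0.5, 0.5)

    def test_missing_excluded(self):
        bu, bm = estimate_equilibrium(
            _mm([[1, 0], [1, 0]], mask=[[False, True], [False, False]]))
        assert bm == pytest.approx(2 / 3)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            estimate_equilibrium(_mm([[1, 1], [1, 1]]))

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            estimate_equilibrium(_mm([[1, 0]], mask=[[True, True]]))


class TestChainSchedule:
    def test_default_retains_ten_thousand(self):
        assert McmcConfig().n_retained == 10_000

    def test_short_chain_arithmetic(self):
        data = _mm([[1, 0], [0, 1], [1, 1], [0, 0]])
        cfg = McmcConfig(burnin=0, n_keep=10, thin=5, seed=1)
        assert len(run_mcmc(data, config=cfg)) == 2

    def test_deterministic_under_seed(self):
        data = _mm(np.random.default_rng(0).integers(0, 2, (12, 4)))
        cfg = McmcConfig(burnin=20, n_keep=40, thin=4, seed=9)
        t1 = run_mcmc(data, config=cfg)
        t2 = run_mcmc(data, config=cfg)
        for s1, s2 in zip(t1, t2):
            assert (s1.codes == s2.codes).all()
            assert s1.cdll == pytest.approx(s2.cdll)
            assert s1.node_labels == s2.node_labels

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(burnin=-1)
        with pytest.raises(ValueError):
            McmcConfig(thin=0)


def _trace_from_codes(code_rows):
    samples = []
    for row in code_rows:
        row = np.asarray(row)
        samples.append(Sample(node_labels=[(i,) for i in
                                           range(row.max() + 1)],
                              codes=row, snapshot={}, cdll=0.0, n_big=0))
    return Trace(samples=samples, n_obs=len(code_rows[0]),
                 kind="methylation", config=McmcConfig())


class TestPosteriorSimilarity:
    def test_constant_trace(self):
        psm = posterior_similarity(_trace_from_codes([[0, 0, 1]] * 4))
        assert psm.tolist() == [[1, 1, 0], [1, 1, 0], [0, 0, 1]]

    def test_half_and_half(self):
        psm = posterior_similarity(_trace_from_codes([[0, 0], [0, 1]]))
        assert psm[0, 1] == pytest.approx(0.5)

    def test_symmetric_unit_diagonal(self, rng):
        rows = rng.integers(0, 3, (20, 8))
        psm = posterior_similarity(_trace_from_codes(list(rows)))
        assert (psm == psm.T).all()
        assert np.diag(psm) == pytest.approx(1.0)
        assert ((psm >= 0) & (psm <= 1)).all()

    def test_empty_trace_rejected(self):
        t = Trace(samples=[], n_obs=0, kind="methylation",
                  config=McmcConfig())
        with pytest.raises(ValueError):
            posterior_similarity(t)


def _set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


class TestMpear:
    def test_block_diagonal_recovered(self):
        psm = np.kron(np.eye(3), np.ones((3, 3)))
        labels = mpear_summary(psm)
        assert len(set(labels)) == 3
        assert len(set(labels[:3])) == 1

    def test_all_ones_single_cluster(self):
        labels = mpear_summary(np.ones((6, 6)))
        assert len(set(labels)) == 1

    def test_matches_brute_force_over_all_partitions(self):
        # noisy two-block psm over 6 points; exhaustive search over the
        # 203 set partitions of 6 elements
        psm = np.full((6, 6), 0.1)
        psm[:3, :3] = 0.85
        psm[3:, 3:] = 0.9
        rng = np.random.default_rng(2)
        noise = rng.uniform(-0.05, 0.05, (6, 6))
        psm += (noise + noise.T) / 2
        np.fill_diagonal(psm, 1.0)
        parts = list(_set_partitions(list(range(6))))
        assert len(parts) == 203
        best = -np.inf
        for part in parts:
            labels = np.empty(6, dtype=int)
            for k, block in enumerate(part):
                labels[block] = k
            best = max(best, pear_index(labels, psm))
        got = pear_index(mpear_summary(psm), psm)
        assert got == pytest.approx(best)


class TestSelectMapTree:
    @staticmethod
    def _sample(n_big, cdll):
        return Sample(node_labels=[()], codes=np.zeros(1, int),
                      snapshot={"id": (n_big, cdll)}, cdll=cdll,
                      n_big=n_big)

    def _trace(self, pairs):
        return Trace(samples=[self._sample(b, c) for b, c in pairs],
                     n_obs=1, kind="methylation", config=McmcConfig())

    def test_single_sample(self):
        t = self._trace([(2, -10.0)])
        assert select_map_tree(t).cdll == -10.0

    def test_majority_group_best_likelihood(self):
        t = self._trace([(2, -30.0), (2, -10.0), (2, -20.0), (3, -1.0)])
        best = select_map_tree(t)
        assert best.n_big == 2 and best.cdll == -10.0

    def test_frequency_tie_prefers_fewer_big_nodes(self):
        t = self._trace([(2, -5.0), (2, -6.0), (3, -1.0), (3, -2.0)])
        assert select_map_tree(t).n_big == 2


class TestCompleteDataLoglik:
    def _sampler(self, data, **kw):
        # hand-built tree states below: start everything at the root
        cfg = McmcConfig(seed=4, init="root", **kw)
        return TreeSampler(data, cfg)

    def test_single_clone_reduction(self):
        data = _mm([[1, 0], [0, 0], [1, 1]])
        s = self._sampler(data, max_depth=0)
        p = s.params
        expected = root_log_prior(s.tree.root.theta, p.mu, p.Lambda)
        for row, mrow in zip(data.values, data.missing_mask):
            expected += local_loglik(row, s.tree.root.theta, mrow)
        assert s.complete_data_loglik() == pytest.approx(expected)

    def test_matches_exhaustive_enumeration(self):
        data = _mm([[1], [0]])
        s = self._sampler(data)
        # instantiate one child with known parameters
        root = s.tree.root
        root.sticks, root.children = [1.0], [None]
        child = s.tree._make_child(root, 1, s.rng)
        root.nu, root.theta = 0.6, np.array([-2.0])
        child.nu, child.t = 1.0, 0.7
        child.theta = np.array([2.5])
        root.data, child.data = {0}, {1}
        root._ll = child._ll = None
        s.assign = [root, child]
        w = clone_weights(s.tree)
        pis = [w[()], w[(1,)]]
        nodes = [root, child]
        term1 = 0.0
        for n in range(2):
            liks = [pis[k] * math.exp(local_loglik(data.values[n],
                                                   nodes[k].theta))
                    for k in range(2)]
            term1 += math.log(sum(liks))
        p = s.params
        expected = (term1 + root_log_prior(root.theta, p.mu, p.Lambda)
                    + transition_logpdf(child.theta, root.theta, 0.7, p))
        assert s.complete_data_loglik() == pytest.approx(expected)

    def test_insensitive_to_negligible_empty_node(self):
        data = _mm([[1], [0], [1]])
        s = self._sampler(data)
        root = s.tree.root
        before = s.complete_data_loglik()
        root.sticks, root.children = [1e-14], [None]
        child = s.tree._make_child(root, 1, s.rng)
        child.theta = np.array([0.0])
        after = s.complete_data_loglik()
        assert abs(after - before) < 1e-9


class TestSwapMove:
    def _state(self, seed=0):
        rng = np.random.default_rng(seed)
        data = _mm(rng.integers(0, 2, (30, 4)))
        cfg = McmcConfig(seed=seed)
        s = TreeSampler(data, cfg)
        for _ in range(30):
            s.sweep()
        return s

    def test_symmetric_state_always_accepted(self):
        # two nodes with identical parameters, masses and data counts:
        # the Metropolis ratio is 1, so the swap always goes through
        data = _mm([[1, 0], [1, 0], [0, 1], [0, 1]])
        for seed in range(10):
            s = TreeSampler(data, McmcConfig(seed=seed, init="root"))
            root = s.tree.root
            root.sticks, root.children = [1.0], [None]
            child = s.tree._make_child(root, 1, s.rng)
            child.nu, child.t = root.nu, 1.0
            theta = np.array([1.5, -1.5])
            root.theta = theta.copy()
            child.theta = theta.copy()
            root._ll = child._ll = None
            root.data, child.data = {0, 1}, {2, 3}
            s.assign = [root, root, child, child]
            assert s.swap_clone_move() is True

    def test_observation_count_conserved(self):
        s = self._state(3)
        for _ in range(50):
            s.swap_clone_move()
            total = sum(len(n.data) for n in s.tree.iter_nodes())
            assert total == s.N

    def test_root_never_left_empty(self):
        s = self._state(5)
        for _ in range(100):
            s.sweep()
            assert len(s.tree.root.data) >= 1

    def test_single_node_tree_is_noop(self):
        data = _mm([[1, 0], [0, 1]])
        s = TreeSampler(data, McmcConfig(seed=2, max_depth=0))
        assert s.swap_clone_move() is False


class TestKernelCorrectness:
    def test_root_posterior_matches_quadrature(self):
        """Single observation, root-only tree, fixed hyperparameters:
        the chain's marginal over theta_root at a site must match the
        analytic posterior root_prior(theta) * likelihood(x | theta)
        (sites decouple, so the one-site marginal is exact)."""
        data = _mm([[1, 0]])
        cfg = McmcConfig(burnin=500, n_keep=6000, thin=1, seed=8,
                         max_depth=0, update_hypers=False, do_swap=False,
                         update_sticks=False, mu_init=2.0, Lambda_init=1.0)
        s = TreeSampler(data, cfg)
        draws = []
        for i in range(cfg.burnin + cfg.n_keep):
            s.sweep()
            if i >= cfg.burnin:
                draws.append(float(s.tree.root.theta[0]))
        draws = np.array(draws)
        grid = np.linspace(-15, 15, 30001)
        logp = (-np.abs(grid + 2.0) - np.log(2.0)
                - np.log1p(np.exp(-grid)))
        dens = np.exp(logp - logsumexp(logp))
        mean = float(grid @ dens)
        sd = math.sqrt(float(grid ** 2 @ dens) - mean ** 2)
        assert draws.mean() == pytest.approx(mean, abs=0.15)
        assert draws.std() == pytest.approx(sd, rel=0.15)

    def test_assignment_kernel_stationary_under_fixed_sticks(self):
        """Two observations, one site, frozen two-node tree: the slice
        assignment kernel must leave the exact conditional
        Discrete(pi_eps * lik) invariant (chi-square over the 4 joint
        assignment states)."""
        data = _mm([[1], [0]])
        cfg = McmcConfig(seed=12, max_depth=1, init="root",
                         update_theta=False, update_t=False,
                         update_sticks=False, update_hypers=False,
                         do_swap=False)
        s = TreeSampler(data, cfg)
        root = s.tree.root
        root.nu = 0.5
        root.sticks, root.children = [1.0], [None]
        child = s.tree._make_child(root, 1, s.rng)
        child.t = 1.0
        root.theta = np.array([-1.5])
        child.theta = np.array([1.0])
        root._ll = child._ll = None
        root.data, child.data = {0, 1}, set()
        s.assign = [root, root]
        w = clone_weights(s.tree)
        pis = {0: w[()], 1: w[(1,)]}
        liks = {(n, k): math.exp(local_loglik(data.values[n], th))
                for n, _ in enumerate(data.values)
                for k, th in ((0, root.theta), (1, child.theta))}
        probs = np.array([pis[a] * liks[(0, a)] * pis[b] * liks[(1, b)]
                          for a in (0, 1) for b in (0, 1)])
        probs /= probs.sum()
        counts = np.zeros(4)
        n_sweeps = 20_000
        for _ in range(n_sweeps):
            s.resample_assignments()
            a = 0 if s.assign[0] is root else 1
            b = 0 if s.assign[1] is root else 1
            counts[2 * a + b] += 1
        p = stats.chisquare(counts, probs * n_sweeps).pvalue
        assert p > 1e-3


class TestRecovery:
    def test_monoclonal_perfect_clustering(self):
        _, _, labels, trace = cached_chain("monoclonal", 150, 0.0, 7, 7,
                                           burnin=400, n_keep=600, thin=5)
        pred = mpear_summary(posterior_similarity(trace))
        assert v_measure(labels, pred.tolist()) == pytest.approx(1.0)

    def test_mutator_near_perfect_clustering(self):
        _, _, labels, trace = cached_chain("mutator", 260, 0.0, 7, 7,
                                           burnin=1500, n_keep=1500, thin=4)
        pred = mpear_summary(posterior_similarity(trace))
        assert v_measure(labels, pred.tolist()) >= 0.95

    def test_two_clone_co_clustering_separates(self):
        """Posterior similarity separates two well-separated clones."""
        fx = make_fixture("monoclonal")
        X, labels = sample_observations(fx, 80, np.random.default_rng(2))
        cfg = McmcConfig(burnin=800, n_keep=600, thin=5, seed=2)
        trace = run_mcmc(X, config=cfg)
        psm = posterior_similarity(trace)
        in_root = [i for i, l in enumerate(labels) if l == ()]
        in_child = [i for i, l in enumerate(labels) if l == (1,)]
        off_block = psm[np.ix_(in_root, in_child)]
        assert off_block.mean() < 0.1

    def test_degenerate_data_propagates(self):
        with pytest.raises(ValueError):
            run_mcmc(_mm([[1, 1], [1, 1]]),
                     config=McmcConfig(burnin=1, n_keep=2, thin=1))
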