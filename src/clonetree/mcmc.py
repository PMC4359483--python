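"""Posterior sampling for the nonparametric clone-tree mixture model.

The sampler targets the joint posterior over clone assignments, clone
parameters, branch lengths, stick variables, and the kernel
hyperparameters ``mu`` and ``Lambda``, with ``(lam, alpha0, gamma)`` and
the equilibrium frequencies held fixed.  One sweep comprises:

(a) per-observation assignment resampling by slice sampling over the
    stick-breaking layout, instantiating new nodes lazily (new clone
    parameters are drawn from the parent transition kernel, branch
    lengths from their Exponential(1) prior), followed by a vectorized
    restricted-Gibbs refinement that redraws all assignments jointly
    over the instantiated nodes plus one fresh prior-drawn child per
    node (the sampler's clone-birth mechanism);
(b) per-node, per-site Metropolis updates of ``theta`` against the local
    likelihood, the incoming transition density, and the outgoing
    transition terms to the children;
(c) Metropolis random-walk updates of each branch length on the log
    scale under the Exponential(1) prior;
(d) Gibbs resampling of the nu and psi sticks from their Beta full
    conditionals given the assignment counts;
(e) Metropolis updates of ``mu`` (half-Normal(5) hyperprior) and
    ``Lambda`` (Gamma(2, 1) hyperprior);
(f) culling of empty leaf-side nodes;

followed by swap-clone moves -- the parameters, assigned data and nu
masses of two random nodes are exchanged, accepted by a Metropolis
ratio on the joint density, with sticks then resampled -- and
prune-and-regraft moves relocating whole subtrees.  States in which the
root clone holds no observations are treated as invalid.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import logsumexp

from .models import (EvolutionParams, MarkerMatrix, root_log_prior,
                     sigmoid)
from .tssb import Node, TssbTree

__all__ = [
    "McmcConfig",
    "Sample",
    "Trace",
    "TreeSampler",
    "estimate_equilibrium",
    "run_mcmc",
    "posterior_similarity",
    "pear_index",
    "mpear_summary",
    "select_map_tree",
]


@dataclass
class McmcConfig:
    """Chain schedule and fixed hyperparameters.

    The default schedule (burn-in 30,000; 50,000 kept sweeps thinned by
    5) retains 10,000 samples.  ``lam=2, alpha0=0.3, gamma=0.1`` are the
    fixed tree hyperparameters.
    """

    burnin: int = 30_000
    n_keep: int = 50_000
    thin: int = 5
    seed: int = 0
    lam: float = 2.0
    alpha0: float = 0.3
    gamma: float = 0.1
    max_depth: int = 15
    eta: float = 1.0
    mu_init: float = 4.0
    Lambda_init: float = 1.0
    theta_step: float = 0.5
    theta_iters: int = 3    # MH refinement passes per sweep
    assignment_passes: int = 1  # slice-sampling passes per sweep
    gibbs_passes: int = 1   # restricted-Gibbs refinement passes per sweep
    t_step: float = 0.5
    mu_step: float = 0.25
    Lambda_step: float = 0.25
    swap_moves: int = 5     # swap-clone attempts per sweep
    reattach_moves: int = 5  # subtree prune-and-regraft attempts per sweep
    mu_hyper_shape: float = 4.0     # Gamma prior for mu (mode 3)
    mu_hyper_scale: float = 1.0
    Lambda_hyper_shape: float = 2.0  # Gamma prior for Lambda (mean 1)
    Lambda_hyper_scale: float = 0.5
    init: str = "patterns"  # "patterns" (over-split start) or "root"
    init_max_groups: int = 30
    # toggles, mainly for targeted validation of individual kernels
    resample_assignments: bool = True
    update_theta: bool = True
    update_t: bool = True
    update_sticks: bool = True
    update_hypers: bool = True
    do_swap: bool = True

    def __post_init__(self):
        if self.burnin < 0 or self.n_keep <= 0 or self.thin <= 0:
            raise ValueError("invalid chain schedule")

    @property
    def n_retained(self) -> int:
        return self.n_keep // self.thin


@dataclass
class Sample:
    """One retained posterior sample."""

    node_labels: list                 # clone label per integer code
    codes: np.ndarray                 # int code per observation
    snapshot: dict                    # label -> NodeSnap
    cdll: float                       # complete-data log-likelihood
    n_big: int                        # nodes with pi > 0.01

    @property
    def labels(self) -> list:
        """Clone label per observation."""
        return [self.node_labels[c] for c in self.codes]


@dataclass
class Trace:
    """Ordered retained samples of one chain."""

    samples: list
    n_obs: int
    kind: str
    config: McmcConfig

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)


def _P_entries(p: EvolutionParams, t: float) -> tuple:
    """Closed-form ``(P[m->m], P[u->m])`` of the two-state chain.

    Equivalent to reading those entries off ``transition_matrix``; kept
    scalar for the sampler's inner loops.
    """
    if p.kind == "methylation":
        e = math.exp(-p.rho * t)
        return p.beta_m + p.beta_u * e, p.beta_m * (1.0 - e)
    e = math.exp(-p.beta_m * p.rho * t)
    return 1.0, 1.0 - e


def _safe_log(x: float) -> float:
    return math.log(x) if x > 0.0 else -np.inf


def _trans_site_terms(theta_child: np.ndarray, theta_parent: np.ndarray,
                      t: float, p: EvolutionParams) -> np.ndarray:
    """Per-site log transition density (fast path of the Laplace-mixture
    kernel; agrees with ``models.transition_logpdf``)."""
    pmm, pum = _P_entries(p, t)
    lw = np.where(theta_parent >= p.eta, _safe_log(pmm), _safe_log(pum))
    l1w = np.where(theta_parent >= p.eta,
                   _safe_log(1.0 - pmm), _safe_log(1.0 - pum))
    c = -math.log(2.0 * p.Lambda)
    pos = c - np.abs(theta_child - p.mu) / p.Lambda
    neg = c - np.abs(theta_child + p.mu) / p.Lambda
    return np.logaddexp(lw + pos, l1w + neg)


def estimate_equilibrium(data: MarkerMatrix) -> tuple:
    """Equilibrium frequencies ``(beta_u, beta_m)`` from the population.

    ``beta_m`` is the mean of the non-missing entries.  Fully missing or
    constant matrices are rejected (the CTMC equilibrium would
    degenerate).
    """
    obs = data.values[~data.missing_mask]
    if obs.size == 0:
        raise ValueError("marker matrix has no observed entries")
    beta_m = float(obs.mean())
    if beta_m in (0.0, 1.0):
        raise ValueError("degenerate data: all observed entries identical")
    return 1.0 - beta_m, beta_m


class TreeSampler:
    """MCMC engine for one marker matrix.

    Holds the mutable chain state (tree, assignments, hyperparameters)
    and caches each node's per-observation log-likelihood vector, which
    is invalidated whenever the node's ``theta`` changes.
    """

    def __init__(self, data: MarkerMatrix, config: McmcConfig,
                 model_kind: Optional[str] = None):
        self.data = data
        self.config = config
        self.kind = model_kind or data.kind
        self.rng = np.random.default_rng(config.seed)
        obs_mask = ~data.missing_mask
        self.X1 = ((data.values == 1) & obs_mask).astype(float)
        self.X0 = ((data.values == 0) & obs_mask).astype(float)
        self.N, self.M = data.values.shape
        beta_u, beta_m = estimate_equilibrium(data)
        self.params = EvolutionParams(
            kind=self.kind, beta_m=beta_m, mu=config.mu_init,
            Lambda=config.Lambda_init, eta=config.eta)
        self.tree = TssbTree(config.lam, config.alpha0, config.gamma,
                             max_depth=config.max_depth,
                             param_prior=self._draw_node_params)
        root = self.tree.root
        root.nu = (1.0 if config.max_depth == 0
                   else float(self.rng.beta(1.0, config.alpha0)))
        root.theta = self.rng.laplace(-self.params.mu, self.params.Lambda,
                                      size=self.M)
        root.data = set(range(self.N))
        self.assign = [root] * self.N
        if config.init == "patterns" and config.max_depth >= 1:
            self._init_pattern_star()
        elif config.init not in ("patterns", "root"):
            raise ValueError(f"unknown init strategy {config.init!r}")

    def _init_pattern_star(self) -> None:
        """Over-split starting state: observations grouped by observed
        pattern, groups attached as a star under the root.

        Merging redundant clones is the easy direction for the sampler
        (plain Gibbs reassignment), whereas splitting a heavy clone
        requires rare birth events, so short chains mix far better from
        an over-split state.  Initialization does not change the
        invariant distribution.  Rare patterns (beyond
        ``init_max_groups``) are folded into the nearest frequent
        pattern by Hamming distance on observed sites; the group whose
        pattern has the fewest present markers seeds the root.
        """
        rng = self.rng
        p = self.params
        obs_mask = ~self.data.missing_mask
        keys = [tuple(int(v) if m else -1
                      for v, m in zip(row, mrow))
                for row, mrow in zip(self.data.values, obs_mask)]
        groups: dict = {}
        for n, key in enumerate(keys):
            groups.setdefault(key, []).append(n)
        ranked = sorted(groups, key=lambda k: (-len(groups[k]), k))
        top = ranked[:self.config.init_max_groups]
        reps = np.array([[max(v, 0) for v in key] for key in top])
        rep_mask = np.array([[v >= 0 for v in key] for key in top])
        for key in ranked[len(top):]:
            row = np.array([max(v, 0) for v in key])
            mask = np.array([v >= 0 for v in key])
            both = rep_mask & mask
            d = ((reps != row) & both).sum(axis=1)
            top_key = top[int(np.argmin(d))]
            groups[top_key].extend(groups.pop(key))
        # the group with the fewest present markers seeds the root
        root_key = min(top, key=lambda k: (sum(v == 1 for v in k), k))
        root = self.tree.root
        root.data = set(groups[root_key])
        root.theta = np.where(
            np.array([v == 1 for v in root_key]), p.mu, -p.mu
        ).astype(float)
        for key in top:
            if key == root_key:
                continue
            root.sticks.append(float(rng.beta(1.0, self.config.gamma)))
            root.children.append(None)
            child = self.tree._make_child(root, len(root.sticks), rng)
            child.theta = np.where(
                np.array([v == 1 for v in key]), p.mu, -p.mu
            ).astype(float)
            child._ll = None
            child.data = set(groups[key])
        for node in self.tree.iter_nodes():
            for n in node.data:
                self.assign[n] = node
        self.resample_sticks()

    # -- node-level quantities --------------------------------------------

    def _draw_node_params(self, parent: Node, rng) -> tuple:
        t = max(float(rng.exponential(1.0)), 1e-6)
        pmm, pum = _P_entries(self.params, t)
        w = np.where(parent.theta >= self.params.eta, pmm, pum)
        loc = np.where(rng.random(self.M) < w, self.params.mu,
                       -self.params.mu)
        theta = rng.laplace(loc, self.params.Lambda)
        return theta, t

    def ll(self, node: Node) -> np.ndarray:
        """Cached per-observation log-likelihood vector of a node."""
        if node._ll is None:
            s = sigmoid(node.theta)
            node._ll = self.X1 @ np.log(s) + self.X0 @ np.log(1.0 - s)
        return node._ll

    def _trans_total(self, mu: float, Lam: float) -> float:
        """Root prior plus all parent-to-child transition densities."""
        p = replace(self.params, mu=mu, Lambda=Lam)
        total = root_log_prior(self.tree.root.theta, mu, Lam)
        for node in self.tree.iter_nodes():
            if node.parent is not None:
                total += float(_trans_site_terms(
                    node.theta, node.parent.theta, node.t, p).sum())
        return total

    def log_joint(self) -> float:
        """Joint log density of assignments, data, and clone parameters
        (terms constant under the swap move are omitted)."""
        total = 0.0
        for node, pi in self.tree.node_weights().items():
            nd = len(node.data)
            if nd:
                if pi <= 0.0:
                    return -np.inf
                idx = np.fromiter(node.data, dtype=np.intp, count=nd)
                total += nd * math.log(pi) + float(self.ll(node)[idx].sum())
        return total + self._trans_total(self.params.mu, self.params.Lambda)

    def complete_data_loglik(self) -> float:
        """Assignment-marginalized data likelihood plus the clone
        parameter transition terms (assignments integrated out against
        the instantiated clone weights).

        Transition terms run over the occupied part of the tree only:
        the parameters of an empty leaf-side node marginalize out of the
        complete-data likelihood (its kernel integrates to one), so
        instantiating one must not shift the value.
        """
        occupied = set()

        def mark(node: Node) -> bool:
            keep = bool(node.data)
            for child in node.real_children():
                keep |= mark(child)
            if keep:
                occupied.add(node)
            return keep

        mark(self.tree.root)
        nodes = []
        logpi = []
        for node, pi in self.tree.node_weights().items():
            if pi > 0.0:
                nodes.append(node)
                logpi.append(math.log(pi))
        L = np.stack([self.ll(n) for n in nodes])
        term1 = float(logsumexp(L + np.array(logpi)[:, None], axis=0).sum())
        p = self.params
        term2 = root_log_prior(self.tree.root.theta, p.mu, p.Lambda)
        for node in occupied:
            if node.parent is not None:
                term2 += float(_trans_site_terms(
                    node.theta, node.parent.theta, node.t, p).sum())
        return term1 + term2

    # -- (a) assignments ---------------------------------------------------

    def _move_obs(self, n: int, new_node: Node) -> None:
        old = self.assign[n]
        old.data.discard(n)
        new_node.data.add(n)
        self.assign[n] = new_node

    def resample_assignments(self) -> None:
        rng = self.rng
        tree = self.tree
        for n in rng.permutation(self.N):
            n = int(n)
            cur = self.assign[n]
            cur_path = cur.label
            slice_ll = math.log(rng.random()) + self.ll(cur)[n]
            min_u, max_u = 0.0, 1.0
            while True:
                u = min_u + (max_u - min_u) * rng.random()
                node, path = tree.find_node(u, rng)
                if self.ll(node)[n] > slice_ll:
                    if node is not cur:
                        self._move_obs(n, node)
                    break
                if max_u - min_u < 1e-12 or path == cur_path:
                    break
                if path < cur_path:
                    min_u = u
                else:
                    max_u = u

    def refine_assignments(self) -> None:
        """Vectorized restricted Gibbs over the instantiated nodes.

        Given the sticks and clone parameters, the assignments are
        conditionally independent, so all N observations can be redrawn
        at once from Discrete(pi_eps * p(x_n | theta_eps)) restricted to
        the instantiated nodes (a detailed-balance-preserving restricted
        kernel; the slice pass supplies ergodicity over the rest of the
        infinite tree).  One fresh child per node is first instantiated
        from the prior so that clone births are proposed at every
        possible extension point with their exact conditional
        probability -- this is the sampler's main split mechanism.
        """
        tree = self.tree
        rng = self.rng
        for node in list(tree.iter_nodes()):
            node.sticks.append(float(rng.beta(1.0, self.config.gamma)))
            node.children.append(None)
            tree._make_child(node, len(node.sticks), rng)
        nodes = []
        logpi = []
        for node, pi in tree.node_weights().items():
            if pi > 0.0:
                nodes.append(node)
                logpi.append(math.log(pi))
        logits = (np.stack([self.ll(n) for n in nodes])
                  + np.array(logpi)[:, None])
        choice = np.argmax(logits + rng.gumbel(size=logits.shape), axis=0)
        for node in tree.iter_nodes():
            node.data = set()
        for n, k in enumerate(choice):
            nodes[k].data.add(n)
        self.assign = [nodes[k] for k in choice]
        tree.cull()

    # -- (b) clone parameters ----------------------------------------------

    def _theta_site_logp(self, node: Node, theta: np.ndarray,
                         s1: np.ndarray, s0: np.ndarray,
                         child_pre: list) -> np.ndarray:
        p = self.params
        s = sigmoid(theta)
        lp = s1 * np.log(s) + s0 * np.log1p(-s)
        c = -math.log(2.0 * p.Lambda)
        pos = c - np.abs(theta - p.mu) / p.Lambda
        neg = c - np.abs(theta + p.mu) / p.Lambda
        if node.parent is None:
            lp = lp + neg
        else:
            pmm, pum = _P_entries(p, node.t)
            at_m = node.parent.theta >= p.eta
            lw = np.where(at_m, _safe_log(pmm), _safe_log(pum))
            l1w = np.where(at_m, _safe_log(1.0 - pmm), _safe_log(1.0 - pum))
            lp = lp + np.logaddexp(lw + pos, l1w + neg)
        for lwm, l1wm, lwu, l1wu, pos_c, neg_c in child_pre:
            at_m = theta >= p.eta
            lw = np.where(at_m, lwm, lwu)
            l1w = np.where(at_m, l1wm, l1wu)
            lp = lp + np.logaddexp(lw + pos_c, l1w + neg_c)
        return lp

    def update_theta(self) -> None:
        rng = self.rng
        p = self.params
        c = -math.log(2.0 * p.Lambda)
        for node in self.tree.iter_nodes():
            if node.data:
                idx = np.fromiter(node.data, dtype=np.intp,
                                  count=len(node.data))
                s1 = self.X1[idx].sum(axis=0)
                s0 = self.X0[idx].sum(axis=0)
            else:
                s1 = s0 = np.zeros(self.M)
            child_pre = []
            for child in node.real_children():
                pmm, pum = _P_entries(p, child.t)
                child_pre.append((
                    _safe_log(pmm), _safe_log(1.0 - pmm),
                    _safe_log(pum), _safe_log(1.0 - pum),
                    c - np.abs(child.theta - p.mu) / p.Lambda,
                    c - np.abs(child.theta + p.mu) / p.Lambda))
            cur = node.theta
            prop = cur + self.config.theta_step * rng.standard_normal(self.M)
            delta = (self._theta_site_logp(node, prop, s1, s0, child_pre)
                     - self._theta_site_logp(node, cur, s1, s0, child_pre))
            accept = np.log(rng.random(self.M)) < delta
            if accept.any():
                node.theta = np.where(accept, prop, cur)
                node._ll = None

    # -- (c) branch lengths --------------------------------------------------

    def update_branch_lengths(self) -> None:
        rng = self.rng
        p = self.params
        for node in self.tree.iter_nodes():
            if node.parent is None:
                continue
            t_cur = node.t
            t_prop = t_cur * math.exp(self.config.t_step
                                      * rng.standard_normal())
            # Exponential(1) prior; log-scale walk needs the Jacobian
            delta = ((-t_prop + math.log(t_prop)
                      + float(_trans_site_terms(node.theta,
                                                node.parent.theta,
                                                t_prop, p).sum()))
                     - (-t_cur + math.log(t_cur)
                        + float(_trans_site_terms(node.theta,
                                                  node.parent.theta,
                                                  t_cur, p).sum())))
            if math.log(rng.random()) < delta:
                node.t = t_prop

    # -- (d) sticks ----------------------------------------------------------

    def resample_sticks(self) -> None:
        rng = self.rng
        cfg = self.config

        def descend(node: Node, d: int) -> int:
            counts = [0 if c is None else descend(c, d + 1)
                      for c in node.children]
            n_here = len(node.data)
            total = n_here + sum(counts)
            if d < self.tree.max_depth:
                node.nu = float(rng.beta(
                    1.0 + n_here,
                    cfg.alpha0 * cfg.lam ** -d + (total - n_here)))
            tail = 0
            for i in range(len(counts) - 1, -1, -1):
                node.sticks[i] = float(rng.beta(1.0 + counts[i],
                                                cfg.gamma + tail))
                tail += counts[i]
            return total

        descend(self.tree.root, 0)

    # -- (e) kernel hyperparameters ------------------------------------------

    def update_hypers(self) -> None:
        rng = self.rng
        cfg = self.config
        p = self.params
        cur_total = self._trans_total(p.mu, p.Lambda)

        def gamma_logpdf_delta(prop, cur, shape, scale):
            return ((shape - 1.0) * math.log(prop / cur)
                    - (prop - cur) / scale)

        # mu: random walk under a Gamma hyperprior whose mode sits at the
        # intended mode separation (mu -> 0 would erase the signal)
        mu_prop = p.mu + cfg.mu_step * rng.standard_normal()
        if mu_prop > 0:
            prop_total = self._trans_total(mu_prop, p.Lambda)
            delta = (prop_total - cur_total
                     + gamma_logpdf_delta(mu_prop, p.mu,
                                          cfg.mu_hyper_shape,
                                          cfg.mu_hyper_scale))
            if math.log(rng.random()) < delta:
                self.params = p = replace(p, mu=mu_prop)
                cur_total = prop_total
        # Lambda: log-scale walk under a Gamma hyperprior keeping the
        # within-mode spread well below the mode separation
        lam_prop = p.Lambda * math.exp(cfg.Lambda_step
                                       * rng.standard_normal())
        prop_total = self._trans_total(p.mu, lam_prop)
        delta = (prop_total - cur_total
                 + gamma_logpdf_delta(lam_prop, p.Lambda,
                                      cfg.Lambda_hyper_shape,
                                      cfg.Lambda_hyper_scale)
                 + math.log(lam_prop / p.Lambda))   # Jacobian
        if math.log(rng.random()) < delta:
            self.params = replace(p, Lambda=lam_prop)

    # -- swap-clone move -----------------------------------------------------

    @staticmethod
    def _swap_fields(a: Node, b: Node) -> None:
        a.theta, b.theta = b.theta, a.theta
        a._ll, b._ll = b._ll, a._ll
        a.data, b.data = b.data, a.data
        a.nu, b.nu = b.nu, a.nu

    def _reindex_after_swap(self, a: Node, b: Node) -> None:
        for node in (a, b):
            for n in node.data:
                self.assign[n] = node

    def swap_clone_move(self) -> bool:
        """One swap-clone Metropolis move; returns True if accepted."""
        nodes = list(self.tree.iter_nodes())
        if len(nodes) < 2:
            return False
        rng = self.rng
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        before = self.log_joint()
        self._swap_fields(a, b)
        after = self.log_joint()
        accept = math.log(rng.random()) < after - before
        if accept:
            self._reindex_after_swap(a, b)
            self.resample_sticks()
            self._ensure_root_occupied()
        else:
            self._swap_fields(a, b)
        return bool(accept)

    def reattach_move(self) -> bool:
        """Prune-and-regraft Metropolis move on the tree topology.

        A non-root subtree is detached (its stick position stays behind
        as an unoccupied ghost, so sibling weights are untouched) and
        regrafted as a fresh child of another node; the new breadth
        stick is drawn from its prior, whose density cancels against the
        proposal.  Candidate targets exclude the subtree itself and
        anything that would push the subtree past the depth truncation.
        The move relocates whole clades in one step, which neither the
        assignment kernels nor the swap move can do.
        """
        nodes = list(self.tree.iter_nodes())
        if len(nodes) < 3:
            return False
        rng = self.rng

        def subtree_height(node: Node) -> int:
            return 1 + max((subtree_height(c)
                            for c in node.real_children()), default=0)

        cand = [n for n in nodes if n.parent is not None]
        sub = cand[int(rng.integers(len(cand)))]
        in_subtree = set()
        stack = [sub]
        while stack:
            n = stack.pop()
            in_subtree.add(n)
            stack.extend(n.real_children())
        height = subtree_height(sub)
        targets = [n for n in nodes
                   if n not in in_subtree and n is not sub.parent
                   and n.depth + height < self.tree.max_depth]
        if not targets:
            return False
        target = targets[int(rng.integers(len(targets)))]
        before = self.log_joint()
        old_parent, old_pos = sub.parent, sub.pos
        old_parent.children[old_pos - 1] = None
        target.sticks.append(float(rng.beta(1.0, self.config.gamma)))
        target.children.append(None)
        target.children[-1] = sub
        sub.parent, sub.pos = target, len(target.sticks)
        after = self.log_joint()
        # reverse move: same subtree, old parent as target
        n_rev_targets = sum(1 for n in nodes
                            if n not in in_subtree and n is not target
                            and n.depth + height < self.tree.max_depth)
        hastings = math.log(len(targets)) - math.log(max(n_rev_targets, 1))
        if n_rev_targets > 0 and math.log(rng.random()) < (after - before
                                                           + hastings):
            self.resample_sticks()
            return True
        target.children.pop()
        target.sticks.pop()
        sub.parent, sub.pos = old_parent, old_pos
        old_parent.children[old_pos - 1] = sub
        return False

    def _ensure_root_occupied(self) -> None:
        """Empty-root states are invalid: swap the root with a random
        occupied node until the root holds at least one observation."""
        root = self.tree.root
        while not root.data:
            occupied = [n for n in self.tree.iter_nodes()
                        if n is not root and n.data]
            if not occupied:
                return
            other = occupied[int(self.rng.integers(len(occupied)))]
            self._swap_fields(root, other)
            self._reindex_after_swap(root, other)
            self.resample_sticks()

    # -- sweep and chain -----------------------------------------------------

    def gibbs_sweep(self) -> None:
        cfg = self.config
        if cfg.resample_assignments:
            for _ in range(cfg.assignment_passes):
                self.resample_assignments()
                self.tree.cull()  # drop slice-rejected transient nodes
            for _ in range(cfg.gibbs_passes):
                self.refine_assignments()
        if cfg.update_theta:
            for _ in range(cfg.theta_iters):
                self.update_theta()
        if cfg.update_t:
            self.update_branch_lengths()
        if cfg.update_sticks:
            self.resample_sticks()
        if cfg.update_hypers:
            self.update_hypers()
        self.tree.cull()

    def sweep(self) -> None:
        self.gibbs_sweep()
        if self.config.do_swap:
            for _ in range(self.config.swap_moves):
                self.swap_clone_move()
        for _ in range(self.config.reattach_moves):
            self.reattach_move()

    def record(self) -> Sample:
        snap = self.tree.snapshot()
        nodes = list(self.tree.iter_nodes())
        index = {node: k for k, node in enumerate(nodes)}
        codes = np.fromiter((index[node] for node in self.assign),
                            dtype=np.int32, count=self.N)
        n_big = sum(1 for ns in snap.values() if ns.pi > 0.01)
        return Sample(node_labels=[n.label for n in nodes], codes=codes,
                      snapshot=snap, cdll=self.complete_data_loglik(),
                      n_big=n_big)


def run_mcmc(data: MarkerMatrix, model_kind: Optional[str] = None,
             config: Optional[McmcConfig] = None) -> Trace:
    """Run one chain and return the thinned post-burn-in trace."""
    config = config or McmcConfig()
    sampler = TreeSampler(data, config, model_kind)
    for _ in range(config.burnin):
        sampler.sweep()
    samples = []
    for j in range(1, config.n_keep + 1):
        sampler.sweep()
        if j % config.thin == 0:
            samples.append(sampler.record())
    return Trace(samples=samples, n_obs=sampler.N, kind=sampler.kind,
                 config=config)


def posterior_similarity(trace: Trace) -> np.ndarray:
    """N x N matrix of posterior co-clustering probabilities."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    psm = np.zeros((trace.n_obs, trace.n_obs))
    for s in trace:
        psm += s.codes[:, None] == s.codes[None, :]
    return psm / len(trace)


def pear_index(labels: np.ndarray, psm: np.ndarray) -> float:
    """Posterior expected adjusted Rand index of a candidate partition
    against a posterior similarity matrix (Fritsch-Ickstadt form)."""
    labels = np.asarray(labels)
    n = len(labels)
    iu = np.triu_indices(n, 1)
    ind = (labels[:, None] == labels[None, :])[iu].astype(float)
    sim = psm[iu]
    n_pairs = ind.size
    si, sp = ind.sum(), sim.sum()
    expected = si * sp / n_pairs
    denom = 0.5 * (si + sp) - expected
    if denom == 0.0:
        return 0.0
    return float((ind @ sim - expected) / denom)


def mpear_summary(psm: np.ndarray, max_k: int = 20) -> np.ndarray:
    """Summary partition maximizing PEAR over hierarchical cuts.

    Candidate partitions are the cuts of average- and complete-linkage
    hierarchical clusterings of ``1 - psm`` at every cluster number from
    1 to ``min(N, max_k)``; ties prefer fewer clusters (exact
    maximization over all partitions is infeasible).
    """
    psm = np.asarray(psm, dtype=float)
    n = psm.shape[0]
    d = 1.0 - (psm + psm.T) / 2.0
    np.fill_diagonal(d, 0.0)
    best_labels = np.ones(n, dtype=int)
    best = pear_index(best_labels, psm)
    if n >= 2:
        condensed = squareform(d, checks=False)
        for method in ("average", "complete"):
            Z = linkage(condensed, method=method)
            for k in range(2, min(n, max_k) + 1):
                labels = fcluster(Z, k, criterion="maxclust")
                score = pear_index(labels, psm)
                if score > best:
                    best, best_labels = score, labels
    return np.asarray(best_labels)


def select_map_tree(trace: Trace) -> Sample:
    """Empirical MAP tree via big-node-number grouping.

    Samples are grouped by their big-node count (nodes with pi > 0.01);
    within the most frequent group (ties broken toward fewer big nodes)
    the sample with the highest complete-data log-likelihood is
    returned.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    counts = Counter(s.n_big for s in trace)
    target = max(counts, key=lambda c: (counts[c], -c))
    group = [s for s in trace if s.n_big == target]
    return max(group, key=lambda s: s.cdll)
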