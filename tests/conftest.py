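"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from clonetree.mcmc import McmcConfig, TreeSampler, run_mcmc
from clonetree.simulate import add_flip_noise, make_fixture, sample_observations
from clonetree.tssb import Node, TssbTree


def build_tree(spec: dict, lam=2.0, alpha0=0.3, gamma=0.1,
               max_depth=15) -> TssbTree:
    """Construct a tree with given sticks.

    ``spec`` maps labels to ``(nu, psi_list)``; labels must be
    prefix-closed.  Missing child positions stay un-instantiated ghosts.
    """
    root_nu, root_psi = spec[()]
    tree = TssbTree(lam, alpha0, gamma, max_depth=max_depth,
                    root_nu=root_nu)
    nodes = {(): tree.root}
    tree.root.sticks = list(root_psi)
    tree.root.children = [None] * len(root_psi)
    for label in sorted(spec, key=lambda l: (len(l), l)):
        if label == ():
            continue
        nu, psi = spec[label]
        par = nodes[label[:-1]]
        node = Node(parent=par, pos=label[-1], nu=nu)
        node.sticks = list(psi)
        node.children = [None] * len(psi)
        par.children[label[-1] - 1] = node
        nodes[label] = node
    return tree


def scaled_chain(mode: str, n: int, error: float, data_seed: int,
                 chain_seed: int, burnin=2000, n_keep=3000, thin=5):
    """Simulate one data set and run one reduced-schedule chain."""
    rng = np.random.default_rng(data_seed)
    fixture = make_fixture(mode)
    X, labels = sample_observations(fixture, n, rng)
    X = add_flip_noise(X, error, rng)
    config = McmcConfig(burnin=burnin, n_keep=n_keep, thin=thin,
                        seed=chain_seed)
    trace = run_mcmc(X, "methylation", config)
    return fixture, X, labels, trace


# chains shared between the acceptance criteria (several criteria probe
# the same simulated condition)
cached_chain = lru_cache(maxsize=None)(scaled_chain)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
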