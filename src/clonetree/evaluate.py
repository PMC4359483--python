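"""Clustering and tree-topology comparison metrics.

* v-measure: entropy-based clustering agreement (harmonic mean of
  homogeneity and completeness), in [0, 1].
* consensus node-based shortest path distance: for the marker patterns
  carried by nodes of the ground-truth tree and of *every* inferred
  tree, compare the lower-triangular pairwise shortest-path (hop)
  distance matrices by the sum of absolute entry differences.
* tree summaries: maximum depth, clone counts, big clones (mixture
  weight above 1%), total branch length, per-level mass distribution,
  and the symmetrized Kullback-Leibler divergence between level-mass
  distributions as a measure of topological diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.metrics import v_measure_score

from .baselines import BaselineResult
from .models import genotype_call
from .simulate import TrueTree

__all__ = ["PatternTree", "TreeSummary", "v_measure",
           "pattern_tree_from_fixture", "pattern_tree_from_snapshot",
           "pattern_tree_from_baseline", "consensus_sp_distance",
           "tree_summary", "trace_level_mass", "symmetrized_kl"]


def _encode(labels) -> np.ndarray:
    index = {}
    return np.array([index.setdefault(l, len(index)) for l in labels])


def v_measure(true_labels, pred_labels) -> float:
    """Harmonic mean of homogeneity and completeness, in [0, 1]."""
    if len(true_labels) != len(pred_labels):
        raise ValueError("label vectors differ in length")
    return float(v_measure_score(_encode(true_labels),
                                 _encode(pred_labels)))


@dataclass(frozen=True)
class PatternTree:
    """A clone tree whose nodes carry marker patterns.

    ``patterns`` maps the pattern-carrying (non-empty) nodes to their
    binary marker tuple; ``masses`` is used to break ties when the same
    pattern occurs at several nodes (the heaviest node represents it).
    """

    graph: nx.Graph
    patterns: dict
    masses: dict


def pattern_tree_from_fixture(fixture: TrueTree) -> PatternTree:
    g = nx.Graph()
    patterns, masses = {}, {}
    for clone in fixture.clones:
        g.add_node(clone.label)
        if clone.label != ():
            g.add_edge(clone.label[:-1], clone.label)
        patterns[clone.label] = clone.genotype
        masses[clone.label] = clone.frequency
    return PatternTree(g, patterns, masses)


def pattern_tree_from_snapshot(snap: dict, eta: float = 1.0) -> PatternTree:
    """Pattern tree of an inferred tree snapshot.

    All instantiated nodes shape the graph (and hence the hop
    distances); only non-empty clones carry patterns, obtained by
    thresholding the clone parameters at ``eta``.
    """
    g = nx.Graph()
    patterns, masses = {}, {}
    for label, ns in snap.items():
        g.add_node(label)
        if label != ():
            g.add_edge(label[:-1], label,
                       length=1.0 if ns.t is None else float(ns.t))
        if ns.n_assigned > 0 and ns.theta is not None:
            patterns[label] = tuple(int(v)
                                    for v in genotype_call(ns.theta, eta))
            masses[label] = ns.pi
    return PatternTree(g, patterns, masses)


def pattern_tree_from_baseline(result: BaselineResult) -> PatternTree:
    g = nx.Graph()
    g.add_nodes_from(range(result.tree.n_nodes))
    g.add_edges_from(result.tree.edges)
    sizes = np.bincount(result.labels, minlength=result.tree.n_nodes + 1)
    patterns = {i: tuple(int(v) for v in row)
                for i, row in enumerate(result.methyltypes)}
    masses = {i: sizes[i + 1] / result.labels.size
              for i in range(result.tree.n_nodes)}
    return PatternTree(g, patterns, masses)


def _pattern_nodes(tree: PatternTree, shared: set) -> dict:
    """Representative node per shared pattern (highest mass, then the
    smallest node id for determinism)."""
    best = {}
    for node in sorted(tree.patterns, key=str):
        pat = tree.patterns[node]
        if pat in shared:
            if pat not in best or tree.masses[node] > tree.masses[best[pat]]:
                best[pat] = node
    return best


def _hop_matrix(tree: PatternTree, reps: dict, order: list,
                use_branch_lengths: bool = False) -> np.ndarray:
    n = len(order)
    D = np.zeros((n, n))
    weight = "length" if use_branch_lengths else None
    for a in range(n):
        lengths = nx.single_source_dijkstra_path_length(
            tree.graph, reps[order[a]], weight=weight) \
            if use_branch_lengths else \
            nx.single_source_shortest_path_length(tree.graph,
                                                  reps[order[a]])
        for b in range(n):
            D[a, b] = lengths[reps[order[b]]]
    return D


def consensus_sp_distance(true_tree: PatternTree, inferred_trees: list,
                          use_branch_lengths: bool = False) -> list:
    """Consensus node-based shortest path distance per inferred tree.

    The shared set is the intersection of the node patterns of the
    ground truth and of every inferred tree; each tree contributes the
    lower-triangular part of its path-distance matrix over the shared
    patterns, compared to the truth by the sum of absolute differences.
    Paths are counted in hops by default; ``use_branch_lengths`` weighs
    edges by their ``length`` attribute instead (edges without one count
    as 1).
    """
    shared = set(true_tree.patterns.values())
    for t in inferred_trees:
        shared &= set(t.patterns.values())
    if not shared:
        raise ValueError("no marker pattern shared by all trees")
    order = sorted(shared)
    il = np.tril_indices(len(order), -1)
    D_true = _hop_matrix(true_tree, _pattern_nodes(true_tree, shared),
                         order, use_branch_lengths)[il]
    out = []
    for t in inferred_trees:
        D = _hop_matrix(t, _pattern_nodes(t, shared), order,
                        use_branch_lengths)[il]
        out.append(float(np.abs(D - D_true).sum()))
    return out


@dataclass(frozen=True)
class TreeSummary:
    max_depth: int
    n_clones: int
    n_big_clones: int
    total_branch_length: float
    level_mass: np.ndarray


def tree_summary(snap: dict) -> TreeSummary:
    """Topological summary statistics of a tree snapshot.

    Depth and clone counts refer to non-empty clones; big clones are the
    nodes carrying more than 1% of the mass; level masses sum the
    mixture weights per tree depth over all instantiated nodes.
    """
    occupied = [l for l, ns in snap.items() if ns.n_assigned > 0]
    max_depth = max((len(l) for l in occupied), default=0)
    depth_all = max(len(l) for l in snap)
    level_mass = np.zeros(depth_all + 1)
    for label, ns in snap.items():
        level_mass[len(label)] += ns.pi
    total_t = sum(ns.t for l, ns in snap.items() if l != () and ns.t)
    return TreeSummary(
        max_depth=max_depth,
        n_clones=len(occupied),
        n_big_clones=sum(1 for ns in snap.values() if ns.pi > 0.01),
        total_branch_length=float(total_t),
        level_mass=level_mass)


def trace_level_mass(trace) -> np.ndarray:
    """Posterior mean level-mass distribution across a trace."""
    per_sample = [tree_summary(s.snapshot).level_mass for s in trace]
    depth = max(len(v) for v in per_sample)
    out = np.zeros(depth)
    for v in per_sample:
        out[:len(v)] += v
    return out / len(per_sample)


def symmetrized_kl(p, q, eps: float = 1e-10) -> float:
    """Symmetrized KL divergence between two level-mass distributions.

    The inputs are padded to a common length, smoothed by ``eps`` and
    renormalized before computing KL(p||q) + KL(q||p) in nats.
    """
    p, q = np.asarray(p, dtype=float), np.asarray(q, dtype=float)
    n = max(len(p), len(q))
    p = np.pad(p, (0, n - len(p))) + eps
    q = np.pad(q, (0, n - len(q))) + eps
    p, q = p / p.sum(), q / q.sum()
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))
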