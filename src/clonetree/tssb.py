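"""Tree-structured stick-breaking (TSSB) prior over clone trees.

The TSSB defines a distribution over infinitely many mixture weights
arranged in a tree of unbounded depth and width.  Every node ``eps`` (a
tuple of 1-based child positions, root = ``()``) carries a depth stick
``nu ~ Beta(1, alpha0 * lam**(-depth))`` deciding how much of the mass
arriving at the node stays there, and each child carries a breadth stick
``psi ~ Beta(1, gamma)`` splitting the remainder among siblings.  The
weight of a node is

    pi_eps = nu_eps * phi_eps * prod_{eps' ancestor} phi_eps' (1 - nu_eps'),

with ``phi`` the usual stick-breaking product over elder siblings and
``pi_root = nu_root``.

``lam`` is the depth *decay* rate: with ``lam > 1`` the stick parameter
shrinks geometrically with depth, deep sticks concentrate near 1, and
descents terminate almost surely, keeping trees shallow (the regime the
clone-tree model works in, default ``lam = 2``).  Values below 1 invert
the decay and push mass toward infinite depth; since a fraction of mass
would then never be absorbed, descents are truncated at ``max_depth``
(depth sticks at the cap are pinned to 1), which also bounds the work
per descent in the proper regime.

Only a finite part of the infinite tree is ever instantiated; nodes are
created lazily when a stick-breaking descent lands on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

CloneLabel = tuple  # tuple of positive ints; () addresses the root

_BELOW_ONE = math.nextafter(1.0, 0.0)

__all__ = [
    "CloneLabel",
    "Node",
    "NodeSnap",
    "TssbTree",
    "depth",
    "parent",
    "branch_weight",
    "clone_weights",
    "sample_prior_tree",
    "cull_empty",
    "snapshot_to_newick",
]


def depth(label: CloneLabel) -> int:
    """Depth of a clone label; the root ``()`` has depth 0."""
    return len(label)


def parent(label: CloneLabel) -> CloneLabel:
    """Parent label (the label with the last element removed).

    Raises ``ValueError`` for the root, which has no parent.
    """
    if len(label) == 0:
        raise ValueError("the root clone has no parent")
    return tuple(label[:-1])


def branch_weight(psi: float, elder_psis: Sequence[float]) -> float:
    """Stick-breaking branch probability ``phi = psi * prod(1 - psi_elder)``.

    ``elder_psis`` are the breadth sticks of the elder siblings (children
    1..i-1 of the same parent, in order).
    """
    for p in (psi, *elder_psis):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"stick value {p} outside [0, 1]")
    out = psi
    for p in elder_psis:
        out *= 1.0 - p
    return out


class Node:
    """One instantiated node of the finite portion of the tree.

    ``sticks[i]`` is the psi stick of child position i+1; ``children[i]``
    is the corresponding child ``Node`` or ``None`` if that position is
    currently not instantiated (a culled or never-created child whose
    stick is kept so that sibling weights stay put).
    """

    __slots__ = ("parent", "pos", "nu", "sticks", "children",
                 "theta", "t", "data", "_ll")

    def __init__(self, parent=None, pos=0, nu=0.5, theta=None, t=None):
        self.parent = parent
        self.pos = pos          # 1-based position within parent, 0 for root
        self.nu = float(nu)
        self.sticks: list[float] = []
        self.children: list[Optional[Node]] = []
        self.theta = theta      # length-M parameter vector (may be None)
        self.t = t              # branch length; None for the root
        self.data: set[int] = set()
        self._ll = None         # cached per-observation log-likelihood

    @property
    def label(self) -> CloneLabel:
        parts = []
        node = self
        while node.parent is not None:
            parts.append(node.pos)
            node = node.parent
        return tuple(reversed(parts))

    @property
    def depth(self) -> int:
        d = 0
        node = self
        while node.parent is not None:
            d += 1
            node = node.parent
        return d

    def real_children(self) -> Iterator["Node"]:
        return (c for c in self.children if c is not None)


@dataclass
class NodeSnap:
    """Frozen per-node state used for serialization and trace snapshots."""

    label: CloneLabel
    nu: float
    psi: list
    theta: Optional[np.ndarray]
    t: Optional[float]
    n_assigned: int
    pi: float


class TssbTree:
    """The finite, instantiated portion of a TSSB tree.

    Parameters
    ----------
    lam, alpha0, gamma
        TSSB hyperparameters: depth decay of the nu sticks, base
        concentration, and breadth-stick concentration.
    max_depth
        Truncation depth; nu sticks at this depth are pinned to 1.
    param_prior
        Optional callback ``(parent_node, rng) -> (theta, t)`` used to
        draw clone parameters and a branch length whenever a new node is
        instantiated. ``None`` leaves both unset.
    """

    def __init__(self, lam: float, alpha0: float, gamma: float,
                 max_depth: int = 15,
                 param_prior: Optional[Callable] = None,
                 root_nu: float = 0.5):
        if lam <= 0 or alpha0 <= 0 or gamma <= 0:
            raise ValueError("TSSB hyperparameters must be positive")
        if max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        self.lam = float(lam)
        self.alpha0 = float(alpha0)
        self.gamma = float(gamma)
        self.max_depth = int(max_depth)
        self.param_prior = param_prior
        self.root = Node(nu=1.0 if max_depth == 0 else root_nu)

    # -- traversal ---------------------------------------------------------

    def iter_nodes(self) -> Iterator[Node]:
        """Pre-order traversal of the instantiated nodes."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(list(node.real_children())))

    def nodes(self) -> dict:
        """Map ``label -> Node`` over the instantiated nodes."""
        return {node.label: node for node in self.iter_nodes()}

    def n_nodes(self) -> int:
        return sum(1 for _ in self.iter_nodes())

    # -- weights -----------------------------------------------------------

    def node_weights(self) -> dict:
        """Map ``Node -> pi`` over instantiated nodes (sum <= 1)."""
        out = {}

        def descend(node: Node, mass_in: float):
            out[node] = mass_in * node.nu
            rem = mass_in * (1.0 - node.nu)
            prod = 1.0
            for psi, child in zip(node.sticks, node.children):
                if child is not None:
                    descend(child, rem * prod * psi)
                prod *= 1.0 - psi

        descend(self.root, 1.0)
        return out

    # -- lazy descent ------------------------------------------------------

    def _make_child(self, parent_node: Node, pos: int, rng) -> Node:
        d = parent_node.depth + 1
        if d >= self.max_depth:
            nu = 1.0
        else:
            nu = float(rng.beta(1.0, self.alpha0 * self.lam ** -d))
        theta = t = None
        if self.param_prior is not None:
            theta, t = self.param_prior(parent_node, rng)
        node = Node(parent=parent_node, pos=pos, nu=nu, theta=theta, t=t)
        parent_node.children[pos - 1] = node
        return node

    def find_node(self, u: float, rng) -> tuple:
        """Locate the node owning position ``u`` of the unit interval.

        Descends the stick-breaking layout (node's nu interval first,
        then the children's phi intervals in order), instantiating sticks
        and nodes on demand.  Returns ``(node, path)`` where ``path`` is
        the label of the node; the pre-order of paths matches increasing
        ``u``, which is what the slice sampler's interval shrinkage
        relies on.
        """
        node = self.root
        path: list[int] = []
        d = 0
        max_depth = self.max_depth
        while True:
            if d >= max_depth or u < node.nu:
                return node, tuple(path)
            u = (u - node.nu) / (1.0 - node.nu)
            if u < 0.0:
                u = 0.0
            elif u > _BELOW_ONE:
                u = _BELOW_ONE
            sticks = node.sticks
            children = node.children
            lower, rem, i = 0.0, 1.0, 0
            while True:
                if i == len(sticks):
                    sticks.append(float(rng.beta(1.0, self.gamma)))
                    children.append(None)
                psi = sticks[i]
                seg = rem * psi
                if u < lower + seg or rem <= 1e-200:
                    break
                lower += seg
                rem *= 1.0 - psi
                i += 1
            u = 0.0 if seg <= 0.0 else min((u - lower) / seg, _BELOW_ONE)
            child = node.children[i]
            if child is None:
                child = self._make_child(node, i + 1, rng)
            node = child
            path.append(i + 1)
            d += 1

    # -- maintenance -------------------------------------------------------

    def cull(self) -> None:
        """Drop empty leaf-side nodes (no data anywhere in their subtree).

        The psi sticks of dropped middle children are kept in place so
        the weights of the surviving siblings are unchanged; trailing
        unused sticks are trimmed.
        """

        def descend(node: Node) -> int:
            n = len(node.data)
            for i, child in enumerate(node.children):
                if child is None:
                    continue
                sub = descend(child)
                if sub == 0:
                    node.children[i] = None
                n += sub
            while node.children and node.children[-1] is None:
                node.children.pop()
                node.sticks.pop()
            return n

        descend(self.root)

    # -- snapshots ---------------------------------------------------------

    def snapshot(self) -> dict:
        """Frozen ``label -> NodeSnap`` view of the current tree."""
        weights = self.node_weights()
        out = {}
        for node in self.iter_nodes():
            theta = None if node.theta is None else np.array(node.theta, copy=True)
            out[node.label] = NodeSnap(
                label=node.label, nu=node.nu, psi=list(node.sticks),
                theta=theta, t=node.t, n_assigned=len(node.data),
                pi=weights[node])
        return out

    @classmethod
    def from_snapshot(cls, snap: dict, lam: float, alpha0: float,
                      gamma: float, max_depth: int = 15) -> "TssbTree":
        """Rebuild an instantiated tree from a snapshot mapping."""
        root_snap = snap[()]
        tree = cls(lam, alpha0, gamma, max_depth=max_depth,
                   root_nu=root_snap.nu)
        by_label = {(): tree.root}
        for label in sorted(snap, key=lambda l: (len(l), l)):
            ns = snap[label]
            if label == ():
                node = tree.root
            else:
                par = by_label[label[:-1]]
                node = Node(parent=par, pos=label[-1], nu=ns.nu,
                            theta=None if ns.theta is None
                            else np.array(ns.theta, copy=True),
                            t=ns.t)
                par.children[label[-1] - 1] = node
                by_label[label] = node
            node.sticks = list(ns.psi)
            node.children = [None] * len(ns.psi)
            node.data = set(range(ns.n_assigned))  # counts only
        return tree


# -- module-level operations matching the mathematical surface -------------

def clone_weights(tree: TssbTree) -> dict:
    """Map ``label -> pi`` over the instantiated nodes of ``tree``."""
    return {node.label: w for node, w in tree.node_weights().items()}


def sample_prior_tree(hypers: tuple, n_obs: int, rng,
                      max_depth: int = 15) -> tuple:
    """Draw a finite tree and ``n_obs`` assignments from the TSSB prior.

    Nodes are instantiated lazily while the assignments' uniform variates
    descend the stick layout, so the returned tree is exactly the part of
    the infinite tree touched by the sample.  Returns
    ``(tree, labels)`` with one clone label per observation.
    """
    lam, alpha0, gamma = hypers
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    tree = TssbTree(lam, alpha0, gamma, max_depth=max_depth)
    tree.root.nu = 1.0 if max_depth == 0 else float(rng.beta(1.0, alpha0))
    labels = []
    for n in range(n_obs):
        node, path = tree.find_node(float(rng.random()), rng)
        node.data.add(n)
        labels.append(path)
    return tree, labels


def cull_empty(tree: TssbTree) -> TssbTree:
    """Remove empty leaf-side nodes in place; idempotent; returns the tree."""
    tree.cull()
    return tree


def snapshot_to_newick(snap: dict, precision: int = 6) -> str:
    """Newick string for a snapshot; internal labels are ``'path:count'``.

    Node names are single-quoted because they contain a colon; branch
    lengths are the per-node ``t``.  The root carries no label.  Clone
    parameters cannot be represented in Newick; the structured dump is
    the canonical serialization.
    """

    children = {}
    for label in snap:
        if label != ():
            children.setdefault(label[:-1], []).append(label)

    def fmt(label) -> str:
        ns = snap[label]
        kids = sorted(children.get(label, ()))
        inner = ""
        if kids:
            inner = "(" + ",".join(fmt(k) for k in kids) + ")"
        if label == ():
            return inner if inner else ""
        name = ".".join(str(i) for i in label)
        bl = 0.0 if ns.t is None else ns.t
        return f"{inner}'{name}:{ns.n_assigned}':{bl:.{precision}f}"

    body = fmt(())
    return (body if body else "") + ";"
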