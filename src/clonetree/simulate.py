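"""Synthetic benchmark: five canonical clone trees and noisy samples.

The fixtures cover the classic modes of tumor evolution:

* ``monoclonal`` -- a healthy root plus one tumor clone.
* ``polyclonal_low`` -- a three-layer tree of 6 clones with a dominant
  mid-layer clone and minor siblings.
* ``polyclonal_medium`` -- the low tree plus a fourth layer of five
  small clones with frequencies (0.03, 0.03, 0.03, 0.02, 0.02); the
  pre-existing clones are scaled down so the total stays 1.
* ``polyclonal_high`` -- extended to 18 clones, the additions at
  frequency about 0.02 (all frequencies renormalized).
* ``mutator`` -- a star: the root plus twelve low-frequency leaves.

Each clone carries an 8-site binary genotype obtained from its parent's
genotype by a fixed set of site flips, so the fixtures are pure
functions of ``(mode, n_sites)``.  Several fourth-layer clones differ
from their (much larger) parent at exactly one site; this deliberately
reproduces the hard regime of near-identical, highly asymmetric clones
in which mixture-based clustering plateaus just below perfect accuracy.

Observations are drawn i.i.d. from the clone frequencies; measurement
error flips every site independently with a fixed probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import MarkerMatrix

__all__ = ["Clone", "TrueTree", "MODES", "make_fixture",
           "sample_observations", "add_flip_noise"]

MODES = ("monoclonal", "polyclonal_low", "polyclonal_medium",
         "polyclonal_high", "mutator")


@dataclass(frozen=True)
class Clone:
    label: tuple           # clone label; () is the root
    frequency: float
    genotype: tuple        # length-M 0/1 tuple


@dataclass(frozen=True)
class TrueTree:
    """Ground-truth simulation fixture."""

    mode: str
    clones: tuple          # tuple of Clone, pre-order

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([c.frequency for c in self.clones])

    @property
    def genotypes(self) -> np.ndarray:
        return np.array([c.genotype for c in self.clones], dtype=np.int8)

    def clone(self, label) -> Clone:
        for c in self.clones:
            if c.label == tuple(label):
                return c
        raise KeyError(label)


# label -> (frequency, sites flipped relative to the parent)
_LOW = {
    (): (0.05, ()),
    (1,): (0.55, (0, 1, 2)),
    (2,): (0.10, (4, 5)),
    (1, 1): (0.15, (3,)),
    (1, 2): (0.10, (4,)),
    (2, 1): (0.05, (6,)),
}

_MEDIUM_ADDED = {
    (1, 1, 1): (0.03, (5,)),
    (1, 1, 2): (0.03, (6,)),
    (1, 2, 1): (0.03, (7,)),
    (2, 1, 1): (0.02, (0,)),
    (2, 1, 2): (0.02, (3,)),
}

_HIGH_ADDED = {
    (1, 1, 1, 1): (0.02, (7,)),
    (1, 1, 2, 1): (0.02, (1,)),
    (1, 2, 1, 1): (0.02, (5,)),
    (2, 1, 1, 1): (0.02, (1,)),
    (3,): (0.02, (6, 7)),
    (3, 1): (0.02, (5,)),
    (3, 2): (0.02, (2,)),
}

_MUTATOR_FLIPS = [(0, 3), (1, 4), (2, 5), (3, 6), (4, 7), (0, 5),
                  (1, 6), (2, 7), (0, 4), (1, 5), (2, 6), (3, 7)]


def _build(table: dict, n_sites: int, mode: str) -> TrueTree:
    genotypes = {}
    clones = []
    for label in sorted(table, key=lambda l: (len(l), l)):
        freq, flips = table[label]
        base = (np.zeros(n_sites, dtype=np.int8) if label == ()
                else genotypes[label[:-1]].copy())
        for site in flips:
            if site >= n_sites:
                raise ValueError(f"fixture needs at least {site + 1} sites")
            base[site] ^= 1
        genotypes[label] = base
        clones.append(Clone(label, freq, tuple(int(v) for v in base)))
    seen = [c.genotype for c in clones]
    if len(set(seen)) != len(seen):
        raise AssertionError("fixture genotypes are not unique")
    total = sum(c.frequency for c in clones)
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"fixture frequencies sum to {total}")
    return TrueTree(mode=mode, clones=tuple(clones))


def make_fixture(mode: str, n_sites: int = 8) -> TrueTree:
    """The canonical ground-truth tree for one mode of evolution.

    A pure function of ``(mode, n_sites)``: clone frequencies and the
    per-edge genotype flips are fixed tables.
    """
    if mode == "monoclonal":
        table = {(): (0.2, ()), (1,): (0.8, (0, 1, 2, 3))}
    elif mode == "polyclonal_low":
        table = dict(_LOW)
    elif mode == "polyclonal_medium":
        scale = 1.0 - sum(f for f, _ in _MEDIUM_ADDED.values())
        table = {lab: (f * scale, flips) for lab, (f, flips) in _LOW.items()}
        table.update(_MEDIUM_ADDED)
    elif mode == "polyclonal_high":
        low_scale = 1.0 - sum(f for f, _ in _MEDIUM_ADDED.values())
        table = {lab: (f * low_scale, flips)
                 for lab, (f, flips) in _LOW.items()}
        table.update(_MEDIUM_ADDED)
        table.update(_HIGH_ADDED)
        total = sum(f for f, _ in table.values())
        table = {lab: (f / total, flips) for lab, (f, flips) in table.items()}
    elif mode == "mutator":
        table = {(): (0.04, ())}
        share = (1.0 - 0.04) / len(_MUTATOR_FLIPS)
        for i, flips in enumerate(_MUTATOR_FLIPS, start=1):
            table[(i,)] = (share, flips)
    else:
        raise ValueError(f"unknown fixture mode {mode!r}")
    return _build(table, n_sites, mode)


def sample_observations(fixture: TrueTree, n: int, rng) -> tuple:
    """Draw ``n`` observations i.i.d. from the clone frequencies.

    Each observation's row is its clone's genotype (no noise); returns
    ``(MarkerMatrix, labels)`` with one clone label per row.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    freqs = fixture.frequencies
    memberships = rng.choice(len(fixture.clones), size=n, p=freqs)
    X = fixture.genotypes[memberships]
    labels = [fixture.clones[k].label for k in memberships]
    mask = np.zeros_like(X, dtype=bool)
    return MarkerMatrix(X, mask, kind="methylation"), labels


def add_flip_noise(X: MarkerMatrix, p: float, rng) -> MarkerMatrix:
    """Flip every non-missing entry independently with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("flip probability must lie in [0, 1]")
    flips = (rng.random(X.values.shape) < p) & ~X.missing_mask
    values = X.values ^ flips.astype(np.int8)
    return MarkerMatrix(values, X.missing_mask.copy(), kind=X.kind)
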