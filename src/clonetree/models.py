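"""Per-clone observation likelihoods and parent-to-child transition kernels.

Two model variants share the same sigmoid-Bernoulli observation layer:

* ``methylation`` -- binary CpG methylation patterns.  State changes are
  reversible; the two-state continuous-time Markov chain has equilibrium
  frequencies ``(beta_u, beta_m)`` and is scaled so the mean event rate
  is one (``2 * beta_u * beta_m * rho = 1``).
* ``snv`` -- single-cell genotypes (0 wild type, 1 heterozygous
  mutation).  Back mutation is forbidden: the rate out of the mutated
  state is zero, so ``P(m -> u) = 0`` for every branch length.  The
  scaling satisfies ``beta_m * (1 - beta_m) * rho = 1``.

Clone parameters ``theta`` live on the real line; ``sigmoid(theta_i)``
is the per-site probability of observing a 1.  Parent-to-child evolution
of ``theta`` is a two-component Laplace mixture whose component weights
come from the CTMC transition matrix ``P(t) = expm(A t)``: sites whose
parent parameter clears the calling threshold ``eta`` use the
``m -> m`` entry, the rest the ``u -> m`` entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

_SIG_EPS = 1e-15

__all__ = [
    "MarkerMatrix",
    "EvolutionParams",
    "sigmoid",
    "local_loglik",
    "rate_matrix",
    "transition_matrix",
    "mixture_weight",
    "laplace_logpdf",
    "transition_logpdf",
    "root_log_prior",
    "call_state",
    "genotype_call",
]


@dataclass
class MarkerMatrix:
    """N x M binary observations with an explicit missing-value mask."""

    values: np.ndarray          # int8, 0/1 (arbitrary where masked)
    missing_mask: np.ndarray    # bool, True = missing
    kind: str = "methylation"   # "methylation" or "snv"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if self.kind not in ("methylation", "snv"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        ok = np.isin(self.values[~self.missing_mask], (0, 1))
        if not ok.all():
            raise ValueError("non-binary entry in marker matrix")

    @classmethod
    def from_array(cls, arr, kind: str = "methylation") -> "MarkerMatrix":
        """Build from a float array where NaN marks missing entries."""
        arr = np.asarray(arr, dtype=float)
        mask = np.isnan(arr)
        vals = np.where(mask, 0, arr)
        return cls(vals.astype(np.int8), mask, kind)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]


@dataclass
class EvolutionParams:
    """Hyperparameters of the transition kernel and observation layer.

    ``mu`` is the Laplace mode location (clone parameters are pushed
    toward +mu for present and -mu for absent markers), ``Lambda`` the
    Laplace scale, ``eta`` the state-calling threshold (default 1, a
    conservative call), and ``beta_m`` the equilibrium frequency of the
    methylated/mutated state.  ``rho`` is derived from the scaling
    convention of the respective model kind.
    """

    kind: str
    beta_m: float
    mu: float = 4.0
    Lambda: float = 1.0
    eta: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.beta_m < 1.0:
            raise ValueError("beta_m must lie strictly in (0, 1)")
        if self.Lambda <= 0:
            raise ValueError("Lambda must be positive")
        if self.kind not in ("methylation", "snv"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def beta_u(self) -> float:
        return 1.0 - self.beta_m

    @property
    def rho(self) -> float:
        if self.kind == "methylation":
            return 1.0 / (2.0 * self.beta_u * self.beta_m)
        return 1.0 / (self.beta_m * (1.0 - self.beta_m))

    def rate(self) -> np.ndarray:
        return rate_matrix(self.kind, self.beta_m)

    def transition(self, t: float) -> np.ndarray:
        return transition_matrix(self.rate(), t)


def sigmoid(theta):
    """Logistic function clamped away from {0, 1} for stable logs."""
    s = expit(np.asarray(theta, dtype=float))
    return np.clip(s, _SIG_EPS, 1.0 - _SIG_EPS)


def local_loglik(x_row, theta, missing_mask=None) -> float:
    """Bernoulli log-likelihood of one observation row under a clone.

    Missing sites contribute nothing (missing-completely-at-random
    entries are simply ignored).
    """
    x = np.asarray(x_row, dtype=float)
    s = sigmoid(theta)
    terms = x * np.log(s) + (1.0 - x) * np.log(1.0 - s)
    if missing_mask is not None:
        terms = np.where(np.asarray(missing_mask, dtype=bool), 0.0, terms)
    return float(terms.sum())


def rate_matrix(kind: str, beta_m: float) -> np.ndarray:
    """2x2 CTMC generator over states (u, m), scaled per model kind."""
    if not 0.0 < beta_m < 1.0:
        raise ValueError("degenerate equilibrium: beta_m must be in (0, 1)")
    beta_u = 1.0 - beta_m
    if kind == "methylation":
        rho = 1.0 / (2.0 * beta_u * beta_m)
        return np.array([[-beta_m, beta_m], [beta_u, -beta_u]]) * rho
    if kind == "snv":
        rho = 1.0 / (beta_m * (1.0 - beta_m))
        return np.array([[-beta_m, beta_m], [0.0, 0.0]]) * rho
    raise ValueError(f"unknown model kind {kind!r}")


def transition_matrix(A: np.ndarray, t: float) -> np.ndarray:
    """Transition matrix ``P(t) = expm(A t)`` of a two-state chain.

    Uses the closed-form spectral solution, which keeps structural zeros
    exact (in particular ``P[1, 0] = 0`` for the irreversible SNV
    generator) and the rows summing to one.
    """
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    A = np.asarray(A, dtype=float)
    q1, q2 = A[0, 1], A[1, 0]
    s = q1 + q2
    if s == 0.0:
        return np.eye(2)
    e = np.exp(-s * t)
    return np.array([
        [(q2 + q1 * e) / s, q1 * (1.0 - e) / s],
        [q2 * (1.0 - e) / s, (q1 + q2 * e) / s],
    ])


def mixture_weight(theta_parent_i: float, P: np.ndarray, eta: float) -> float:
    """Weight of the +mu Laplace component for one site.

    The parent's state call selects the CTMC row: ``P[m -> m]`` when the
    parent parameter is at or above ``eta``, otherwise ``P[u -> m]``.
    """
    return float(P[1, 1]) if theta_parent_i >= eta else float(P[0, 1])


def laplace_logpdf(x, loc: float, scale: float):
    if scale <= 0:
        raise ValueError("Laplace scale must be positive")
    x = np.asarray(x, dtype=float)
    return -np.log(2.0 * scale) - np.abs(x - loc) / scale


def _mixture_weights_vec(theta_parent: np.ndarray, P: np.ndarray,
                         eta: float) -> np.ndarray:
    return np.where(np.asarray(theta_parent) >= eta, P[1, 1], P[0, 1])


def transition_logpdf(theta_child, theta_parent, t: float,
                      params: EvolutionParams) -> float:
    """Log density of a child's clone parameters given its parent's.

    Site-wise two-component Laplace mixture with CTMC-derived weights;
    the branch length ``t`` enters through ``P(t)``.
    """
    if t <= 0:
        raise ValueError("branch length must be positive")
    theta_child = np.asarray(theta_child, dtype=float)
    theta_parent = np.asarray(theta_parent, dtype=float)
    P = params.transition(t)
    w = _mixture_weights_vec(theta_parent, P, params.eta)
    with np.errstate(divide="ignore"):
        lw = np.log(np.clip(w, 0.0, 1.0))
        l1w = np.log(np.clip(1.0 - w, 0.0, 1.0))
    pos = laplace_logpdf(theta_child, params.mu, params.Lambda)
    neg = laplace_logpdf(theta_child, -params.mu, params.Lambda)
    return float(np.logaddexp(lw + pos, l1w + neg).sum())


def root_log_prior(theta_root, mu: float, Lambda: float) -> float:
    """Log prior of the root clone: independent Laplace(-mu, Lambda) per
    site, favoring a fully unmethylated/unmutated root."""
    return float(laplace_logpdf(theta_root, -mu, Lambda).sum())


def call_state(theta_i: float, eta: float) -> str:
    """Discrete state call for one site: 'm' iff ``theta_i >= eta``."""
    return "m" if theta_i >= eta else "u"


def genotype_call(theta, eta: float) -> np.ndarray:
    """Vectorized 0/1 state call over a clone parameter vector."""
    return (np.asarray(theta, dtype=float) >= eta).astype(np.int8)
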