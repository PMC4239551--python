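"""Truncated-state-space kernels of the linear birth-death-with-gain process.

The model is a continuous-time Markov chain on family size i ∈ {0, 1, 2, ...}
with per-copy birth (expansion) rate λ, per-copy death (loss) rate µ, and a
size-independent gain (innovation) rate κ: from state i the chain jumps to
i+1 at rate λ·i + κ and to i−1 at rate µ·i.  Root family sizes follow a
Poisson distribution with mean Φ.

Numerically the chain is truncated to {0, ..., M}; state M has no outgoing
birth transition, so the truncated generator has exact zero row sums and its
matrix exponential is exactly row-stochastic.  M is chosen large enough that
the probability mass reaching M from any relevant start state is below a
small tail tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.stats import poisson

__all__ = [
    "BranchRates",
    "RootPrior",
    "TruncationBound",
    "TruncationOverflowError",
    "build_generator",
    "transition_matrix",
    "root_distribution",
    "default_bound",
]


@dataclass(frozen=True)
class BranchRates:
    """Rates and duration governing evolution along one branch.

    Parameters
    ----------
    duration : float
        Branch time t ≥ 0.
    expansion_rate : float
        Per-copy birth rate λ ≥ 0.
    loss_rate : float
        Per-copy death rate µ ≥ 0.
    gain_rate : float
        Size-independent innovation rate κ ≥ 0.
    """

    duration: float
    expansion_rate: float
    loss_rate: float
    gain_rate: float

    def __post_init__(self) -> None:
        for name in ("duration", "expansion_rate", "loss_rate", "gain_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def scaled(self, t_f: float = 1.0, lam_f: float = 1.0, mu_f: float = 1.0,
               kap_f: float = 1.0) -> "BranchRates":
        """Branch rates multiplied by family-component multipliers."""
        return BranchRates(
            duration=self.duration * t_f,
            expansion_rate=self.expansion_rate * lam_f,
            loss_rate=self.loss_rate * mu_f,
            gain_rate=self.gain_rate * kap_f,
        )


@dataclass(frozen=True)
class RootPrior:
    """Poisson prior on the family size at the root, with mean Φ."""

    mean: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean) or self.mean < 0:
            raise ValueError(f"root mean must be finite and >= 0, got {self.mean!r}")


@dataclass(frozen=True)
class TruncationBound:
    """Finite cap M on the count state space {0, ..., M}.

    ``tail_tolerance`` is the largest acceptable probability of reaching the
    boundary state M; kernels whose relevant rows exceed it should be
    recomputed at a doubled bound.
    """

    max_count: int
    tail_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.max_count < 1:
            raise ValueError("max_count must be >= 1")
        if not (0 < self.tail_tolerance < 1):
            raise ValueError("tail_tolerance must be in (0, 1)")

    @property
    def n_states(self) -> int:
        return self.max_count + 1


class TruncationOverflowError(RuntimeError):
    """Raised when tail mass at the truncation boundary exceeds tolerance."""


def default_bound(max_leaf_count: int, total_count: int,
                  tail_tolerance: float = 1e-8) -> TruncationBound:
    """Per-family truncation rule: max(2 × largest leaf count, total + 10)."""
    m = max(2 * int(max_leaf_count), int(total_count) + 10, 1)
    return TruncationBound(max_count=m, tail_tolerance=tail_tolerance)


def build_generator(rates: BranchRates, bound: TruncationBound) -> np.ndarray:
    """Rate matrix Q of the truncated birth-death-gain chain on {0, ..., M}.

    Off-diagonals are q(i, i+1) = λ·i + κ for i < M and q(i, i−1) = µ·i for
    i > 0; the diagonal makes every row sum exactly zero.  The boundary state
    M has no birth transition out (truncation device).
    """
    m = bound.max_count
    i = np.arange(m + 1, dtype=float)
    q = np.zeros((m + 1, m + 1))
    up = rates.expansion_rate * i[:-1] + rates.gain_rate
    down = rates.loss_rate * i[1:]
    q[np.arange(m), np.arange(1, m + 1)] = up
    q[np.arange(1, m + 1), np.arange(m)] = down
    q[np.diag_indices(m + 1)] = -q.sum(axis=1)
    return q


def transition_matrix(rates: BranchRates, bound: TruncationBound) -> np.ndarray:
    """Row-stochastic kernel P(i, j) = Pr[count j at branch end | i at start].

    The reference kernel is the matrix exponential of duration × the
    truncated generator, which is exactly row-stochastic by construction.
    """
    if rates.duration == 0:
        return np.eye(bound.n_states)
    p = expm(rates.duration * build_generator(rates, bound))
    # expm can produce tiny negative round-off; clip and renormalize.
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def root_distribution(prior: RootPrior, bound: TruncationBound) -> np.ndarray:
    """Poisson(Φ) pmf over {0, ..., M}; residual tail mass lumped into M."""
    k = np.arange(bound.n_states)
    pi = poisson.pmf(k, prior.mean)
    pi[-1] += max(0.0, 1.0 - pi.sum())
    return pi
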