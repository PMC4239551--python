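"""Pruning-algorithm likelihood of phylogenetic profiles on a species tree.

The conditional-likelihood (pruning) recursion runs on the truncated count
space {0, ..., M}: for every node v and count k it accumulates
Pr[leaf counts below v | state k at v], combines children through the branch
transition kernels, and finishes at the root against the Poisson prior.
Partial likelihoods are rescaled per node (with the log of the scale factors
accumulated) so that profiles with very small likelihood never underflow —
the objective is finite, or exactly −inf for a genuinely impossible profile,
but never NaN.

Family-rate heterogeneity enters as an equal-weight finite mixture over
category combinations: with c_t, c_λ, c_µ, c_κ categories per family
parameter, the family likelihood averages the K = Π c_p component
likelihoods whose branch parameters are multiplied by the combination's
(t_f, λ_f, µ_f, κ_f) category means.

Ascertainment: families are observed only if present in at least one leaf
genome, so by default each family likelihood is conditioned on non-absence,
dividing by 1 − Pr[all leaves 0].  For mixture models the correction is
applied to the mixture as a whole.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np

from .core import (BranchRates, RootPrior, TruncationBound,
                   TruncationOverflowError, default_bound,
                   root_distribution, transition_matrix)
from .models import ModelParams
from .profiles import PhyloProfile, ProfileSet
from .tree import SpeciesTree

__all__ = [
    "PruningEngine",
    "profile_loglik",
    "absent_profile_logprob",
    "corrected_loglik",
    "family_mixture_loglik",
    "dataset_loglik",
]


def _stable_sum(values: np.ndarray) -> float:
    """Order-independent exact-ish summation: fsum over sorted values."""
    v = np.asarray(values, dtype=float)
    if np.any(np.isneginf(v)):
        return float("-inf")
    return math.fsum(np.sort(v))


class PruningEngine:
    """Vectorized likelihood, kernel cache, and truncation management.

    One engine instance is bound to a tree; it evaluates whole datasets at
    once (partial-likelihood arrays carry a family axis) and caches branch
    kernels keyed by their effective (t, λ, µ, κ, M), so repeated
    evaluations during optimization — which typically perturb one branch at
    a time — recompute only the kernels that changed.
    """

    def __init__(self, tree: SpeciesTree, ascertainment: bool = True,
                 tail_tolerance: float = 1e-8, max_bound: int = 128):
        self.tree = tree
        self.ascertainment = ascertainment
        self.tail_tolerance = tail_tolerance
        self.max_bound = max_bound
        self._kernel_cache: dict[tuple, np.ndarray] = {}

    # ------------------------------------------------------------------
    #: bucket sizes for per-family truncation bounds (kernels are shared
    #: within a bucket, so only families that need a large state space pay
    #: for a large kernel; coarse buckets keep the kernel count per
    #: likelihood evaluation small)
    BUCKETS = (24, 48, 96, 128, 192, 256, 384, 512)

    def choose_bound(self, counts: np.ndarray) -> int:
        """Dataset truncation bound: max over families of the per-family rule
        max(2 × largest leaf count, family total + 10), floored at 15."""
        if counts.size == 0:
            return 15
        return int(self.family_bounds(counts).max())

    def family_bounds(self, counts: np.ndarray) -> np.ndarray:
        """Per-family truncation rule, capped at ``max_bound`` (but never
        below the largest observed count)."""
        counts = np.atleast_2d(counts)
        biggest = int(counts.max()) if counts.size else 0
        if biggest + 1 > max(4 * self.max_bound, 2048):
            raise TruncationOverflowError(
                f"a family has {biggest} members; the truncated state space "
                f"needed exceeds the kernel size this engine can afford "
                f"(max_bound={self.max_bound}); raise max_bound or filter "
                "the family"
            )
        req = np.maximum(2 * counts.max(axis=1), counts.sum(axis=1) + 10)
        req = np.maximum(req, 15)
        return np.maximum(np.minimum(req, self.max_bound),
                          counts.max(axis=1) + 1)

    def _bucketize(self, req: np.ndarray) -> np.ndarray:
        out = np.empty_like(req)
        for i, r in enumerate(req):
            for bm in self.BUCKETS:
                if bm >= r:
                    out[i] = bm
                    break
            else:
                out[i] = int(r)
        return out

    def _kernel(self, rates: BranchRates, m: int) -> np.ndarray:
        key = (m, rates.duration, rates.expansion_rate, rates.loss_rate,
               rates.gain_rate)
        p = self._kernel_cache.get(key)
        if p is None:
            p = transition_matrix(rates, TruncationBound(m, self.tail_tolerance))
            if len(self._kernel_cache) > 20000:
                self._kernel_cache.clear()
            self._kernel_cache[key] = p
        return p

    def _combo_kernels(self, params: ModelParams, m: int,
                       mult: tuple[float, float, float, float]
                       ) -> list[np.ndarray]:
        tree = self.tree
        out = []
        for b, node in enumerate(tree.branch_nodes):
            rates = BranchRates(
                duration=params.t_b[b] * mult[0],
                expansion_rate=params.lam_b[b] * mult[1],
                loss_rate=params.mu_b[b] * mult[2],
                gain_rate=params.kap_b[b] * mult[3],
            )
            out.append(self._kernel(rates, m))
        return out

    def _tail_ok(self, kernels: list[np.ndarray], max_obs: int, m: int) -> bool:
        """Mass at the boundary from start states up to the observed range."""
        hi = min(max_obs, m)
        return all(p[: hi + 1, -1].max() <= self.tail_tolerance for p in kernels)

    # ------------------------------------------------------------------
    def _pruning(self, counts: np.ndarray, kernels: list[np.ndarray],
                 root_pi: np.ndarray) -> np.ndarray:
        """Log-likelihood per family for one fixed set of branch kernels.

        counts: (n, n_leaves) in tree leaf order.  Returns (n,) log values
        (−inf where the profile is impossible), never NaN.
        """
        tree = self.tree
        n = counts.shape[0]
        m1 = root_pi.shape[0]
        logscale = np.zeros(n)
        partial: dict[int, np.ndarray] = {}
        leaf_pos = {node: j for j, node in enumerate(tree.leaves)}
        for node in range(tree.n_nodes):  # post-order by construction
            kids = tree.children[node]
            if not kids:
                arr = np.zeros((n, m1))
                arr[np.arange(n), counts[:, leaf_pos[node]]] = 1.0
            else:
                arr = np.ones((n, m1))
                for c in kids:
                    arr *= partial.pop(c) @ kernels[c].T
                scale = arr.max(axis=1)
                pos = scale > 0
                with np.errstate(divide="ignore"):
                    logscale += np.where(pos, np.log(np.where(pos, scale, 1.0)),
                                         -np.inf)
                arr[pos] /= scale[pos, None]
            partial[node] = arr
        lik = partial[tree.root] @ root_pi
        with np.errstate(divide="ignore"):
            out = np.where(lik > 0, np.log(np.where(lik > 0, lik, 1.0)), -np.inf)
        return out + logscale

    # ------------------------------------------------------------------
    def component_logliks(self, params: ModelParams, counts: np.ndarray,
                          m: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-combination per-family log-likelihoods and absence log-probs.

        Returns (ll, ll0): ll has shape (K, n) with the unconditioned
        log-likelihood of every family under every category combination (in
        lexicographic (t, λ, µ, κ) category order); ll0 has shape (K,) with
        the all-zero-profile log-probability of each combination.

        The pruning pass is batched over the K category combinations (the
        all-zero profile rides along as an extra pseudo-family).
        """
        spec = params.spec
        mults = params.family_multipliers()
        root_pi = root_distribution(RootPrior(params.phi),
                                    TruncationBound(m, self.tail_tolerance))
        aug = np.vstack([counts,
                         np.zeros((1, counts.shape[1]), dtype=counts.dtype)])
        stacks: list[np.ndarray | None] = [None] * self.tree.n_nodes
        per_node: list[list[np.ndarray]] = [[] for _ in self.tree.branch_nodes]
        for idx in itertools.product(*(range(c) for c in spec.categories)):
            mult = tuple(float(mults[p][idx[p]]) for p in range(4))
            for b, kern in enumerate(self._combo_kernels(params, m, mult)):
                per_node[b].append(kern)
        for b, node in enumerate(self.tree.branch_nodes):
            stacks[node] = np.ascontiguousarray(
                np.stack(per_node[b]).transpose(0, 2, 1))
        ll_aug = self._pruning_batched(aug, stacks, root_pi)
        return ll_aug[:, :-1], ll_aug[:, -1]

    def _pruning_batched(self, counts: np.ndarray,
                         kernels_t: list[np.ndarray | None],
                         root_pi: np.ndarray) -> np.ndarray:
        """Pruning with a leading category-combination axis.

        ``kernels_t[node]`` holds the transposed kernel stack (K, M+1, M+1)
        for the branch above ``node``.  Returns (K, n) log-likelihoods.
        """
        tree = self.tree
        n = counts.shape[0]
        m1 = root_pi.shape[0]
        k = next(s.shape[0] for s in kernels_t if s is not None)
        logscale = np.zeros((k, n))
        partial: dict[int, np.ndarray] = {}
        leaf_pos = {node: j for j, node in enumerate(tree.leaves)}
        for node in range(tree.n_nodes):  # post-order by construction
            kids = tree.children[node]
            if not kids:
                arr = np.zeros((n, m1))
                arr[np.arange(n), counts[:, leaf_pos[node]]] = 1.0
                arr = arr[None, :, :]  # broadcast over combinations
            else:
                arr = np.ones((k, n, m1))
                for c in kids:
                    arr *= np.matmul(partial.pop(c), kernels_t[c])
                scale = arr.max(axis=2)
                pos = scale > 0
                with np.errstate(divide="ignore"):
                    logscale += np.where(pos,
                                         np.log(np.where(pos, scale, 1.0)),
                                         -np.inf)
                arr = np.where(pos[:, :, None], arr / np.where(
                    pos, scale, 1.0)[:, :, None], arr)
            partial[node] = arr
        lik = partial[tree.root] @ root_pi
        with np.errstate(divide="ignore"):
            out = np.where(lik > 0, np.log(np.where(lik > 0, lik, 1.0)),
                           -np.inf)
        return out + logscale

    def family_logliks(self, params: ModelParams, counts: np.ndarray,
                       m: int | None = None,
                       ascertainment: bool | None = None,
                       grow: bool = True) -> np.ndarray:
        """Per-family mixture log-likelihoods, ascertainment-corrected.

        The truncation bound is audited on the base branch kernels before
        the mixture is evaluated: while the boundary state accumulates more
        mass than the tail tolerance from any observed start state, the
        bound doubles (up to ``max_bound``).  ``grow=False`` freezes the
        bound (used inside optimization loops, where the final estimate is
        re-audited)."""
        if ascertainment is None:
            ascertainment = self.ascertainment
        n = counts.shape[0]
        if m is not None:
            groups = [(int(m), np.arange(n))]
        else:
            buckets = self._bucketize(self.family_bounds(counts))
            groups = [(int(bm), np.flatnonzero(buckets == bm))
                      for bm in np.unique(buckets)]
        out = np.empty(n)
        for bm, idx in groups:
            # identical profiles share one pruning pass
            sub, inverse = np.unique(counts[idx], axis=0, return_inverse=True)
            if grow:
                max_obs = int(sub.max()) if sub.size else 0
                while not self._audit(params, bm, max_obs):
                    if 2 * bm > self.max_bound:
                        warnings.warn(
                            f"truncation bound capped at M={bm}; tail mass "
                            f"above {self.tail_tolerance:g}", stacklevel=2)
                        break
                    bm *= 2
            ll, ll0 = self.component_logliks(params, sub, bm)
            ll = ll[:, inverse]
            logk = math.log(ll.shape[0])
            mix = _logsumexp_axis0(ll) - logk
            if ascertainment:
                p0 = float(np.exp(_logsumexp_axis0(ll0[:, None])[0] - logk))
                if p0 >= 1.0 - 1e-15:
                    raise FloatingPointError(
                        "degenerate model: probability of total absence is "
                        "1; the ascertainment correction is undefined"
                    )
                mix = mix - math.log1p(-p0)
            out[idx] = mix
        return out

    def _audit(self, params: ModelParams, m: int, max_obs: int) -> bool:
        rates = params.rates_list()
        return self._tail_ok([self._kernel(r, m) for r in rates], max_obs, m)

    def dataset_loglik(self, params: ModelParams, data: ProfileSet,
                       m: int | None = None,
                       ascertainment: bool | None = None) -> float:
        counts = data.matrix_for(self.tree)
        ll = self.family_logliks(params, counts, m, ascertainment)
        if np.any(np.isneginf(ll)):
            bad = [data.family_ids[i] for i in np.flatnonzero(np.isneginf(ll))]
            warnings.warn(f"families with zero likelihood: {bad[:5]}"
                          + ("..." if len(bad) > 5 else ""), stacklevel=2)
        return _stable_sum(ll)


def _logsumexp_axis0(a: np.ndarray) -> np.ndarray:
    """logsumexp along axis 0 that propagates −inf columns without NaN."""
    mx = a.max(axis=0)
    finite = np.isfinite(mx)
    out = np.full(a.shape[1:], -np.inf)
    if np.any(finite):
        shifted = a[:, finite] - mx[finite]
        out[finite] = mx[finite] + np.log(np.exp(shifted).sum(axis=0))
    return out


# ----------------------------------------------------------------------
# Single-profile operations (thin wrappers over the engine)
# ----------------------------------------------------------------------

def _single(tree: SpeciesTree, rates: list[BranchRates], prior: RootPrior,
            counts: np.ndarray, bound: TruncationBound) -> float:
    engine = PruningEngine(tree, ascertainment=False,
                           tail_tolerance=bound.tail_tolerance)
    root_pi = root_distribution(prior, bound)
    kernels = [engine._kernel(r, bound.max_count) for r in rates]
    return float(engine._pruning(counts.reshape(1, -1), kernels, root_pi)[0])


def profile_loglik(tree: SpeciesTree, rates: list[BranchRates],
                   prior: RootPrior, profile: PhyloProfile,
                   bound: TruncationBound | None = None) -> float:
    """Unconditioned log-likelihood of one family profile.

    ``rates`` lists BranchRates per branch in post-order (branch = child
    node).  Returns −inf (not NaN) for impossible profiles.
    """
    counts = profile.vector(tree)
    if bound is None:
        bound = default_bound(counts.max(), counts.sum())
    if counts.max() > bound.max_count:
        raise TruncationOverflowError(
            "truncation bound smaller than an observed count")
    return _single(tree, rates, prior, counts, bound)


def absent_profile_logprob(tree: SpeciesTree, rates: list[BranchRates],
                           prior: RootPrior,
                           bound: TruncationBound | None = None) -> float:
    """Log-probability that the family is absent from every leaf."""
    if bound is None:
        bound = default_bound(1, 1)
    zeros = np.zeros(tree.n_leaves, dtype=int)
    return _single(tree, rates, prior, zeros, bound)


def corrected_loglik(tree: SpeciesTree, rates: list[BranchRates],
                     prior: RootPrior, profile: PhyloProfile,
                     bound: TruncationBound | None = None,
                     ascertainment: bool = True) -> float:
    """Family log-likelihood conditioned on presence in ≥1 leaf."""
    ll = profile_loglik(tree, rates, prior, profile, bound)
    if not ascertainment:
        return ll
    ll0 = absent_profile_logprob(tree, rates, prior, bound)
    if ll0 >= 0.0:
        raise FloatingPointError("degenerate model: Pr[absent] >= 1")
    return ll - math.log1p(-math.exp(ll0))


def family_mixture_loglik(tree: SpeciesTree, params: ModelParams,
                          profile: PhyloProfile,
                          bound: TruncationBound | None = None,
                          ascertainment: bool = True) -> float:
    """Equal-weight mixture log-likelihood over family category combinations."""
    counts = profile.vector(tree)
    if bound is None:
        bound = default_bound(counts.max(), counts.sum())
    engine = PruningEngine(tree, ascertainment=ascertainment,
                           tail_tolerance=bound.tail_tolerance,
                           max_bound=bound.max_count)
    return float(engine.family_logliks(params, counts.reshape(1, -1),
                                       m=bound.max_count,
                                       ascertainment=ascertainment)[0])


def dataset_loglik(tree: SpeciesTree, params: ModelParams, data: ProfileSet,
                   bound: TruncationBound | None = None,
                   ascertainment: bool = True) -> float:
    """Sum of per-family (mixture, corrected) log-likelihoods.

    The per-family values are summed in a fixed (sorted) order, so the
    result is invariant to the ordering of the profiles to the last bit.
    """
    engine = PruningEngine(tree, ascertainment=ascertainment)
    m = bound.max_count if bound is not None else None
    return engine.dataset_loglik(params, data, m=m, ascertainment=ascertainment)
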