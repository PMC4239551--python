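"""Second-pass inference: ancestral family sizes and expected branch events.

Given fitted parameters, an inside/outside (up/down) pass over the truncated
count space yields, for every family:

* the exact posterior distribution of the count at each internal node given
  the leaf profile, and its expectation (the expected ancestral family
  size);
* the joint posterior of (parent count x, child count y) on every branch,
  from which endpoint-defined event probabilities are read off:
  gain = Pr[x = 0, y ≥ 1], loss = Pr[x ≥ 1, y = 0],
  expansion = Pr[y > x ≥ 1], contraction = Pr[x > y ≥ 1], and the
  remainder is stasis (x = y, including joint absence).

Events are endpoint-defined: a branch whose family is absent at both ends
counts no event even if a gain and loss occurred within the branch.

Under family-rate mixtures the per-combination posteriors are averaged with
posterior combination weights ∝ (1/K) × component likelihood of the
observed profile.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RootPrior, TruncationBound, root_distribution
from .likelihood import PruningEngine
from .models import ModelParams
from .profiles import PhyloProfile, ProfileSet
from .tree import SpeciesTree

__all__ = ["AncestralPosterior", "EventSummary", "ancestral_posterior",
           "branch_event_probs", "aggregate_events"]

EVENT_KINDS = ("gains", "losses", "expansions", "contractions", "stasis")


@dataclass
class AncestralPosterior:
    """Posterior count distributions at internal nodes for one family."""

    family_id: str
    node_posteriors: dict[str, np.ndarray]
    expected_sizes: dict[str, float]


@dataclass
class EventSummary:
    """Expected event counts per branch, summed over families.

    ``per_branch`` is indexed by branch (child-node) label with columns
    gains / losses / expansions / contractions / net_change; expectations
    are sums over families of per-family endpoint event probabilities, so
    each column is bounded by the number of families.  ``root_fractions``
    holds the family-averaged posterior probabilities of 0, 1, and more than
    one member at the root.
    """

    per_branch: pd.DataFrame
    root_fractions: pd.Series
    n_families: int
    failed_families: list[str] = field(default_factory=list)


# ----------------------------------------------------------------------

class _FamilyPass:
    """Inside/outside arrays for one family under one category combination."""

    def __init__(self, tree: SpeciesTree, kernels: list[np.ndarray],
                 root_pi: np.ndarray, counts: np.ndarray):
        m1 = root_pi.shape[0]
        leaf_pos = {node: j for j, node in enumerate(tree.leaves)}
        inside: list[np.ndarray] = [None] * tree.n_nodes  # type: ignore
        up_msg: list[np.ndarray] = [None] * tree.n_nodes  # type: ignore
        loglik = 0.0
        for node in range(tree.n_nodes):
            kids = tree.children[node]
            if not kids:
                arr = np.zeros(m1)
                arr[counts[leaf_pos[node]]] = 1.0
            else:
                arr = np.ones(m1)
                for c in kids:
                    arr = arr * up_msg[c]
            s = arr.max()
            if s > 0:
                arr = arr / s
                loglik += np.log(s)
            else:
                loglik = -np.inf
            inside[node] = arr
            if node != tree.root:
                up_msg[node] = kernels[node] @ arr
        lik = float(inside[tree.root] @ root_pi)
        self.loglik = (np.log(lik) + loglik) if lik > 0 else -np.inf
        # outside pass
        outside: list[np.ndarray] = [None] * tree.n_nodes  # type: ignore
        outside[tree.root] = root_pi.copy()
        for node in range(tree.n_nodes - 1, -1, -1):
            kids = tree.children[node]
            for c in kids:
                sib = np.ones(m1)
                for c2 in kids:
                    if c2 != c:
                        sib = sib * up_msg[c2]
                msg = (outside[node] * sib) @ kernels[c]
                s = msg.max()
                outside[c] = msg / s if s > 0 else msg
        self.tree = tree
        self.kernels = kernels
        self.inside = inside
        self.outside = outside
        self.up_msg = up_msg

    def node_posterior(self, node: int) -> np.ndarray:
        p = self.outside[node] * self.inside[node]
        s = p.sum()
        if s <= 0:
            raise FloatingPointError("posterior underflow at a node")
        return p / s

    def branch_joint(self, child: int) -> np.ndarray:
        """Joint posterior J(x, y) of parent state x and child state y."""
        parent = self.tree.parent[child]
        sib = np.ones_like(self.inside[child])
        for c2 in self.tree.children[parent]:
            if c2 != child:
                sib = sib * self.up_msg[c2]
        j = (self.outside[parent] * sib)[:, None] * self.kernels[child] \
            * self.inside[child][None, :]
        s = j.sum()
        if s <= 0:
            raise FloatingPointError("posterior underflow on a branch")
        return j / s


def _combo_passes(tree: SpeciesTree, params: ModelParams, counts: np.ndarray,
                  m: int, tail_tol: float,
                  engine: PruningEngine | None = None,
                  ) -> tuple[list[_FamilyPass], np.ndarray]:
    """One _FamilyPass per category combination, plus posterior weights."""
    if engine is None:
        engine = PruningEngine(tree, tail_tolerance=tail_tol)
    mults = params.family_multipliers()
    root_pi = root_distribution(RootPrior(params.phi),
                                TruncationBound(m, tail_tol))
    passes, lls = [], []
    for idx in itertools.product(*(range(c) for c in params.spec.categories)):
        mult = tuple(float(mults[p][idx[p]]) for p in range(4))
        kernels_list = engine._combo_kernels(params, m, mult)
        kernels = {node: kernels_list[b]
                   for b, node in enumerate(tree.branch_nodes)}
        fp = _FamilyPass(tree, kernels, root_pi, counts)
        passes.append(fp)
        lls.append(fp.loglik)
    lls = np.asarray(lls)
    if np.all(np.isneginf(lls)):
        raise FloatingPointError("profile has zero likelihood in every category")
    w = np.exp(lls - lls[np.isfinite(lls)].max())
    w[~np.isfinite(lls)] = 0.0
    return passes, w / w.sum()


def _bound_for(counts: np.ndarray, params: ModelParams,
               max_bound: int = 256) -> int:
    """Max over families of the per-family rule, widened for the root prior."""
    counts = np.atleast_2d(counts)
    per_family = np.maximum(2 * counts.max(axis=1), counts.sum(axis=1) + 10)
    m = int(max(int(per_family.max()), 15))
    m = max(m, int(np.ceil(params.phi + 8 * np.sqrt(params.phi + 1))))
    return min(m, max_bound)


# ----------------------------------------------------------------------

def ancestral_posterior(tree: SpeciesTree, params: ModelParams,
                        profile: PhyloProfile, m: int | None = None,
                        tail_tolerance: float = 1e-8,
                        ascertainment: bool = True) -> AncestralPosterior:
    """Exact posterior count distribution at every internal node.

    The ``ascertainment`` flag is accepted for interface symmetry but does
    not alter the posterior: conditioning on the observed profile already
    implies the family was observable.
    """
    counts = profile.vector(tree)
    if m is None:
        m = _bound_for(counts, params)
    passes, w = _combo_passes(tree, params, counts, m, tail_tolerance)
    node_post: dict[str, np.ndarray] = {}
    expected: dict[str, float] = {}
    ks = np.arange(m + 1)
    for node in tree.internal_nodes():
        p = sum(wi * fp.node_posterior(node) for wi, fp in zip(w, passes))
        p = p / p.sum()
        lbl = tree.labels[node]
        node_post[lbl] = p
        expected[lbl] = float(p @ ks)
    return AncestralPosterior(profile.family_id, node_post, expected)


def branch_event_probs(tree: SpeciesTree, params: ModelParams,
                       profile: PhyloProfile, m: int | None = None,
                       tail_tolerance: float = 1e-8,
                       ascertainment: bool = True) -> pd.DataFrame:
    """Endpoint-event probabilities per branch for one family.

    Returns a DataFrame indexed by branch label with columns gains, losses,
    expansions, contractions, stasis; each row sums to 1.
    """
    counts = profile.vector(tree)
    if m is None:
        m = _bound_for(counts, params)
    passes, w = _combo_passes(tree, params, counts, m, tail_tolerance)
    df = pd.DataFrame(_event_rows(tree, passes, w),
                      index=tree.branch_labels(), columns=EVENT_KINDS)
    df.index.name = "branch"
    return df


def _event_rows(tree: SpeciesTree, passes: list[_FamilyPass],
                w: np.ndarray) -> np.ndarray:
    rows = []
    for child in tree.branch_nodes:
        j = sum(wi * fp.branch_joint(child) for wi, fp in zip(w, passes))
        j = j / j.sum()
        gain = j[0, 1:].sum()
        loss = j[1:, 0].sum()
        upper = np.triu(j, k=1)[1:, :].sum()   # y > x >= 1
        lower = np.tril(j, k=-1)[:, 1:].sum()  # x > y >= 1
        stasis = np.trace(j)
        rows.append((gain, loss, upper, lower, stasis))
    return np.asarray(rows)


def root_posterior(tree: SpeciesTree, params: ModelParams,
                   profile: PhyloProfile, m: int | None = None,
                   tail_tolerance: float = 1e-8) -> np.ndarray:
    counts = profile.vector(tree)
    if m is None:
        m = _bound_for(counts, params)
    passes, w = _combo_passes(tree, params, counts, m, tail_tolerance)
    p = sum(wi * fp.node_posterior(tree.root) for wi, fp in zip(w, passes))
    return p / p.sum()


def aggregate_events(tree: SpeciesTree, params: ModelParams,
                     data: ProfileSet, m: int | None = None,
                     tail_tolerance: float = 1e-8,
                     ascertainment: bool = True) -> EventSummary:
    """Expected per-branch event counts and root size fractions over a dataset.

    Families whose posterior computation fails numerically are excluded from
    the sums and reported in ``failed_families`` (never silently dropped).
    """
    counts = data.matrix_for(tree)
    if m is None:
        m = _bound_for(counts, params) if counts.size else 15
    engine = PruningEngine(tree, tail_tolerance=tail_tolerance)
    totals = np.zeros((tree.n_branches, len(EVENT_KINDS)))
    root_frac = np.zeros(3)
    failed: list[str] = []
    n_used = 0
    for i in range(data.n):
        try:
            passes, w = _combo_passes(tree, params, counts[i], m,
                                      tail_tolerance, engine)
            rows = _event_rows(tree, passes, w)
            rp = sum(wi * fp.node_posterior(tree.root)
                     for wi, fp in zip(w, passes))
            rp = rp / rp.sum()
        except FloatingPointError:
            failed.append(data.family_ids[i])
            continue
        totals += rows
        root_frac += np.array([rp[0], rp[1], rp[2:].sum()])
        n_used += 1
    totals = pd.DataFrame(totals, index=tree.branch_labels(),
                          columns=EVENT_KINDS)
    if n_used:
        root_frac /= n_used
    out = totals[["gains", "losses", "expansions", "contractions"]].copy()
    out["net_change"] = out["gains"] - out["losses"]
    out.index.name = "branch"
    return EventSummary(
        per_branch=out,
        root_fractions=pd.Series(root_frac, index=["0", "1", "M"]),
        n_families=n_used,
        failed_families=failed,
    )
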