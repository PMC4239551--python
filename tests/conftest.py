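"""Shared fixtures and independent brute-force oracles.

The oracles enumerate internal-node state assignments exhaustively on the
truncated space, so they share no code path with the pruning recursion or
the inside/outside pass they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from bdgain import (BranchRates, RootPrior, SpeciesTree, TruncationBound,
                    root_distribution, transition_matrix)


@pytest.fixture
def tree2() -> SpeciesTree:
    return SpeciesTree.from_newick("(A,B);")


@pytest.fixture
def tree3() -> SpeciesTree:
    return SpeciesTree.from_newick("((A,B),C);")


@pytest.fixture
def tree4() -> SpeciesTree:
    return SpeciesTree.from_newick("((A,B),(C,D));")


def brute_force_loglik(tree: SpeciesTree, rates: list[BranchRates],
                       phi: float, counts: np.ndarray, m: int) -> float:
    """Log-likelihood by exhaustive summation over internal-node states."""
    bound = TruncationBound(m)
    kernels = {node: transition_matrix(rates[node], bound)
               for node in tree.branch_nodes}
    pi = root_distribution(RootPrior(phi), bound)
    leaf_pos = {node: j for j, node in enumerate(tree.leaves)}
    internal = tree.internal_nodes()
    total = 0.0
    for assign in itertools.product(range(m + 1), repeat=len(internal)):
        state = {node: assign[i] for i, node in enumerate(internal)}
        for node in tree.leaves:
            state[node] = int(counts[leaf_pos[node]])
        term = pi[state[tree.root]]
        for node in tree.branch_nodes:
            term *= kernels[node][state[tree.parent[node]], state[node]]
        total += term
    return np.log(total) if total > 0 else -np.inf


def brute_force_posteriors(tree: SpeciesTree, rates: list[BranchRates],
                           phi: float, counts: np.ndarray, m: int):
    """Joint enumeration posterior: per-node marginals and per-branch
    (parent, child) joints, normalized."""
    bound = TruncationBound(m)
    kernels = {node: transition_matrix(rates[node], bound)
               for node in tree.branch_nodes}
    pi = root_distribution(RootPrior(phi), bound)
    leaf_pos = {node: j for j, node in enumerate(tree.leaves)}
    internal = tree.internal_nodes()
    node_post = {node: np.zeros(m + 1) for node in internal}
    joint = {node: np.zeros((m + 1, m + 1)) for node in tree.branch_nodes}
    total = 0.0
    for assign in itertools.product(range(m + 1), repeat=len(internal)):
        state = {node: assign[i] for i, node in enumerate(internal)}
        for node in tree.leaves:
            state[node] = int(counts[leaf_pos[node]])
        term = pi[state[tree.root]]
        for node in tree.branch_nodes:
            term *= kernels[node][state[tree.parent[node]], state[node]]
        total += term
        for node in internal:
            node_post[node][state[node]] += term
        for node in tree.branch_nodes:
            joint[node][state[tree.parent[node]], state[node]] += term
    for node in internal:
        node_post[node] /= total
    for node in tree.branch_nodes:
        joint[node] /= total
    return node_post, joint


@pytest.fixture
def oracle_loglik():
    return brute_force_loglik


@pytest.fixture
def oracle_posteriors():
    return brute_force_posteriors
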