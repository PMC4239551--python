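"""Posterior ancestral states and endpoint-defined branch events."""

import numpy as np
import pytest

from bdgain import (BranchRates, ModelParams, ModelSpec, PhyloProfile,
                    ProfileSet, aggregate_events, ancestral_posterior,
                    branch_event_probs)
from bdgain.core import RootPrior, TruncationBound, root_distribution, \
    transition_matrix


def const_params(tree, lam=0.3, mu=0.8, kap=0.2, phi=1.0):
    nb = tree.n_branches
    return ModelParams(ModelSpec.constant(), t_b=np.ones(nb),
                       lam_b=np.full(nb, lam), mu_b=np.full(nb, mu),
                       kap_b=np.full(nb, kap), phi=phi)


class TestAncestralPosterior:
    def test_zero_dynamics_point_mass(self, tree3):
        params = const_params(tree3, 0, 0, 0, 1.0)
        post = ancestral_posterior(tree3, params,
                                   PhyloProfile("f", {"A": 2, "B": 2, "C": 2}))
        for lbl, vec in post.node_posteriors.items():
            assert vec[2] == pytest.approx(1.0, abs=1e-12)
            assert post.expected_sizes[lbl] == pytest.approx(2.0)

    def test_all_zero_profile_root_posterior_is_bayes(self, tree2):
        """With an all-absent profile the root posterior is
        prior(k) · Pr[both leaves 0 | k], normalized."""
        params = const_params(tree2, 0.2, 0.9, 0.1, 1.5)
        m = 12
        from bdgain.events import root_posterior
        got = root_posterior(tree2, params,
                             PhyloProfile("f", {"A": 0, "B": 0}), m=m)
        bound = TruncationBound(m)
        p = transition_matrix(BranchRates(1.0, 0.2, 0.9, 0.1), bound)
        pi = root_distribution(RootPrior(1.5), bound)
        expect = pi * p[:, 0] ** 2
        expect /= expect.sum()
        assert np.allclose(got, expect, atol=1e-10)

    def test_matches_joint_enumeration(self, tree3, oracle_posteriors):
        params = const_params(tree3)
        counts = np.array([1, 0, 2])
        m = 8
        node_ref, _ = oracle_posteriors(tree3, params.rates_list(), 1.0,
                                        counts, m)
        post = ancestral_posterior(tree3, params,
                                   PhyloProfile("f", {"A": 1, "B": 0, "C": 2}),
                                   m=m)
        for node in tree3.internal_nodes():
            assert np.allclose(post.node_posteriors[tree3.labels[node]],
                               node_ref[node], atol=1e-10)


class TestBranchEventProbs:
    def test_zero_rates_yield_no_events(self, tree3):
        params = const_params(tree3, 0, 0, 0, 1.0)
        probs = branch_event_probs(tree3, params,
                                   PhyloProfile("f", {"A": 2, "B": 2, "C": 2}))
        assert np.allclose(probs[["gains", "losses", "expansions",
                                  "contractions"]].to_numpy(), 0.0)

    def test_no_gain_in_subtree_absent_without_innovation(self, tree3):
        """κ = 0: once absent, always absent, so branches inside an
        all-absent subtree have zero gain probability."""
        params = const_params(tree3, 0.4, 0.9, 0.0, 1.0)
        probs = branch_event_probs(tree3, params,
                                   PhyloProfile("f", {"A": 0, "B": 0, "C": 3}))
        assert probs.loc["A", "gains"] == pytest.approx(0.0, abs=1e-12)
        assert probs.loc["B", "gains"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_joint_enumeration(self, tree3, oracle_posteriors):
        params = const_params(tree3)
        counts = np.array([1, 0, 2])
        m = 8
        _, joint_ref = oracle_posteriors(tree3, params.rates_list(), 1.0,
                                         counts, m)
        probs = branch_event_probs(tree3, params,
                                   PhyloProfile("f", {"A": 1, "B": 0, "C": 2}),
                                   m=m)
        for node in tree3.branch_nodes:
            j = joint_ref[node]
            lbl = tree3.labels[node]
            assert probs.loc[lbl, "gains"] == pytest.approx(j[0, 1:].sum(),
                                                            abs=1e-10)
            assert probs.loc[lbl, "losses"] == pytest.approx(j[1:, 0].sum(),
                                                             abs=1e-10)
            assert probs.loc[lbl, "expansions"] == pytest.approx(
                np.triu(j, 1)[1:, :].sum(), abs=1e-10)
            assert probs.loc[lbl, "contractions"] == pytest.approx(
                np.tril(j, -1)[:, 1:].sum(), abs=1e-10)

    def test_categories_partition_unity(self, tree4):
        params = const_params(tree4, 0.5, 0.6, 0.3, 1.2)
        probs = branch_event_probs(
            tree4, params, PhyloProfile("f", {"A": 2, "B": 0, "C": 1, "D": 4}))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-8)

    def test_mixture_model_partition_and_weighting(self, tree3):
        spec = ModelSpec.family_lineage(2)
        nb = tree3.n_branches
        params = ModelParams(spec, t_b=np.ones(nb), lam_b=np.full(nb, 0.3),
                             mu_b=np.full(nb, 0.8), kap_b=np.full(nb, 0.2),
                             phi=1.0, shapes=np.array([1.0, 0.7, 1.3, 2.0]))
        probs = branch_event_probs(tree3, params,
                                   PhyloProfile("f", {"A": 1, "B": 0, "C": 2}))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-8)


class TestAggregateEvents:
    def test_zero_dynamics_summary(self, tree3):
        params = const_params(tree3, 0, 0, 0, 1.0)
        data = ProfileSet.from_profiles(
            [PhyloProfile("f", {"A": 2, "B": 2, "C": 2})], tree3.leaf_names)
        summary = aggregate_events(tree3, params, data)
        assert np.allclose(
            summary.per_branch[["gains", "losses", "expansions",
                                "contractions"]].to_numpy(), 0.0)
        assert summary.root_fractions["M"] == pytest.approx(1.0)
        assert summary.root_fractions.sum() == pytest.approx(1.0, abs=1e-8)

    def test_duplication_doubles_expectations(self, tree3):
        params = const_params(tree3)
        profs = [PhyloProfile("a", {"A": 1, "B": 0, "C": 2}),
                 PhyloProfile("b", {"A": 2, "B": 2, "C": 0})]
        data = ProfileSet.from_profiles(profs, tree3.leaf_names)
        doubled = ProfileSet.from_profiles(
            profs + [PhyloProfile(p.family_id + "x", p.counts) for p in profs],
            tree3.leaf_names)
        s1 = aggregate_events(tree3, params, data)
        s2 = aggregate_events(tree3, params, doubled)
        assert np.allclose(s2.per_branch.to_numpy(),
                           2 * s1.per_branch.to_numpy(), atol=1e-10)

    def test_expectations_bounded_by_family_count(self, tree3):
        params = const_params(tree3)
        data = ProfileSet.from_profiles(
            [PhyloProfile(f"f{i}", {"A": i % 3, "B": (i + 1) % 2, "C": 1})
             for i in range(6)], tree3.leaf_names)
        summary = aggregate_events(tree3, params, data)
        arr = summary.per_branch[["gains", "losses", "expansions",
                                  "contractions"]].to_numpy()
        assert np.all(arr >= 0) and np.all(arr <= 6)


class TestSimulationCalibration:
    def test_expected_events_match_true_histories(self, tree4):
        """Aggregate posterior event expectations under the generating
        model agree with the simulator's recorded endpoint events within
        Monte-Carlo error."""
        from bdgain.simulate import SimConfig, simulate_dataset
        rates = [BranchRates(1.0, 0.25, 0.5, 0.3)] * tree4.n_branches
        config = SimConfig(tree=tree4, branch_rates=rates, root_mean=1.0,
                           n_families=400, ascertainment=False, seed=5)
        sim = simulate_dataset(config)
        params = const_params(tree4, 0.25, 0.5, 0.3, 1.0)
        summary = aggregate_events(tree4, params, sim.profiles,
                                   ascertainment=False)
        truth = sim.truth_table()
        n = sim.profiles.n
        for lbl in tree4.branch_labels():
            labels = truth[f"event[{lbl}]"]
            for kind, word in (("gains", "gain"), ("losses", "loss"),
                               ("expansions", "expansion"),
                               ("contractions", "contraction")):
                obs = float((labels == word).sum())
                exp = float(summary.per_branch.loc[lbl, kind])
                phat = max(obs, exp) / n
                se = np.sqrt(max(phat * (1 - phat), 1e-6) * n)
                assert abs(obs - exp) <= 3.5 * se + 1.0, \
                    f"{lbl} {kind}: obs={obs} exp={exp:.1f}"
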