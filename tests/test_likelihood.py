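"""Pruning likelihood vs exhaustive enumeration, mixtures, ascertainment."""

import itertools
import math

import numpy as np
import pytest

from bdgain import (BranchRates, ModelParams, ModelSpec, PhyloProfile,
                    ProfileSet, RootPrior, TruncationBound,
                    absent_profile_logprob, corrected_loglik, dataset_loglik,
                    family_mixture_loglik, profile_loglik)
from bdgain.likelihood import PruningEngine


def const_rates(tree, t=1.0, lam=0.3, mu=0.8, kap=0.2):
    return [BranchRates(t, lam, mu, kap)] * tree.n_branches


class TestProfileLoglik:
    def test_zero_dynamics_reduces_to_root_prior(self, tree2):
        """With no dynamics the leaves equal the root draw, so the profile
        (2, 2) has exactly the Poisson(1) pmf at 2 as its likelihood."""
        rates = const_rates(tree2, 0, 0, 0, 0)
        ll = profile_loglik(tree2, rates, RootPrior(1.0),
                            PhyloProfile("f", {"A": 2, "B": 2}))
        assert ll == pytest.approx(math.log(math.exp(-1) / 2), abs=1e-12)

    def test_impossible_profile_is_minus_inf_not_nan(self, tree2):
        rates = const_rates(tree2, 0, 0, 0, 0)
        ll = profile_loglik(tree2, rates, RootPrior(1.0),
                            PhyloProfile("f", {"A": 2, "B": 3}))
        assert ll == -np.inf and not np.isnan(ll)

    @pytest.mark.parametrize("newick,counts", [
        ("(A,B);", {"A": 1, "B": 2}),
        ("((A,B),C);", {"A": 1, "B": 0, "C": 2}),
        ("((A,B),(C,D));", {"A": 0, "B": 2, "C": 1, "D": 1}),
        ("(((A,B),C),D);", {"A": 2, "B": 1, "C": 0, "D": 1}),
    ])
    @pytest.mark.parametrize("lam,mu,kap,phi", [
        (0.3, 0.8, 0.2, 1.0), (0.6, 0.6, 0.1, 0.5),
    ])
    def test_matches_enumeration(self, newick, counts, lam, mu, kap, phi,
                                 oracle_loglik):
        from bdgain import SpeciesTree
        tree = SpeciesTree.from_newick(newick)
        m = 8
        rates = const_rates(tree, 1.0, lam, mu, kap)
        prof = PhyloProfile("f", counts)
        got = profile_loglik(tree, rates, RootPrior(phi), prof,
                             TruncationBound(m))
        ref = oracle_loglik(tree, rates, phi, prof.vector(tree), m)
        assert got == pytest.approx(ref, rel=1e-10)

    def test_leaf_mismatch_raises(self, tree2):
        with pytest.raises(ValueError):
            profile_loglik(tree2, const_rates(tree2), RootPrior(1.0),
                           PhyloProfile("f", {"A": 1, "X": 2}))

    def test_zero_rate_branch_length_is_irrelevant(self, tree3):
        """Lengthening a branch whose rates are all zero cannot change the
        likelihood (identity kernel at any duration)."""
        prof = PhyloProfile("f", {"A": 1, "B": 0, "C": 2})
        base = const_rates(tree3)
        for dur in (0.5, 3.0, 10.0):
            rates = list(base)
            rates[0] = BranchRates(dur, 0, 0, 0)
            ref = rates_ll = profile_loglik(tree3, rates, RootPrior(1.0), prof,
                                            TruncationBound(10))
            rates[0] = BranchRates(0.0, 0, 0, 0)
            again = profile_loglik(tree3, rates, RootPrior(1.0), prof,
                                   TruncationBound(10))
            assert again == pytest.approx(rates_ll, abs=1e-12)

    def test_total_probability_near_one(self, tree2):
        """Σ over all leaf-count pairs of the likelihood ≈ 1 − truncation
        tail on a two-leaf tree."""
        m = 14
        rates = const_rates(tree2, 1.0, 0.2, 0.9, 0.15)
        total = sum(
            math.exp(profile_loglik(tree2, rates, RootPrior(0.8),
                                    PhyloProfile("f", {"A": a, "B": b}),
                                    TruncationBound(m)))
            for a in range(m + 1) for b in range(m + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-6)


class TestAscertainment:
    def test_absent_logprob_zero_dynamics(self, tree2):
        rates = const_rates(tree2, 0, 0, 0, 0)
        assert absent_profile_logprob(tree2, rates, RootPrior(1.0)) == \
            pytest.approx(-1.0, abs=1e-12)

    def test_gain_makes_absence_unlikely(self, tree2):
        rates = const_rates(tree2, 1.0, 0.0, 0.1, 5.0)
        ll0 = absent_profile_logprob(tree2, rates, RootPrior(0.0),
                                     TruncationBound(60))
        assert ll0 < -5

    def test_absent_matches_enumeration(self, tree3, oracle_loglik):
        rates = const_rates(tree3)
        got = absent_profile_logprob(tree3, rates, RootPrior(1.0),
                                     TruncationBound(8))
        ref = oracle_loglik(tree3, rates, 1.0, np.zeros(3, dtype=int), 8)
        assert got == pytest.approx(ref, rel=1e-10)

    def test_correction_arithmetic(self, tree2):
        rates = const_rates(tree2, 0, 0, 0, 0)
        prof = PhyloProfile("f", {"A": 2, "B": 2})
        ll = corrected_loglik(tree2, rates, RootPrior(1.0), prof)
        expect = math.log((math.exp(-1) / 2) / (1 - math.exp(-1)))
        assert ll == pytest.approx(expect, abs=1e-12)

    def test_correction_disabled_is_identity(self, tree3):
        rates = const_rates(tree3)
        prof = PhyloProfile("f", {"A": 1, "B": 0, "C": 2})
        assert corrected_loglik(tree3, rates, RootPrior(1.0), prof,
                                ascertainment=False) == \
            profile_loglik(tree3, rates, RootPrior(1.0), prof)


class TestFamilyMixture:
    def _params(self, tree, spec, shapes=(1.0, 0.7, 1.3, 2.0)):
        nb = tree.n_branches
        return ModelParams(spec, t_b=np.ones(nb), lam_b=np.full(nb, 0.3),
                           mu_b=np.full(nb, 0.8), kap_b=np.full(nb, 0.2),
                           phi=1.0, shapes=np.array(shapes))

    def test_single_category_equals_plain_likelihood(self, tree3):
        spec = ModelSpec.family_lineage(1)
        params = self._params(tree3, spec)
        prof = PhyloProfile("f", {"A": 1, "B": 0, "C": 2})
        got = family_mixture_loglik(tree3, params, prof, TruncationBound(12))
        ref = corrected_loglik(tree3, params.rates_list(), RootPrior(1.0),
                               prof, TruncationBound(12))
        assert got == pytest.approx(ref, rel=1e-12)

    def test_degenerate_categories_collapse(self, tree3):
        """Two numerically identical categories per parameter give the same
        value as one category."""
        prof = PhyloProfile("f", {"A": 1, "B": 0, "C": 2})
        one = family_mixture_loglik(
            tree3, self._params(tree3, ModelSpec.family_lineage(1)), prof,
            TruncationBound(12))
        two = family_mixture_loglik(
            tree3, self._params(tree3, ModelSpec.family_lineage(2),
                                shapes=(1e7, 1e7, 1e7, 1e7)), prof,
            TruncationBound(12))
        assert two == pytest.approx(one, abs=1e-5)

    def test_explicit_sixteen_term_average(self, tree3):
        spec = ModelSpec.family_lineage(2)
        params = self._params(tree3, spec)
        prof = PhyloProfile("f", {"A": 1, "B": 0, "C": 2})
        bound = TruncationBound(12)
        mults = params.family_multipliers()
        comps = []
        for idx in itertools.product(range(2), repeat=4):
            mult = [float(mults[p][idx[p]]) for p in range(4)]
            rates = [BranchRates(mult[0], 0.3 * mult[1], 0.8 * mult[2],
                                 0.2 * mult[3])] * tree3.n_branches
            comps.append(profile_loglik(tree3, rates, RootPrior(1.0), prof,
                                        bound))
        expect = math.log(np.mean(np.exp(comps)))
        got = family_mixture_loglik(tree3, params, prof, bound,
                                    ascertainment=False)
        assert got == pytest.approx(expect, rel=1e-10)
        # mixture bounds: between max component − log K and max component
        assert max(comps) - math.log(16) - 1e-9 <= got <= max(comps) + 1e-9


class TestDatasetLoglik:
    def _toy(self, tree):
        return ProfileSet.from_profiles(
            [PhyloProfile("a", {"A": 1, "B": 0, "C": 2}),
             PhyloProfile("b", {"A": 2, "B": 2, "C": 1}),
             PhyloProfile("c", {"A": 0, "B": 1, "C": 0})],
            tree.leaf_names)

    def _params(self, tree):
        nb = tree.n_branches
        return ModelParams(ModelSpec.constant(), t_b=np.ones(nb),
                           lam_b=np.full(nb, 0.3), mu_b=np.full(nb, 0.8),
                           kap_b=np.full(nb, 0.2), phi=1.0)

    def test_single_family_dataset(self, tree3):
        params = self._params(tree3)
        data = ProfileSet.from_profiles(
            [PhyloProfile("a", {"A": 1, "B": 0, "C": 2})], tree3.leaf_names)
        got = dataset_loglik(tree3, params, data)
        ref = family_mixture_loglik(tree3, params, data[0])
        assert got == pytest.approx(ref, rel=1e-9)

    def test_duplication_doubles(self, tree3):
        params = self._params(tree3)
        data = self._toy(tree3)
        doubled = ProfileSet.from_profiles(
            list(data) + [PhyloProfile(p.family_id + "_dup", p.counts)
                          for p in data],
            tree3.leaf_names)
        assert dataset_loglik(tree3, params, doubled) == pytest.approx(
            2 * dataset_loglik(tree3, params, data), rel=1e-12)

    def test_order_invariant_to_the_last_bit(self, tree3):
        params = self._params(tree3)
        data = self._toy(tree3)
        perm = ProfileSet.from_profiles([data[2], data[0], data[1]],
                                        tree3.leaf_names)
        assert dataset_loglik(tree3, params, data) == \
            dataset_loglik(tree3, params, perm)


class TestEngineRobustness:
    def test_bound_doubles_on_tail_overflow(self, tree2):
        """Hot parameters push mass past a small initial bound; the engine
        must grow the bound rather than return a biased value."""
        engine = PruningEngine(tree2, ascertainment=False, max_bound=256)
        nb = tree2.n_branches
        params = ModelParams(ModelSpec.constant(), t_b=np.ones(nb),
                             lam_b=np.full(nb, 1.5), mu_b=np.full(nb, 0.1),
                             kap_b=np.full(nb, 1.0), phi=3.0)
        counts = np.array([[4, 6]])
        ll_small = engine.family_logliks(params, counts, m=16)
        ll_large = engine.family_logliks(params, counts, m=256)
        assert np.isfinite(ll_small[0])
        assert ll_small[0] == pytest.approx(ll_large[0], abs=1e-6)
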