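"""Branching-process combinatorics: genealogies, profiles, estimation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wgdtriplets as w
from wgdtriplets.branching import (
    TrajectoryCounts,
    _closed_gene_count,
    _closed_pair_counts,
)


def params_for(schedule, rates, squared=True):
    return w.SurvivalParams.from_rates(schedule, rates, squared=squared)


class TestValidation:
    def test_ploidy_outside_2_3_rejected(self):
        with pytest.raises(ValueError, match="ploidy 4"):
            w.EventSchedule((4,))
        with pytest.raises(ValueError):
            w.EventSchedule(())

    def test_params_must_match_schedule(self):
        p = params_for((2, 2), (0.5, 0.5))
        with pytest.raises(ValueError):
            p.validate_for(w.EventSchedule((3, 2)))
        with pytest.raises(ValueError):
            p.validate_for(w.EventSchedule((2,)))

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            w.SurvivalParams(((0.5, 0.4),))

    def test_squared_constraint_needs_room_for_p1(self):
        # u + u^2 > 1 leaves p1 < 0
        with pytest.raises(ValueError):
            params_for((3,), (0.9,))


class TestEnumeration:
    def test_single_doubling(self):
        gs = w.enumerate_genealogies((2,), params_for((2,), (0.5,)))
        assert len(gs) == 2
        assert sorted(g.n_leaves for g in gs) == [1, 2]
        assert all(g.weight == 0.5 for g in gs)

    def test_deterministic_tripling(self):
        p = w.SurvivalParams(((0.0, 0.0, 1.0),))
        gs = w.enumerate_genealogies((3,), p)
        assert len(gs) == 1
        assert gs[0].weight == 1.0 and gs[0].n_leaves == 3

    def test_two_doublings_weights_and_mean(self):
        p = params_for((2, 2), (0.5, 0.5))
        gs = w.enumerate_genealogies((2, 2), p)
        assert sum(g.weight for g in gs) == pytest.approx(1.0, abs=1e-12)
        mean = sum(g.weight * g.n_leaves for g in gs)
        assert mean == pytest.approx(2.25, abs=1e-12)

    def test_cap_enforced(self):
        sched = (2,) * 5
        with pytest.raises(ValueError, match="cap"):
            w.enumerate_genealogies(sched, params_for(sched, (0.5,) * 5))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        ploidies=st.lists(st.sampled_from([2, 3]), min_size=1, max_size=3),
        seed=st.integers(0, 10_000),
    )
    def test_weights_sum_to_one(self, ploidies, seed):
        rng = np.random.default_rng(seed)
        rates = rng.uniform(0.05, 0.6, len(ploidies))
        p = params_for(ploidies, rates)
        gs = w.enumerate_genealogies(ploidies, p)
        assert sum(g.weight for g in gs) == pytest.approx(1.0, abs=1e-12)


class TestTrajectoryProbability:
    def test_single_event_cases(self):
        p = params_for((2,), (0.5,))
        assert w.trajectory_probability((2,), p, TrajectoryCounts(((1, 0),))) == 0.5
        both = [TrajectoryCounts(((1, 0),)), TrajectoryCounts(((0, 1),))]
        assert sum(w.trajectory_probability((2,), p, c) for c in both) == 1.0

    def test_two_event_multinomial(self):
        p = params_for((2, 2), (0.5, 0.5))
        counts = TrajectoryCounts(((0, 1), (0, 2)))
        assert w.trajectory_probability((2, 2), p, counts) == pytest.approx(0.125)

    def test_inconsistent_counts_rejected(self):
        p = params_for((2, 2), (0.5, 0.5))
        with pytest.raises(ValueError):
            # m_2 = 2 but second event rows only cover one gene
            w.trajectory_probability((2, 2), p, TrajectoryCounts(((0, 1), (1, 0))))

    def test_matches_aggregated_genealogies(self):
        """Eq.-2 trajectory probabilities equal summed genealogy weights."""
        p = params_for((3, 2), (0.4, 0.3))
        agg = {}
        for g in w.enumerate_genealogies((3, 2), p):
            key = g.trajectory_counts().a
            agg[key] = agg.get(key, 0.0) + g.weight
        for a, weight in agg.items():
            direct = w.trajectory_probability((3, 2), p, TrajectoryCounts(a))
            assert direct == pytest.approx(weight, abs=1e-12)


class TestExpectedCounts:
    def test_gene_count_examples(self):
        assert w.expected_gene_count(
            (3,), w.SurvivalParams(((0.0, 0.0, 1.0),))
        ) == pytest.approx(3.0)
        assert w.expected_gene_count((2,), params_for((2,), (0.0,))) == 1.0
        assert w.expected_gene_count(
            (2, 2), params_for((2, 2), (0.5, 0.5))
        ) == pytest.approx(2.25, abs=1e-12)

    @pytest.mark.parametrize("ploidies", [(2, 2), (3, 2), (2, 3), (3, 3)])
    def test_gene_count_equals_growth_product(self, ploidies):
        p = params_for(ploidies, (0.35, 0.25))
        product = math.prod(p.growth_factor(e) for e in (1, 2))
        assert w.expected_gene_count(ploidies, p) == pytest.approx(product, abs=1e-12)

    def test_pair_count_examples(self):
        p = params_for((2, 2), (0.5, 0.5))
        pairs = w.expected_pair_counts((2, 2), p)
        assert pairs[1] == pytest.approx(1.125)  # u (1+v)^2
        assert pairs[2] == pytest.approx(0.75)   # (1+u) v
        assert w.expected_pair_counts((2,), params_for((2,), (0.0,)))[1] == 0.0
        assert w.expected_pair_counts(
            (3,), w.SurvivalParams(((0.0, 0.0, 1.0),))
        )[1] == pytest.approx(3.0)

    def test_pair_counts_match_closed_form(self):
        for ploidies in [(2, 3), (3, 3, 2)]:
            p = params_for(ploidies, [0.3] * len(ploidies))
            enum = w.expected_pair_counts(ploidies, p)
            closed = _closed_pair_counts(w.EventSchedule(ploidies), p)
            assert np.allclose(list(enum.values()), closed, atol=1e-12)


class TestClassifyTriplet:
    @pytest.fixture()
    def nine_leaf_tree(self):
        p = w.SurvivalParams(((0.0, 0.0, 1.0), (0.0, 0.0, 1.0)))
        (g,) = w.enumerate_genealogies((3, 3), p)
        return g

    def test_same_lineage_triple(self, nine_leaf_tree):
        leaves = [(0, 0), (0, 1), (0, 2)]
        assert w.classify_triplet(nine_leaf_tree, leaves) == (2, 2, 2)

    def test_three_lineages(self, nine_leaf_tree):
        assert w.classify_triplet(
            nine_leaf_tree, [(0, 0), (1, 0), (2, 0)]
        ) == (1, 1, 1)

    def test_mixed(self, nine_leaf_tree):
        assert w.classify_triplet(
            nine_leaf_tree, [(0, 0), (0, 1), (1, 2)]
        ) == (1, 1, 2)

    def test_bad_leaves_rejected(self, nine_leaf_tree):
        with pytest.raises(ValueError):
            w.classify_triplet(nine_leaf_tree, [(0, 0), (0, 0), (1, 0)])
        with pytest.raises(ValueError):
            w.classify_triplet(nine_leaf_tree, [(0, 0), (0, 1), (9, 9)])


class TestTripletProfiles:
    def test_two_doublings_profile(self):
        p = params_for((2, 2), (0.5, 0.5))
        profile = w.expected_triplet_profile_bruteforce((2, 2), p)
        assert profile.values[(1, 1, 2)] == pytest.approx(0.75)
        for t in [(1, 1, 1), (1, 2, 2), (2, 2, 2)]:
            assert profile.values[t] == 0.0

    def test_deterministic_double_tripling(self):
        p = w.SurvivalParams(((0.0, 0.0, 1.0), (0.0, 0.0, 1.0)))
        profile = w.expected_triplet_profile_bruteforce((3, 3), p)
        assert profile.values == {
            (1, 1, 1): 27.0, (1, 1, 2): 54.0, (1, 2, 2): 0.0, (2, 2, 2): 3.0,
        }
        assert profile.total == 84.0  # C(9, 3)

    def test_profile_agrees_with_leafwise_classification(self):
        """Shape-table expectations equal direct per-genealogy triple counting."""
        p = params_for((3, 2), (0.4, 0.5))
        expected = {t: 0.0 for t in w.triplet_types(2)}
        for g in w.enumerate_genealogies((3, 2), p):
            for triple in itertools.combinations(g.leaves(), 3):
                expected[w.classify_triplet(g, triple)] += g.weight
        profile = w.expected_triplet_profile_bruteforce((3, 2), p)
        for t, val in expected.items():
            assert profile.values[t] == pytest.approx(val, abs=1e-12)

    def test_unrealizable_types_exactly_zero(self):
        rng = np.random.default_rng(7)
        for ploidies in [(2, 3), (3, 3), (3, 2, 3)]:
            rates = rng.uniform(0.05, 0.55, len(ploidies))
            profile = w.expected_triplet_profile_bruteforce(
                ploidies, params_for(ploidies, rates)
            )
            for t, val in profile.values.items():
                if not w.is_realizable(t):
                    assert val == 0.0

    def test_closed_form_restricted_to_two_or_three_events(self):
        with pytest.raises(ValueError, match="closed"):
            w.expected_triplet_profile_closed((2,), params_for((2,), (0.5,)))

    def test_tripling_doubling_dead_term(self):
        # u' = 0 kills the only {t1,t1,t1} term of the tripling-doubling model
        p = w.SurvivalParams(((1.0, 0.0, 0.0), (1.0, 0.0)))
        profile = w.expected_triplet_profile_closed((3, 2), p)
        assert profile.values[(1, 1, 1)] == 0.0


class TestPrintedPolynomials:
    """Frozen transcriptions of the published closed-form cells."""

    def test_two_event_table(self):
        u, v = 0.25, 0.45
        up, vp = u * u, v * v
        p = params_for((3, 3), (u, v))
        got = w.expected_triplet_profile_closed((3, 3), p).values
        assert got[(1, 1, 1)] == pytest.approx(up * (1 + 2 * vp + v) ** 3)
        assert got[(1, 1, 2)] == pytest.approx(
            2 * (3 * up + u) * (3 * vp + v) * (1 + 2 * vp + v)
        )
        assert got[(2, 2, 2)] == pytest.approx((1 + 2 * up + u) * vp)

        p23 = params_for((2, 3), (u, v))
        got23 = w.expected_triplet_profile_closed((2, 3), p23).values
        assert got23[(1, 1, 2)] == pytest.approx(
            2 * u * (3 * vp + v) * (1 + 2 * vp + v)
        )
        assert got23[(2, 2, 2)] == pytest.approx((1 + u) * vp)

        p32 = params_for((3, 2), (u, v))
        got32 = w.expected_triplet_profile_closed((3, 2), p32).values
        assert got32[(1, 1, 1)] == pytest.approx(up * (1 + v) ** 3)
        assert got32[(1, 1, 2)] == pytest.approx(2 * (3 * up + u) * v * (1 + v))

        p22 = params_for((2, 2), (u, v))
        assert w.expected_triplet_profile_closed((2, 2), p22).values[
            (1, 1, 2)
        ] == pytest.approx(2 * u * v * (1 + v))

    def test_three_event_table(self):
        u, v, ww = 0.2, 0.3, 0.4
        up, vp, wp = u * u, v * v, ww * ww
        p = params_for((3, 2, 3), (u, v, ww))
        got = w.expected_triplet_profile_closed((3, 2, 3), p).values
        assert got[(1, 1, 1)] == pytest.approx(
            up * (1 + v) ** 3 * (1 + 2 * wp + ww) ** 3
        )
        assert got[(1, 1, 3)] == pytest.approx(
            2 * (3 * up + u) * (1 + v) ** 2 * (3 * wp + ww) * (1 + 2 * wp + ww)
        )
        assert got[(2, 2, 3)] == pytest.approx(
            2 * (1 + 2 * up + u) * v * (3 * wp + ww) * (1 + 2 * wp + ww)
        )
        assert got[(3, 3, 3)] == pytest.approx((1 + 2 * up + u) * (1 + v) * wp)

        p232 = params_for((2, 3, 2), (u, v, ww))
        got232 = w.expected_triplet_profile_closed((2, 3, 2), p232).values
        assert got232[(2, 2, 3)] == pytest.approx(
            2 * (1 + u) * (3 * vp + v) * ww * (1 + ww)
        )
        assert got232[(2, 2, 2)] == pytest.approx((1 + u) * vp * (1 + ww) ** 3)

        p222 = params_for((2, 2, 2), (u, v, ww))
        got222 = w.expected_triplet_profile_closed((2, 2, 2), p222).values
        assert got222[(1, 1, 2)] == pytest.approx(
            2 * u * v * (1 + v) * (1 + ww) ** 3
        )
        assert got222[(1, 1, 3)] == pytest.approx(
            2 * u * (1 + v) ** 2 * ww * (1 + ww)
        )


class TestTripletTypeCombinatorics:
    @pytest.mark.parametrize("m,count", [(1, 1), (2, 4), (3, 10), (4, 20)])
    def test_tetrahedral_number_of_types(self, m, count):
        assert len(w.triplet_types(m)) == count
        assert count == m * (m + 1) * (m + 2) // 6

    def test_realizability_rule(self):
        assert w.is_realizable((1, 1, 2))
        assert w.is_realizable((2, 2, 2))
        assert not w.is_realizable((1, 2, 2))
        assert not w.is_realizable((1, 2, 3))
        assert not w.is_realizable((2, 3, 3))


class TestEstimateSurvivalParams:
    def test_exact_inversion(self):
        truth = params_for((2, 2), (0.3, 0.6))
        counts = {e: 1000 * v for e, v in w.expected_pair_counts((2, 2), truth).items()}
        genes = 1000 * w.expected_gene_count((2, 2), truth)
        fit = w.estimate_survival_params((2, 2), counts, genes)
        assert fit.rates == pytest.approx((0.3, 0.6), abs=1e-6)
        assert fit.root_count == pytest.approx(1000, rel=1e-6)

    def test_exact_inversion_tripling(self):
        truth = params_for((3, 3), (0.3, 0.4))
        counts = {e: 2000 * v for e, v in w.expected_pair_counts((3, 3), truth).items()}
        genes = 2000 * w.expected_gene_count((3, 3), truth)
        fit = w.estimate_survival_params((3, 3), counts, genes)
        assert fit.rates == pytest.approx((0.3, 0.4), abs=1e-6)

    def test_simulated_recovery(self):
        config = w.default_config(schedule=(2, 2), rates=(0.3, 0.6),
                                  root_count=10000, seed=42)
        history = w.simulate_history(config)
        fit = w.estimate_survival_params(
            (2, 2), history.pair_event_counts(), history.n_genes
        )
        assert abs(fit.rates[0] - 0.3) < 0.05
        assert abs(fit.rates[1] - 0.6) < 0.05

    def test_zero_recent_pairs_hits_boundary(self):
        truth = params_for((2, 2), (0.4, 0.3))
        counts = w.expected_pair_counts((2, 2), truth)
        counts = {1: 500 * counts[1], 2: 0.0}
        with pytest.warns(UserWarning, match="boundary"):
            fit = w.estimate_survival_params((2, 2), counts, 500 * 1.4)
        assert fit.rates[1] == pytest.approx(0.0, abs=1e-6)

    def test_multinomial_method_agrees(self):
        truth = params_for((3, 2), (0.3, 0.4))
        counts = {e: 5000 * v for e, v in w.expected_pair_counts((3, 2), truth).items()}
        genes = 5000 * w.expected_gene_count((3, 2), truth)
        fit = w.estimate_survival_params((3, 2), counts, genes, method="multinomial")
        assert fit.rates == pytest.approx((0.3, 0.4), abs=1e-4)

    def test_observable_only_corrects_for_hidden_singletons(self):
        truth = params_for((2, 2), (0.3, 0.5))
        g = 1000
        counts = {e: g * v for e, v in w.expected_pair_counts((2, 2), truth).items()}
        observable = g * _closed_gene_count(
            w.EventSchedule((2, 2)), truth, observable_only=True
        )
        fit = w.estimate_survival_params(
            (2, 2), counts, observable, observable_only=True
        )
        assert fit.rates == pytest.approx((0.3, 0.5), abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            w.estimate_survival_params((2, 2), {1: 0.0, 2: 0.0}, 100)
        with pytest.raises(ValueError):
            w.estimate_survival_params((2, 2), {1: 10.0, 2: 5.0}, 0)
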