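"""Network expansion: examples, fixed-point properties, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootscope.netcore import (
    Gem,
    Reaction,
    community_gain_percent,
    community_scope,
    merge,
    scope,
    unconstrained_ppm,
)

from conftest import naive_scope, random_gem, random_seeds


def gem_of(*reactions: Reaction, organism_id: str = "G") -> Gem:
    return Gem(organism_id=organism_id, reactions=tuple(reactions))


class TestUnconstrainedPpm:
    def test_single_irreversible_reaction_counts_only_products(self):
        g = gem_of(Reaction("R1", frozenset({"a"}), frozenset({"b"})))
        assert unconstrained_ppm(g) == {"b"}

    def test_reversible_reaction_contributes_both_sides(self):
        g = gem_of(Reaction("R4", frozenset({"x"}), frozenset({"y"}), reversible=True))
        assert unconstrained_ppm(g) == {"x", "y"}

    def test_empty_reaction_set_gives_empty_potential(self):
        assert unconstrained_ppm(Gem("G", ())) == frozenset()

    def test_matches_naive_product_side_union_on_random_gem(self, rng):
        g = random_gem(rng, n_metabolites=40, n_reactions=50)
        expected = set()
        for rxn in g.reactions:
            expected |= rxn.products
            if rxn.reversible:
                expected |= rxn.reactants
        assert unconstrained_ppm(g) == expected


class TestScopeExamples:
    def test_one_step_chain(self):
        g = gem_of(Reaction("R1", frozenset({"a"}), frozenset({"b"})))
        assert scope(g, {"a"}).producible == {"b"}

    def test_missing_cosubstrate_blocks_and_supplying_it_unblocks(self):
        g = gem_of(
            Reaction("R1", frozenset({"a"}), frozenset({"b"})),
            Reaction("R2", frozenset({"b", "c"}), frozenset({"d"})),
        )
        assert scope(g, {"a"}).producible == {"b"}
        assert scope(g, {"a", "c"}).producible == {"b", "d"}

    def test_reverse_direction_of_reversible_reaction(self):
        g = gem_of(Reaction("R4", frozenset({"x"}), frozenset({"y"}), reversible=True))
        producible = scope(g, {"y"}).producible
        assert "x" in producible
        # Once x is available the forward direction fires too, so the
        # seed y is regenerated and counts as producible.
        assert producible == {"x", "y"}

    def test_unknown_seeds_are_inert(self):
        g = gem_of(Reaction("R1", frozenset({"a"}), frozenset({"b"})))
        assert scope(g, {"nonexistent"}).producible == frozenset()

    def test_seeds_excluded_unless_regenerated(self):
        g = gem_of(Reaction("R1", frozenset({"a"}), frozenset({"a", "b"})))
        res = scope(g, {"a"})
        assert res.producible == {"a", "b"}  # regenerated seed stays
        g2 = gem_of(Reaction("R1", frozenset({"a"}), frozenset({"b"})))
        assert "a" not in scope(g2, {"a"}).producible
        assert "a" in scope(g2, {"a"}, include_seeds=True).producible

    def test_empty_reactant_reaction_fires_unconditionally(self):
        g = gem_of(Reaction("R0", frozenset(), frozenset({"z"})))
        assert scope(g, set()).producible == {"z"}
        assert scope(g, set()).n_iterations == 1


class TestScopeProperties:
    @pytest.mark.parametrize("trial", range(20))
    def test_oracle_equivalence_on_random_networks(self, trial):
        rng = np.random.default_rng(1000 + trial)
        g = random_gem(rng, n_metabolites=100, n_reactions=80)
        seeds = random_seeds(rng, 100, k=6)
        assert scope(g, seeds).producible == naive_scope(g, seeds)

    @pytest.mark.parametrize("trial", range(10))
    def test_fixed_point_one_more_sweep_adds_nothing(self, trial):
        rng = np.random.default_rng(2000 + trial)
        g = random_gem(rng)
        seeds = random_seeds(rng)
        res = scope(g, seeds)
        rerun = scope(g, seeds | res.producible)
        assert rerun.producible | seeds | res.producible == res.producible | seeds

    @pytest.mark.parametrize("trial", range(10))
    def test_seed_monotonicity(self, trial):
        rng = np.random.default_rng(3000 + trial)
        g = random_gem(rng)
        s1 = random_seeds(rng, k=3)
        s2 = s1 | random_seeds(rng, k=3)
        assert scope(g, s1).producible <= scope(g, s2).producible

    @pytest.mark.parametrize("trial", range(10))
    def test_containment_in_unconstrained_potential(self, trial):
        rng = np.random.default_rng(4000 + trial)
        g = random_gem(rng)
        seeds = random_seeds(rng, k=8)
        assert scope(g, seeds).producible <= unconstrained_ppm(g)

    def test_order_independence_under_reaction_shuffling(self, rng):
        g = random_gem(rng, n_reactions=40)
        seeds = random_seeds(rng, k=5)
        reference = scope(g, seeds).producible
        for trial in range(5):
            order = rng.permutation(len(g.reactions))
            shuffled = Gem(
                organism_id=g.organism_id,
                reactions=tuple(g.reactions[i] for i in order),
            )
            assert scope(shuffled, seeds).producible == reference

    def test_iteration_count_bounded_by_direction_count(self, rng):
        g = random_gem(rng, n_reactions=30)
        seeds = random_seeds(rng)
        n_directions = sum(2 if r.reversible else 1 for r in g.reactions)
        assert scope(g, seeds).n_iterations <= n_directions


class TestMerge:
    def test_two_gems_two_reactions(self, t1_community):
        meta = merge(t1_community[:2])
        assert len(meta.reactions) == 2
        assert meta.organism_id == "A+B"

    def test_identical_content_not_deduplicated(self):
        a = gem_of(Reaction("R1", frozenset({"a"}), frozenset({"b"})), organism_id="A")
        c = gem_of(Reaction("R9", frozenset({"a"}), frozenset({"b"})), organism_id="C")
        assert len(merge([a, c]).reactions) == 2

    def test_duplicate_organism_ids_rejected(self, t1_community):
        with pytest.raises(ValueError, match="duplicate organism"):
            merge([t1_community[0], t1_community[0]])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge([])

    @pytest.mark.parametrize("trial", range(10))
    def test_merged_scope_contains_union_of_member_scopes(self, trial):
        rng = np.random.default_rng(5000 + trial)
        x = random_gem(rng, organism_id="X")
        y = random_gem(rng, organism_id="Y")
        seeds = random_seeds(rng, k=5)
        merged = scope(merge([x, y]), seeds).producible
        assert scope(x, seeds).producible | scope(y, seeds).producible <= merged


class TestCommunityScope:
    def test_hand_checkable_three_member_instance(self, t1_community):
        cs = community_scope(t1_community, {"a"})
        assert cs.individual_ppm == {
            "A": frozenset({"b"}),
            "B": frozenset(),
            "C": frozenset({"b"}),
        }
        assert cs.community_ppm == {"b", "c"}
        assert cs.added_value == {"c"}
        assert cs.cppm == frozenset()

    def test_single_member_community_has_no_added_value(self, rng):
        g = random_gem(rng)
        cs = community_scope([g], random_seeds(rng))
        assert cs.added_value == frozenset()

    @pytest.mark.parametrize("trial", range(10))
    def test_added_value_disjoint_from_every_individual_scope(self, trial):
        rng = np.random.default_rng(6000 + trial)
        gems = [random_gem(rng, organism_id=f"G{i}") for i in range(6)]
        cs = community_scope(gems, random_seeds(rng, k=5))
        for ppm in cs.individual_ppm.values():
            assert not (cs.added_value & ppm)

    @pytest.mark.parametrize("trial", range(10))
    def test_member_monotonicity(self, trial):
        rng = np.random.default_rng(7000 + trial)
        gems = [random_gem(rng, organism_id=f"G{i}") for i in range(5)]
        seeds = random_seeds(rng, k=5)
        smaller = community_scope(gems[:4], seeds).community_ppm
        bigger = community_scope(gems, seeds).community_ppm
        assert smaller <= bigger

    def test_invariant_relations_hold(self, t1_community):
        cs = community_scope(t1_community, {"a"})
        union = frozenset().union(*cs.individual_ppm.values())
        assert cs.added_value == cs.community_ppm - union
        assert cs.cppm == frozenset.intersection(*cs.individual_ppm.values())
        assert union <= cs.community_ppm


class TestCommunityGain:
    def test_hand_checkable_gain_is_100_percent(self, t1_community):
        cs = community_scope(t1_community, {"a"})
        assert community_gain_percent(cs) == 100.0

    def test_no_added_value_means_zero_gain(self, t1_community):
        cs = community_scope(t1_community[:1], {"a"})
        assert community_gain_percent(cs) == 0.0

    def test_empty_union_is_an_explicit_error(self, t1_community):
        cs = community_scope(t1_community, {"zzz"})
        with pytest.raises(ValueError, match="undefined"):
            community_gain_percent(cs)

    def test_gain_recomputed_from_set_sizes(self, rng):
        gems = [random_gem(rng, organism_id=f"G{i}") for i in range(4)]
        seeds = random_seeds(rng, k=6)
        cs = community_scope(gems, seeds)
        union = frozenset().union(*cs.individual_ppm.values())
        if union:
            expected = 100.0 * len(cs.added_value) / len(union)
            assert community_gain_percent(cs) == pytest.approx(expected)


class TestValidation:
    def test_reaction_without_products_rejected(self):
        with pytest.raises(ValueError, match="no products"):
            Reaction("R1", frozenset({"a"}), frozenset())

    def test_blank_ids_rejected(self):
        with pytest.raises(ValueError):
            Reaction("  ", frozenset({"a"}), frozenset({"b"}))
        with pytest.raises(ValueError):
            Gem("", ())

    def test_duplicate_reaction_ids_rejected(self):
        r = Reaction("R1", frozenset({"a"}), frozenset({"b"}))
        with pytest.raises(ValueError, match="duplicate reaction"):
            Gem("G", (r, r))


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_scope_equals_oracle_for_hypothesis_seeds(instance_seed):
    """Property: expansion equals the naive oracle on arbitrary networks."""
    rng = np.random.default_rng(instance_seed)
    g = random_gem(rng, n_metabolites=25, n_reactions=25)
    seeds = random_seeds(rng, 25, k=4)
    assert scope(g, seeds).producible == naive_scope(g, seeds)
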