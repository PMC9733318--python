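"""Shared fixtures and independent oracles.

The oracles here re-derive producibility by deliberately different code
paths than the package (single-pass saturation over the final available
set, exhaustive subset enumeration) so that agreement is evidence, not
tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from rootscope.netcore import Gem, Reaction


# ---------------------------------------------------------------------------
# Independent oracles


def naive_scope(gem: Gem, seeds) -> frozenset:
    """Brute-force fixed point, coded independently of rootscope.scope.

    Saturate the available set by repeated full passes, then report the
    union of products of every direction enabled at the fixed point
    (availability is monotone, so a direction fires iff its reactants
    are contained in the final available set).
    """
    directions = []
    for rxn in gem.reactions:
        directions.append((set(rxn.reactants), set(rxn.products)))
        if rxn.reversible:
            directions.append((set(rxn.products), set(rxn.reactants)))
    available = set(seeds)
    while True:
        new = set(available)
        for reactants, products in directions:
            if reactants <= available:
                new |= products
        if new == available:
            break
        available = new
    produced = set()
    for reactants, products in directions:
        if reactants <= available:
            produced |= products
    return frozenset(produced)


def exhaustive_minimal_solutions(gems, seeds, achievable):
    """All smallest subsets covering ``achievable``, by full enumeration."""
    from rootscope.netcore import merge, scope

    for k in range(1, len(gems) + 1):
        found = []
        for combo in itertools.combinations(gems, k):
            covered = scope(merge(list(combo)), seeds).producible
            if achievable <= covered:
                found.append(tuple(sorted(g.organism_id for g in combo)))
        if found:
            return k, sorted(found)
    return None, []


# ---------------------------------------------------------------------------
# Random instance generators (unstructured, unlike rootscope.synthetic)


def random_gem(
    rng: np.random.Generator,
    organism_id: str = "G",
    n_metabolites: int = 30,
    n_reactions: int = 20,
    reversible_prob: float = 0.2,
) -> Gem:
    """Arbitrary random network: cycles, overlaps and all."""
    mets = [f"m{i}" for i in range(n_metabolites)]
    reactions = []
    for r in range(n_reactions):
        n_sub = int(rng.integers(1, 4))
        n_prod = int(rng.integers(1, 3))
        reactants = frozenset(rng.choice(mets, size=n_sub, replace=False))
        products = frozenset(rng.choice(mets, size=n_prod, replace=False))
        reactions.append(
            Reaction(
                id=f"r{r}",
                reactants=reactants,
                products=products,
                reversible=bool(rng.random() < reversible_prob),
            )
        )
    return Gem(organism_id=organism_id, reactions=tuple(reactions))


def random_seeds(rng: np.random.Generator, n_metabolites: int = 30, k: int = 4):
    mets = [f"m{i}" for i in range(n_metabolites)]
    return frozenset(rng.choice(mets, size=min(k, len(mets)), replace=False))


# ---------------------------------------------------------------------------
# The hand-checkable three-member community


@pytest.fixture
def t1_community():
    """A{a->b}, B{b->c}, C{a->b}: with seeds {a}, c needs cooperation."""
    gem_a = Gem("A", (Reaction("R1", frozenset({"a"}), frozenset({"b"})),))
    gem_b = Gem("B", (Reaction("R2", frozenset({"b"}), frozenset({"c"})),))
    gem_c = Gem("C", (Reaction("R3", frozenset({"a"}), frozenset({"b"})),))
    return [gem_a, gem_b, gem_c]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
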