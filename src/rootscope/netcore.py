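"""Directed metabolic networks and reachability-based producibility.

A genome-scale metabolic model (GEM) is represented qualitatively: each
reaction is a pair of metabolite *sets* (reactants, products), optionally
reversible.  Stoichiometric coefficients are deliberately ignored — the
question asked of a draft network is *whether* a compound can be made at
all, not at what flux.

The central primitive is **network expansion** (the "scope"): starting
from a seed set of nutrient metabolites, a reaction direction fires once
every one of its reactants is available, its products become available in
turn, and iteration continues to the least fixed point.  The producible
set of a GEM under a growth medium is exactly this fixed point.  Merging
several GEMs into a meta-GEM — unrestricted metabolite exchange between
members — is the union of their reaction repertoires, and the *community
added value* is whatever the merged network can reach that no member can
reach alone.

Conventions:

* a reversible reaction is treated as two independent directed reactions;
* a reaction with no reactants fires unconditionally at the first sweep
  (this models spontaneous/exchange inputs; generators avoid emitting
  such reactions unless intended);
* metabolite identifiers are compared verbatim — compartment suffixes
  are never stripped, since cross-organism exchange presumes one shared
  namespace and silent munging would corrupt community scopes;
* the returned producible set excludes the seeds themselves unless a
  fired reaction regenerates them (``include_seeds=True`` overrides).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

__all__ = [
    "Metabolite",
    "Reaction",
    "Gem",
    "ScopeResult",
    "CommunityScope",
    "unconstrained_ppm",
    "scope",
    "merge",
    "community_scope",
    "community_gain_percent",
]


def _check_id(value: str, what: str) -> None:
    if not isinstance(value, str) or not value.strip():
        raise ValueError(f"{what} must be a non-empty identifier, got {value!r}")


@dataclass(frozen=True)
class Metabolite:
    """A compound, identified by a MetaCyc-style (or synthetic) id."""

    id: str
    name: Optional[str] = None

    def __post_init__(self) -> None:
        _check_id(self.id, "metabolite id")


@dataclass(frozen=True)
class Reaction:
    """One directed (or reversible) conversion between metabolite sets.

    ``reactants`` may be empty (an unconditional source); ``products``
    may not.  Reactants and products may overlap (autocatalysis).
    """

    id: str
    reactants: FrozenSet[str]
    products: FrozenSet[str]
    reversible: bool = False

    def __post_init__(self) -> None:
        _check_id(self.id, "reaction id")
        object.__setattr__(self, "reactants", frozenset(self.reactants))
        object.__setattr__(self, "products", frozenset(self.products))
        if not self.products:
            raise ValueError(f"reaction {self.id!r} has no products")

    def directions(self) -> Tuple[Tuple[FrozenSet[str], FrozenSet[str]], ...]:
        """Allowed (reactants, products) pairs; two for a reversible reaction."""
        if self.reversible:
            return ((self.reactants, self.products), (self.products, self.reactants))
        return ((self.reactants, self.products),)


@dataclass(frozen=True)
class Gem:
    """An organism's reaction repertoire (a draft genome-scale model)."""

    organism_id: str
    reactions: Tuple[Reaction, ...]
    genome_size_bp: Optional[int] = None
    taxonomy: Optional[Tuple[str, str]] = None  # (phylum, class)

    def __post_init__(self) -> None:
        _check_id(self.organism_id, "organism id")
        object.__setattr__(self, "reactions", tuple(self.reactions))
        seen = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ValueError(
                    f"duplicate reaction id {rxn.id!r} in gem {self.organism_id!r}"
                )
            seen.add(rxn.id)
        if self.genome_size_bp is not None and self.genome_size_bp < 0:
            raise ValueError("genome_size_bp must be non-negative")

    def directions(self) -> list[Tuple[FrozenSet[str], FrozenSet[str]]]:
        dirs: list[Tuple[FrozenSet[str], FrozenSet[str]]] = []
        for rxn in self.reactions:
            dirs.extend(rxn.directions())
        return dirs

    @property
    def metabolites(self) -> FrozenSet[str]:
        ids: set[str] = set()
        for rxn in self.reactions:
            ids |= rxn.reactants | rxn.products
        return frozenset(ids)


@dataclass(frozen=True)
class ScopeResult:
    """A fixed point of network expansion from ``seeds``.

    ``n_iterations`` counts synchronous expansion sweeps; it never
    exceeds the number of reaction directions considered, since every
    counted sweep fires at least one previously unfired direction.
    """

    seeds: FrozenSet[str]
    producible: FrozenSet[str]
    n_iterations: int

    def to_dict(self) -> dict:
        return {
            "seeds": sorted(self.seeds),
            "producible": sorted(self.producible),
            "n_iterations": self.n_iterations,
        }


@dataclass(frozen=True)
class CommunityScope:
    """Community-level producibility and the Table-1 style derived sets.

    * ``community_ppm``   — scope of the merged meta-GEM;
    * ``individual_ppm``  — scope of each member alone, same seeds;
    * ``added_value``     — community_ppm minus the union of individual
      scopes: compounds reachable only through exchange;
    * ``cppm``            — the core: compounds every member can make
      individually.
    """

    community_ppm: FrozenSet[str]
    individual_ppm: Mapping[str, FrozenSet[str]]
    added_value: FrozenSet[str]
    cppm: FrozenSet[str]

    def to_dict(self) -> dict:
        return {
            "community_ppm": sorted(self.community_ppm),
            "individual_ppm": {
                org: sorted(ppm) for org, ppm in sorted(self.individual_ppm.items())
            },
            "added_value": sorted(self.added_value),
            "cppm": sorted(self.cppm),
        }


def unconstrained_ppm(gem: Gem) -> FrozenSet[str]:
    """Every metabolite on the product side of at least one allowed direction.

    This is the constraint-free metabolic potential: all compounds the
    repertoire could conceivably emit, ignoring nutrient availability.
    Both sides of a reversible reaction qualify.
    """
    out: set[str] = set()
    for _reactants, products in gem.directions():
        out |= products
    return frozenset(out)


def scope(
    gem: Gem, seeds: Iterable[str], *, include_seeds: bool = False
) -> ScopeResult:
    """Least fixed point of network expansion from ``seeds``.

    Sweeps are synchronous: every direction whose reactants are all
    available fires, the union of fired products is added, and the
    process repeats until no pending direction can fire.  Unknown seed
    ids are permitted and simply inert.  The result is monotone in the
    seed set and independent of reaction iteration order.
    """
    seeds = frozenset(seeds)
    available = set(seeds)
    produced: set[str] = set()
    pending = gem.directions()
    n_iterations = 0
    while pending:
        fired_products: set[str] = set()
        still_pending = []
        for reactants, products in pending:
            if reactants <= available:
                fired_products |= products
            else:
                still_pending.append((reactants, products))
        if len(still_pending) == len(pending):
            break  # nothing fired: fixed point
        n_iterations += 1
        produced |= fired_products
        available |= fired_products
        pending = still_pending
    producible = frozenset(produced | seeds) if include_seeds else frozenset(produced)
    return ScopeResult(seeds=seeds, producible=producible, n_iterations=n_iterations)


def merge(gems: Sequence[Gem]) -> Gem:
    """Union of member repertoires: the meta-GEM with free exchange.

    Reaction ids are prefixed with the owning organism id, so identical
    reaction content carried by two members is retained twice (no
    content deduplication — membership bookkeeping matters downstream).
    The merged organism id is the sorted join of member ids.
    """
    if not gems:
        raise ValueError("merge requires at least one gem")
    ids = [g.organism_id for g in gems]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate organism ids in community: {dupes}")
    reactions = []
    for gem in sorted(gems, key=lambda g: g.organism_id):
        for rxn in gem.reactions:
            reactions.append(
                Reaction(
                    id=f"{gem.organism_id}__{rxn.id}",
                    reactants=rxn.reactants,
                    products=rxn.products,
                    reversible=rxn.reversible,
                )
            )
    return Gem(organism_id="+".join(sorted(ids)), reactions=tuple(reactions))


def community_scope(
    gems: Sequence[Gem], seeds: Iterable[str], *, include_seeds: bool = False
) -> CommunityScope:
    """Scope of the merged community plus each member alone, same seeds."""
    seeds = frozenset(seeds)
    meta = merge(gems)
    community_ppm = scope(meta, seeds, include_seeds=include_seeds).producible
    individual = {
        g.organism_id: scope(g, seeds, include_seeds=include_seeds).producible
        for g in gems
    }
    union_individual: FrozenSet[str] = frozenset().union(*individual.values())
    cppm = frozenset.intersection(*individual.values())
    added_value = community_ppm - union_individual
    return CommunityScope(
        community_ppm=community_ppm,
        individual_ppm=individual,
        added_value=added_value,
        cppm=cppm,
    )


def community_gain_percent(cs: CommunityScope) -> float:
    """Added value as a percentage of what members produce without exchange.

    100 * |added_value| / |union of individual scopes|.  Undefined when
    no member produces anything — raised explicitly rather than
    silently returning zero.
    """
    union_individual: FrozenSet[str] = frozenset().union(*cs.individual_ppm.values())
    if not union_individual:
        raise ValueError(
            "community gain is undefined: no member produces any metabolite"
        )
    return 100.0 * len(cs.added_value) / len(union_individual)
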