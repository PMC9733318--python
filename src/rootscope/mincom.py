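"""Exact enumeration of minimum-cardinality cooperating communities.

Given a community of GEMs, a growth medium (seed set) and a set of
target compounds, first determine the maximal achievable coverage T* —
the targets the *whole* community can produce cooperatively — then find
every smallest subset of members whose merged scope still covers T*.
Larger covering subsets are deliberately ignored: the object of interest
is the simplest consortium, and the multiplicity of distinct minimal
solutions measures community-level functional redundancy.

The search is iterative deepening over subset size with a sound pruning
step (members provably unable to contribute any non-seed metabolite in
any context are dropped) and an explicit combinatorial budget: when the
budget is exhausted the result carries a truncation flag rather than a
silently partial answer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .netcore import Gem, community_scope, merge, scope

__all__ = [
    "MincomProblem",
    "MincomResult",
    "max_coverage",
    "minimal_communities",
    "classify_targets",
    "gem_frequencies",
]


@dataclass(frozen=True)
class MincomProblem:
    """A minimal-community query: who jointly covers the targets?"""

    community: Tuple[Gem, ...]
    seeds: FrozenSet[str]
    targets: FrozenSet[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "community", tuple(self.community))
        object.__setattr__(self, "seeds", frozenset(self.seeds))
        object.__setattr__(self, "targets", frozenset(self.targets))
        if not self.community:
            raise ValueError("mincom problem needs at least one gem")
        if not self.targets:
            raise ValueError("mincom problem needs at least one target")
        clash = self.targets & self.seeds
        if clash:
            raise ValueError(
                f"targets present in the seed set (no-target-in-media rule): "
                f"{sorted(clash)}"
            )


@dataclass
class MincomResult:
    """All minimum-cardinality solutions and their bookkeeping.

    ``achievable`` is T*, the coverage of the full community;
    ``min_size`` the smallest subset cardinality reaching T* (None when
    nothing is achievable); ``solutions`` every subset of that size, as
    sorted organism-id tuples in lexicographic order; ``tiers`` labels
    each target individual / cooperative / unproducible; ``truncated``
    flags a search cut short by the subset budget.
    """

    achievable: FrozenSet[str]
    unproducible: FrozenSet[str]
    min_size: Optional[int]
    solutions: List[Tuple[str, ...]]
    gem_frequency: Dict[str, int]
    tiers: Dict[str, str]
    truncated: bool = False

    def to_dict(self) -> dict:
        return {
            "achievable": sorted(self.achievable),
            "unproducible": sorted(self.unproducible),
            "min_size": self.min_size,
            "solutions": [list(s) for s in self.solutions],
            "frequencies": dict(sorted(self.gem_frequency.items())),
            "tiers": dict(sorted(self.tiers.items())),
            "truncated": self.truncated,
        }


def max_coverage(problem: MincomProblem) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    """Targets the full community covers cooperatively, and the rest."""
    cs = community_scope(list(problem.community), problem.seeds)
    achievable = problem.targets & cs.community_ppm
    return achievable, problem.targets - achievable


def _expand_directions(directions, seeds, stop_when=None):
    """Fixed-point expansion over raw (reactants, products) pairs.

    Same semantics as :func:`rootscope.netcore.scope` on the merged
    network (reaction-id prefixes never affect the reachable set), but
    without constructing merged Gem objects, and with an optional early
    exit once ``stop_when`` is covered — the enumeration only needs a
    yes/no coverage answer per subset.
    """
    available = set(seeds)
    produced: set = set()
    pending = directions
    while pending:
        fired: set = set()
        still = []
        for reactants, products in pending:
            if reactants <= available:
                fired |= products
            else:
                still.append((reactants, products))
        if len(still) == len(pending):
            break
        produced |= fired
        available |= fired
        if stop_when is not None and stop_when <= produced:
            break
        pending = still
    return produced


def _relevant_members(problem: MincomProblem) -> List[Gem]:
    """Sound pruning: drop members that cannot contribute anything.

    A member is droppable when every reaction direction it carries
    either can never fire even with the whole community's scope
    available (so, by seed monotonicity, in no subset either), or
    produces only metabolites already in the seed set.  Such a member
    adds no metabolite to any subset's scope, so removing it from any
    solution preserves coverage — no true solution is lost.
    """
    full = scope(merge(list(problem.community)), problem.seeds).producible
    ceiling = full | problem.seeds
    relevant = []
    for gem in problem.community:
        for reactants, products in gem.directions():
            if reactants <= ceiling and (products - problem.seeds):
                relevant.append(gem)
                break
    return relevant


def minimal_communities(
    problem: MincomProblem, *, max_subsets: int = 2_000_000
) -> MincomResult:
    """Enumerate every smallest member subset covering the achievable targets.

    Iterative deepening on subset size k = 1, 2, ...: all size-k subsets
    of the (pruned) community are tested for coverage via their merged
    scope; the first k with at least one covering subset wins and *all*
    covering subsets of that size are returned, in lexicographic order
    of sorted organism ids.  ``max_subsets`` bounds the total number of
    subsets examined; exceeding it yields ``truncated=True`` with
    whatever was proven so far.
    """
    achievable, unproducible = max_coverage(problem)
    gems_by_id = {g.organism_id: g for g in problem.community}
    if not achievable:
        result = MincomResult(
            achievable=achievable,
            unproducible=unproducible,
            min_size=None,
            solutions=[],
            gem_frequency={},
            tiers={},
        )
        result.tiers = classify_targets(problem, result)
        return result

    candidates = sorted(_relevant_members(problem), key=lambda g: g.organism_id)
    directions = {g.organism_id: g.directions() for g in candidates}
    examined = 0
    truncated = False
    solutions: List[Tuple[str, ...]] = []
    min_size: Optional[int] = None
    for k in range(1, len(candidates) + 1):
        found: List[Tuple[str, ...]] = []
        for combo in itertools.combinations(candidates, k):
            examined += 1
            if examined > max_subsets:
                truncated = True
                break
            pooled = [d for g in combo for d in directions[g.organism_id]]
            covered = _expand_directions(pooled, problem.seeds,
                                         stop_when=achievable)
            if achievable <= covered:
                found.append(tuple(sorted(g.organism_id for g in combo)))
        if found:
            min_size = k
            solutions = sorted(found)
            break
        if truncated:
            break

    frequency: Dict[str, int] = {}
    for sol in solutions:
        for org in sol:
            frequency[org] = frequency.get(org, 0) + 1
    result = MincomResult(
        achievable=achievable,
        unproducible=unproducible,
        min_size=min_size,
        solutions=solutions,
        gem_frequency=frequency,
        tiers={},
        truncated=truncated,
    )
    result.tiers = classify_targets(problem, result)
    return result


def classify_targets(problem: MincomProblem, result: MincomResult) -> Dict[str, str]:
    """Tier each target: individual, cooperative, or unproducible.

    *individual* — some single member's own scope contains it;
    *cooperative* — only the merged community reaches it (an added-value
    compound); *unproducible* — out of reach even cooperatively.
    """
    individual_union: Set[str] = set()
    for gem in problem.community:
        individual_union |= scope(gem, problem.seeds).producible
    tiers: Dict[str, str] = {}
    for target in problem.targets:
        if target in individual_union:
            tiers[target] = "individual"
        elif target in result.achievable:
            tiers[target] = "cooperative"
        else:
            tiers[target] = "unproducible"
    return tiers


def gem_frequencies(result: MincomResult, *, top: Optional[int] = None) -> pd.DataFrame:
    """Occurrence counts of members across all minimal solutions.

    Sorted by descending count, ties broken by organism id; counts sum
    to min_size x number of solutions.  ``top`` slices the head.
    """
    if not result.solutions:
        raise ValueError("no solutions to tabulate")
    rows = sorted(result.gem_frequency.items(), key=lambda kv: (-kv[1], kv[0]))
    if top is not None:
        rows = rows[:top]
    return pd.DataFrame(rows, columns=["organism_id", "count"])
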