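"""Synthetic communities with the statistical structure the analysis assumes.

The generator emulates a root-microbiome culture collection at desk
scale: a random coalescent phylogeny; an ancestral reaction pool from
which each organism inherits its repertoire, with accessory reactions
lost along branches so that repertoire similarity decays with
phylogenetic distance; a shared core immune to loss; private reactions
per organism; genome sizes proportional to repertoire size plus noise;
and a mineral-like poor growth medium.

The reaction pool is *layered*: metabolites are ordered, every
reaction's reactants sit strictly below its products, and the lowest
layer is the mineral seed set.  This makes biosynthesis proceed in
chains from the medium, so scopes are non-trivial, constrained scopes
respond to the medium, and planted cross-feeding has room to act.

All randomness flows from a single seed through one numpy generator; no
global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .media import MediaRegistry, Medium
from .netcore import Gem, Reaction, unconstrained_ppm
from .syncom import PhyloTree
from .targets import TargetSet

__all__ = [
    "GeneratorParams",
    "SyntheticCommunity",
    "make_community",
    "plant_split_pathway",
    "make_media_suite",
    "make_target_set",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the community generator.

    ``reactions_per_gem`` is (mean, dispersion): the mean sets the
    ancestral pool size so an average organism retains about that many
    reactions; the dispersion is the standard deviation of the private
    (organism-specific) reaction count, spreading repertoire sizes.
    ``phylo_decay`` is the per-branch-length loss rate of accessory
    reactions; 0 makes every organism identical to the ancestor.
    ``precursor_bias`` sets how strongly reaction substrates concentrate
    on the low (precursor) layers of the metabolite ordering, as the
    e-folding fraction of the universe: small values mimic the funneling
    of biosynthesis through a handful of central precursors and keep
    mineral-seeded scopes deep.
    """

    n_metabolites: int = 300
    n_gems: int = 20
    reactions_per_gem: Tuple[float, float] = (60.0, 6.0)
    reactants_per_reaction: Tuple[int, int] = (1, 3)
    reversibility_prob: float = 0.1
    shared_core_fraction: float = 0.3
    phylo_decay: float = 0.5
    n_minerals: int = 8
    precursor_bias: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_metabolites <= self.n_minerals:
            raise ValueError("metabolite universe smaller than the mineral layer")
        if self.n_gems < 1:
            raise ValueError("need at least one organism")
        for p in (self.reversibility_prob, self.shared_core_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.phylo_decay < 0:
            raise ValueError("phylo_decay must be non-negative")
        if self.reactions_per_gem[0] <= 0:
            raise ValueError("mean reactions per gem must be positive")


@dataclass
class SyntheticCommunity:
    """A generated instance: organisms, phylogeny and the base medium."""

    gems: List[Gem]
    tree: PhyloTree
    medium: Medium
    universe: Tuple[str, ...]
    minerals: FrozenSet[str]

    def __iter__(self):
        # Allows (gems, tree, medium) = make_community(params)
        return iter((self.gems, self.tree, self.medium))


# ---------------------------------------------------------------------------
# Tree simulation (simple Kingman-style coalescent)


class _Node:
    __slots__ = ("label", "children", "lengths", "height")

    def __init__(self, label=None, height=0.0):
        self.label = label
        self.children: List["_Node"] = []
        self.lengths: List[float] = []
        self.height = height

    def newick(self) -> str:
        if not self.children:
            return self.label
        parts = [
            f"{child.newick()}:{length:.6f}"
            for child, length in zip(self.children, self.lengths)
        ]
        return "(" + ",".join(parts) + ")"


def _coalescent_tree(labels: Sequence[str], rng: np.random.Generator) -> _Node:
    nodes = [_Node(label=l) for l in labels]
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(scale=1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = _Node(height=height)
        for child in (nodes[i], nodes[j]):
            parent.children.append(child)
            parent.lengths.append(height - child.height)
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    return nodes[0]


# ---------------------------------------------------------------------------
# Layered reaction sampling


def _metabolite_ids(n: int) -> Tuple[str, ...]:
    width = max(4, len(str(n)))
    return tuple(f"M{i:0{width}d}" for i in range(1, n + 1))


def _sample_reaction(
    rid: str,
    universe: Sequence[str],
    n_minerals: int,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> Reaction:
    n = len(universe)
    n_products = 1 if rng.random() < 0.7 else 2
    product_idx = rng.choice(np.arange(n_minerals, n), size=n_products, replace=False)
    floor = int(product_idx.min())
    lo, hi = params.reactants_per_reaction
    n_reactants = int(rng.integers(lo, hi + 1))
    n_reactants = min(n_reactants, floor)
    idx = np.arange(floor)
    weights = np.exp(-idx / (params.precursor_bias * n))
    weights /= weights.sum()
    reactant_idx = rng.choice(idx, size=n_reactants, replace=False, p=weights)
    return Reaction(
        id=rid,
        reactants=frozenset(universe[i] for i in reactant_idx),
        products=frozenset(universe[i] for i in product_idx),
        reversible=bool(rng.random() < params.reversibility_prob),
    )


# ---------------------------------------------------------------------------
# Community generation


def _leaf_taxonomy(root: _Node) -> Dict[str, Tuple[str, str]]:
    """Phylum from the root bipartition, class from the next split."""
    taxonomy: Dict[str, Tuple[str, str]] = {}

    def leaves(node: _Node) -> List[str]:
        if not node.children:
            return [node.label]
        out: List[str] = []
        for c in node.children:
            out.extend(leaves(c))
        return out

    for p_idx, phylum_node in enumerate(root.children):
        phylum = f"Phylum{chr(ord('A') + p_idx)}"
        subclades = phylum_node.children if phylum_node.children else [phylum_node]
        for c_idx, class_node in enumerate(subclades):
            klass = f"{phylum}-Class{c_idx + 1}"
            for label in leaves(class_node):
                taxonomy[label] = (phylum, klass)
    return taxonomy


def make_community(params: GeneratorParams) -> SyntheticCommunity:
    """Generate organisms, their phylogeny and a poor mineral medium.

    Accessory reactions are inherited from the ancestral pool under a
    per-branch loss process: on every edge of the root-to-leaf path a
    reaction not in the shared core is lost with probability
    1 - exp(-phylo_decay * branch_length).  Loss events on shared edges
    are shared, so closely related leaves lose (and keep) similar sets
    and repertoire dissimilarity grows with patristic distance.
    """
    rng = np.random.default_rng(params.rng_seed)
    universe = _metabolite_ids(params.n_metabolites)
    minerals = frozenset(universe[: params.n_minerals])

    labels = [f"ORG{i:02d}" for i in range(1, params.n_gems + 1)]
    root = _coalescent_tree(labels, rng)
    tree = PhyloTree.from_newick(root.newick() + ";")
    taxonomy = _leaf_taxonomy(root)

    mean_rxn, dispersion = params.reactions_per_gem
    pool_size = max(1, int(round(mean_rxn * 1.5)))
    pool = [
        _sample_reaction(f"RXN-{i:04d}", universe, params.n_minerals, params, rng)
        for i in range(1, pool_size + 1)
    ]
    n_core = int(round(params.shared_core_fraction * pool_size))
    core = pool[:n_core]
    accessory = pool[n_core:]

    # Per-branch loss, simulated reaction by reaction down the tree.
    retained: Dict[str, List[Reaction]] = {l: list(core) for l in labels}
    for rxn in accessory:

        def descend(node: _Node, lost: bool) -> None:
            if not node.children:
                if not lost:
                    retained[node.label].append(rxn)
                return
            for child, length in zip(node.children, node.lengths):
                child_lost = lost or (
                    rng.random() < 1.0 - np.exp(-params.phylo_decay * length)
                )
                descend(child, child_lost)

        descend(root, False)

    gems: List[Gem] = []
    for label in labels:
        n_private = max(0, int(round(rng.normal(mean_rxn * 0.1, dispersion))))
        private = [
            _sample_reaction(
                f"PRIV-{label}-R{k:03d}", universe, params.n_minerals, params, rng
            )
            for k in range(1, n_private + 1)
        ]
        reactions = tuple(retained[label]) + tuple(private)
        genome_size = int(
            round((500_000 + 25_000 * len(reactions)) * rng.lognormal(0.0, 0.05))
        )
        gems.append(
            Gem(
                organism_id=label,
                reactions=reactions,
                genome_size_bp=genome_size,
                taxonomy=taxonomy.get(label),
            )
        )

    medium = Medium(
        name="mineral_poor",
        nutrients=minerals,
        category="poor",
        base_name="mineral_poor",
    )
    return SyntheticCommunity(
        gems=gems, tree=tree, medium=medium, universe=universe, minerals=minerals
    )


# ---------------------------------------------------------------------------
# Planted cross-feeding


def plant_split_pathway(
    gems: Sequence[Gem],
    target: str,
    n_steps: int,
    cut_assignment: Mapping[int, Union[str, Sequence[str]]],
    *,
    source: str,
) -> List[Gem]:
    """Insert a linear biosynthesis chain split across organisms.

    A chain ``source -> i1 -> ... -> target`` of ``n_steps`` reactions
    is created with fresh intermediate ids, and each segment's reaction
    is given to the organism(s) named in ``cut_assignment`` (segment
    indices 0..n_steps-1; a segment may be redundantly assigned to
    several organisms).  Because the intermediates exist nowhere else,
    an organism holding only part of the chain cannot reach the target
    alone — any set of organisms jointly holding every segment can,
    provided ``source`` is available (e.g. in the medium).

    Preconditions enforced: the target is absent from every repertoire,
    and every segment is assigned to at least one organism.
    """
    if n_steps < 1:
        raise ValueError("a pathway needs at least one step")
    for gem in gems:
        if target in gem.metabolites:
            raise ValueError(
                f"target {target!r} already present in {gem.organism_id!r}"
            )
    missing = [s for s in range(n_steps) if s not in cut_assignment]
    if missing:
        raise ValueError(f"unassigned pathway segment(s): {missing}")

    chain = [source] + [f"{target}-I{k}" for k in range(1, n_steps)] + [target]
    segment_reactions = [
        Reaction(
            id=f"PLANT-{target}-S{s}",
            reactants=frozenset({chain[s]}),
            products=frozenset({chain[s + 1]}),
            reversible=False,
        )
        for s in range(n_steps)
    ]
    assignment: Dict[str, List[Reaction]] = {}
    known = {g.organism_id for g in gems}
    for segment, owners in cut_assignment.items():
        if isinstance(owners, str):
            owners = [owners]
        for owner in owners:
            if owner not in known:
                raise ValueError(f"unknown organism {owner!r} in cut assignment")
            assignment.setdefault(owner, []).append(segment_reactions[segment])

    out: List[Gem] = []
    for gem in gems:
        extra = assignment.get(gem.organism_id, [])
        if extra:
            out.append(replace(gem, reactions=gem.reactions + tuple(extra)))
        else:
            out.append(gem)
    return out


# ---------------------------------------------------------------------------
# Media and target suites over a synthetic universe


def make_media_suite(
    universe: Sequence[str],
    n_poor: int,
    n_rich: int,
    rng: np.random.Generator,
    *,
    n_minerals: int = 8,
    with_are_versions: bool = True,
) -> MediaRegistry:
    """A poor/rich media suite with ARE siblings over a synthetic universe.

    Poor media are small mineral subsets; every rich medium is a strict
    superset of one of the poor media plus extra carbon-like compounds
    from the lower-middle of the layered universe.  One ARE set (drawn
    once) and one cofactor set apply to all media.
    """
    if len(universe) < 4 * n_minerals:
        raise ValueError("universe too small for a media suite")
    minerals = list(universe[:n_minerals])
    organics = list(universe[n_minerals : max(2 * n_minerals, len(universe) // 3)])
    # Supplements mimic central carbon compounds (sugars, organic acids,
    # amino acids): draw them preferentially from the precursor end of
    # the layered universe, where they actually feed reactions.
    ranks = np.arange(len(organics))
    central = np.exp(-ranks / max(1.0, 0.05 * len(universe)))
    central /= central.sum()

    def pick_organics(k: int) -> frozenset:
        k = min(k, len(organics))
        return frozenset(rng.choice(organics, size=k, replace=False, p=central))

    cofactors = pick_organics(2)
    are_compounds = pick_organics(9)
    registry = MediaRegistry(cofactors=cofactors, are_compounds=are_compounds)

    poor_names = []
    for i in range(1, n_poor + 1):
        size = int(rng.integers(max(3, n_minerals - 3), n_minerals + 1))
        nutrients = frozenset(rng.choice(minerals, size=size, replace=False))
        name = f"poor{i}"
        registry.add(
            Medium(name=name, nutrients=nutrients, category="poor", base_name=name)
        )
        poor_names.append(name)
    for i in range(1, n_rich + 1):
        base = registry[poor_names[(i - 1) % len(poor_names)]]
        extras = pick_organics(int(rng.integers(4, 9)))
        name = f"rich{i}"
        registry.add(
            Medium(
                name=name,
                nutrients=base.nutrients | extras,
                category="rich",
                base_name=name,
            )
        )
    if with_are_versions:
        from .media import are_enrich

        for name in list(registry.media):
            are_enrich(registry[name], registry)
    return registry


def make_target_set(
    gems: Sequence[Gem],
    rng: np.random.Generator,
    *,
    n_targets: int = 12,
    exclude: Iterable[str] = (),
    seeds: Optional[Iterable[str]] = None,
    group_names: Tuple[str, ...] = ("groupA", "groupB", "groupC"),
) -> TargetSet:
    """Pick focal end products for a community's target analyses.

    With ``seeds`` given (a reference growth medium), targets mimic the
    profile of curated focal compounds — core products most organisms
    encode: roughly half are drawn from compounds some member produces
    individually under the medium and half from the community's added
    value (reachable only through exchange), so downstream
    minimal-community runs see both "individual" and "cooperative"
    tiers and stay small.  Without ``seeds``, targets are sampled
    uniformly from the unconstrained potential.  Anything in
    ``exclude`` (typically the medium itself) is never picked.
    """
    exclude = set(exclude) | (set(seeds) if seeds is not None else set())
    potential: set = set()
    for gem in gems:
        potential |= unconstrained_ppm(gem)
    if seeds is None:
        candidates = sorted(potential - exclude)
        if len(candidates) < n_targets:
            raise ValueError("not enough producible compounds to pick targets from")
        chosen = sorted(rng.choice(candidates, size=n_targets, replace=False))
    else:
        from .netcore import community_scope

        cs = community_scope(gems, frozenset(seeds))
        individual_pool = sorted(
            (frozenset().union(*cs.individual_ppm.values())) - exclude
        )
        coop_pool = sorted(cs.added_value - exclude)
        fallback = sorted(potential - exclude)
        n_coop = min(n_targets // 2, len(coop_pool))
        n_ind = min(n_targets - n_coop, len(individual_pool))
        chosen_set: set = set(
            rng.choice(coop_pool, size=n_coop, replace=False)
        ) | set(rng.choice(individual_pool, size=n_ind, replace=False))
        remaining = [c for c in fallback if c not in chosen_set]
        short = n_targets - len(chosen_set)
        if short > len(remaining):
            raise ValueError("not enough producible compounds to pick targets from")
        if short > 0:
            chosen_set |= set(rng.choice(remaining, size=short, replace=False))
        chosen = sorted(chosen_set)
    groups: Dict[str, List[str]] = {g: [] for g in group_names}
    for i, compound in enumerate(chosen):
        groups[group_names[i % len(group_names)]].append(compound)
    return TargetSet(groups={g: tuple(m) for g, m in groups.items() if m})
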