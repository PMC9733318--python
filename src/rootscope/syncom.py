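"""Random synthetic communities (SynComs) and their covariates.

A SynCom is a random subset of strains drawn without replacement from
the pool.  For each sampled community we record the regression row used
downstream: size S, mean pairwise phylogenetic (patristic) distance P,
mean genome size G, and the two count responses — Y1, the number of
metabolites the merged repertoire could produce without nutritional
constraint (the union of members' metabolic potentials: with no seeds
applied no cooperative added value can arise), and Y2, the core, i.e.
the intersection of members' potentials.

Sampling design default: sizes 2..20, 500 replicates per size, all
randomness from one seeded generator.  The regression downstream caps
SynCom size at 12, where the count responses plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .netcore import Gem, unconstrained_ppm

__all__ = [
    "PhyloTree",
    "SynComRecord",
    "ExperimentConfig",
    "pairwise_distance",
    "average_pd",
    "sample_syncoms",
    "syncom_table",
]


class PhyloTree:
    """A rooted tree with branch lengths; leaf labels are organism ids.

    Thin wrapper over a dendropy tree that validates label uniqueness,
    treats missing branch lengths as zero (with a warning), and
    precomputes the patristic distance matrix for O(1) lookups.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels in tree: {dupes}")
        n_missing = 0
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                edge.length = 0.0
                n_missing += 1
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length in tree")
        if n_missing:
            warnings.warn(
                f"{n_missing} branch length(s) missing; treated as 0", stacklevel=2
            )
        self._labels = sorted(labels)
        self._pdm = tree.phylogenetic_distance_matrix()
        self._taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}

    @classmethod
    def from_newick(cls, source: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate leaf labels in tree: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    @property
    def leaf_labels(self) -> List[str]:
        return list(self._labels)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def _taxon(self, label: str) -> dendropy.Taxon:
        try:
            return self._taxa[label]
        except KeyError:
            raise KeyError(f"unknown leaf {label!r}") from None

    def distance(self, a: str, b: str) -> float:
        if a == b:
            self._taxon(a)  # still validate the label
            return 0.0
        return float(self._pdm.patristic_distance(self._taxon(a), self._taxon(b)))


def pairwise_distance(tree: PhyloTree, a: str, b: str) -> float:
    """Patristic distance: sum of branch lengths on the path a -> b."""
    return tree.distance(a, b)


def average_pd(tree: PhyloTree, members: Iterable[str]) -> float:
    """Mean of all C(n,2) pairwise patristic distances among members."""
    members = sorted(set(members))
    if len(members) < 2:
        raise ValueError("average phylogenetic distance needs >= 2 members")
    dists = [tree.distance(a, b) for a, b in combinations(members, 2)]
    return float(np.mean(dists))


@dataclass(frozen=True)
class SynComRecord:
    """One sampled community: the regression row."""

    members: FrozenSet[str]
    size: int
    avg_pd: float
    mean_genome: float
    n_ppm: int
    n_cppm: int
    is_whole_community: bool = False

    def __post_init__(self) -> None:
        if self.size != len(self.members):
            raise ValueError("size must equal the number of members")
        if self.avg_pd < 0:
            raise ValueError("avg_pd must be non-negative")
        if self.n_cppm > self.n_ppm:
            raise ValueError("core (CPPM) cannot exceed the union (PPM)")


@dataclass(frozen=True)
class ExperimentConfig:
    """Sampling design for the SynCom experiment."""

    sizes: Tuple[int, ...] = tuple(range(2, 21))
    replicates_per_size: int = 500
    rng_seed: int = 0
    glm_max_size: int = 12

    def __post_init__(self) -> None:
        if min(self.sizes) < 2:
            raise ValueError("SynCom sizes start at 2")
        if self.replicates_per_size < 1:
            raise ValueError("need at least one replicate per size")


def sample_syncoms(
    pool: Sequence[str], config: ExperimentConfig, rng: np.random.Generator
) -> List[FrozenSet[str]]:
    """Uniform without-replacement samples: replicates x each size.

    Repeated member-sets across replicates are allowed (resampling is
    unbiased); the draw order is fixed by the generator state, so a
    seeded generator reproduces the exact sample list.
    """
    pool = list(pool)
    if max(config.sizes) > len(pool):
        raise ValueError(
            f"requested SynCom size {max(config.sizes)} exceeds pool of {len(pool)}"
        )
    samples: List[FrozenSet[str]] = []
    for size in config.sizes:
        for _ in range(config.replicates_per_size):
            picked = rng.choice(len(pool), size=size, replace=False)
            samples.append(frozenset(pool[i] for i in picked))
    return samples


def syncom_table(
    gems: Sequence[Gem],
    tree: PhyloTree,
    config: ExperimentConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Sample SynComs and assemble the full covariate/response table.

    Per sample: Y1 = |union of members' metabolic potentials|, Y2 =
    |intersection|, P = mean patristic distance, G = mean genome size.
    A final row for the whole pool is appended, flagged.  Members whose
    gem lacks a genome size cannot contribute to G: any sample touching
    one is skipped with a warning and counted in the report.

    Returns (table, report) where report counts skipped samples.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    by_id = {g.organism_id: g for g in gems}
    missing_tree = sorted(set(by_id) - set(tree.leaf_labels))
    if missing_tree:
        raise ValueError(f"organisms absent from the tree: {missing_tree}")
    potentials = {org: unconstrained_ppm(g) for org, g in by_id.items()}
    no_genome = {org for org, g in by_id.items() if g.genome_size_bp is None}

    def make_record(members: FrozenSet[str], whole: bool) -> Optional[SynComRecord]:
        if members & no_genome:
            return None
        sets = [potentials[m] for m in members]
        union: FrozenSet[str] = frozenset().union(*sets)
        core = frozenset.intersection(*sets)
        return SynComRecord(
            members=members,
            size=len(members),
            avg_pd=average_pd(tree, members),
            mean_genome=float(
                np.mean([by_id[m].genome_size_bp for m in members])
            ),
            n_ppm=len(union),
            n_cppm=len(core),
            is_whole_community=whole,
        )

    samples = sample_syncoms(sorted(by_id), config, rng)
    records: List[SynComRecord] = []
    n_skipped = 0
    for members in samples:
        rec = make_record(members, whole=False)
        if rec is None:
            n_skipped += 1
        else:
            records.append(rec)
    if len(by_id) >= 2:
        whole = make_record(frozenset(by_id), whole=True)
        if whole is None:
            n_skipped += 1
        else:
            records.append(whole)
    if n_skipped:
        warnings.warn(
            f"{n_skipped} SynCom(s) skipped: member(s) lack genome size",
            stacklevel=2,
        )
    table = pd.DataFrame(
        {
            "members": [";".join(sorted(r.members)) for r in records],
            "size": [r.size for r in records],
            "avg_pd": [r.avg_pd for r in records],
            "mean_genome": [r.mean_genome for r in records],
            "n_ppm": [r.n_ppm for r in records],
            "n_cppm": [r.n_cppm for r in records],
            "is_whole_community": [r.is_whole_community for r in records],
        }
    )
    return table, {"n_skipped_missing_genome": n_skipped}
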