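"""Growth media as nutritional constraints.

A medium is a named seed set: the nutrients a repertoire may rely on.
Media come in two broad classes — *poor* (mainly mineral nutrients) and
*rich* (more carbon sources) — and every base medium has an ARE-enriched
sibling, where ARE (artificial root exudates) is a sugar / organic-acid /
amino-acid supplement mimicking what plant roots secrete.  A common
cofactor list is added to every registered medium.

Media used for target-production analyses must satisfy two validity
rules: no target compound may already sit in the nutrients (production
would be trivially confounded), and no undescribed "mixture" ingredient
(tryptone, yeast extract, ...) may be present, because a mixture's
compound content is unknown.  Rich media typically fail these rules for
some target groups only, so admissibility is tracked per group.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .netcore import Gem, scope, unconstrained_ppm
from .targets import TargetSet

__all__ = [
    "Medium",
    "MediaRegistry",
    "Violation",
    "DEFAULT_COFACTORS",
    "DEFAULT_ARE_COMPOUNDS",
    "DEFAULT_MIXTURE_BLACKLIST",
    "DEFAULT_MIXTURE_GROUPS",
    "load_media",
    "load_media_tsv",
    "are_enrich",
    "validate_medium",
    "ppm_by_medium_table",
    "media_dendrogram_input",
]

CATEGORIES = ("poor", "rich")

#: Placeholder cofactor default: ubiquitous carriers most seed-set
#: conventions grant for free.  Registry-level input; override at load.
DEFAULT_COFACTORS: FrozenSet[str] = frozenset(
    {"ATP", "NAD", "NADP", "CO-A", "WATER", "PROTON"}
)

#: Default ARE composition: 3 sugars + 3 organic acids + 3 amino acids.
#: Serine, alanine and glutamate are the three amino acids deliberately
#: excluded from the target registry, precisely because ARE supplies them.
DEFAULT_ARE_COMPOUNDS: FrozenSet[str] = frozenset(
    {
        "GLC",  # glucose
        "FRU",  # fructose
        "SUCROSE",
        "PYRUVATE",
        "MAL",  # malate
        "CIT",  # citrate
        "SER",
        "L-ALPHA-ALANINE",
        "GLT",  # glutamate
    }
)

DEFAULT_MIXTURE_BLACKLIST: FrozenSet[str] = frozenset(
    {"tryptone", "yeast extract", "peptone", "casamino acids"}
)

#: Which target groups an undescribed mixture ingredient contaminates.
#: Tryptone-like digests supply amino acids; yeast extract additionally
#: supplies B vitamins.  Overridable at registry load.
DEFAULT_MIXTURE_GROUPS: Mapping[str, FrozenSet[str]] = {
    "tryptone": frozenset({"amino_acids"}),
    "peptone": frozenset({"amino_acids"}),
    "casamino acids": frozenset({"amino_acids"}),
    "yeast extract": frozenset({"amino_acids", "vitamins"}),
}


@dataclass(frozen=True)
class Medium:
    """A named nutrient set with its category and enrichment status."""

    name: str
    nutrients: FrozenSet[str]
    category: str
    base_name: str
    are_enriched: bool = False
    mixtures: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("medium name must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for medium {self.name!r}"
            )
        if not self.nutrients:
            raise ValueError(f"medium {self.name!r} has an empty nutrient list")
        object.__setattr__(self, "nutrients", frozenset(self.nutrients))
        object.__setattr__(self, "mixtures", frozenset(self.mixtures))


@dataclass(frozen=True)
class Violation:
    """One reason a medium is unusable for a target analysis."""

    medium: str
    kind: str  # "target_in_nutrients" | "mixture"
    offender: str
    group: Optional[str] = None


@dataclass
class MediaRegistry:
    """All media of a study plus the shared supplements and blacklist."""

    media: Dict[str, Medium] = field(default_factory=dict)
    cofactors: FrozenSet[str] = DEFAULT_COFACTORS
    are_compounds: FrozenSet[str] = DEFAULT_ARE_COMPOUNDS
    mixture_blacklist: FrozenSet[str] = DEFAULT_MIXTURE_BLACKLIST
    mixture_groups: Mapping[str, FrozenSet[str]] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE_GROUPS)
    )

    def add(self, medium: Medium) -> None:
        if medium.name in self.media:
            raise ValueError(f"duplicate medium name {medium.name!r}")
        # Every registered medium carries the common cofactor set.
        enriched = Medium(
            name=medium.name,
            nutrients=medium.nutrients | self.cofactors,
            category=medium.category,
            base_name=medium.base_name,
            are_enriched=medium.are_enriched,
            mixtures=medium.mixtures,
        )
        self.media[medium.name] = enriched

    def __getitem__(self, name: str) -> Medium:
        return self.media[name]

    def __iter__(self):
        return iter(self.media.values())

    def names(self) -> List[str]:
        return sorted(self.media)


def load_media(path: str | Path, *, with_are_versions: bool = False) -> MediaRegistry:
    """Load a registry from the JSON media dialect.

    Layout::

        {"cofactors": [...], "are_compounds": [...],
         "mixture_blacklist": [...],
         "media": [{"name": ..., "category": "poor"|"rich",
                    "nutrients": [...], "mixtures": [...]}]}

    Cofactors are added to every medium on registration.  With
    ``with_are_versions=True`` an ARE-enriched sibling is registered for
    every base medium.
    """
    raw = json.loads(Path(path).read_text())
    registry = MediaRegistry(
        cofactors=frozenset(raw.get("cofactors", DEFAULT_COFACTORS)),
        are_compounds=frozenset(raw.get("are_compounds", DEFAULT_ARE_COMPOUNDS)),
        mixture_blacklist=frozenset(
            raw.get("mixture_blacklist", DEFAULT_MIXTURE_BLACKLIST)
        ),
        mixture_groups={
            k: frozenset(v) for k, v in raw.get("mixture_groups", {}).items()
        }
        or dict(DEFAULT_MIXTURE_GROUPS),
    )
    entries = raw.get("media", [])
    if not entries:
        raise ValueError(f"no media declared in {path}")
    for entry in entries:
        medium = Medium(
            name=entry["name"],
            nutrients=frozenset(entry["nutrients"]),
            category=entry["category"],
            base_name=entry.get("base_name", entry["name"]),
            are_enriched=bool(entry.get("are_enriched", False)),
            mixtures=frozenset(entry.get("mixtures", [])),
        )
        registry.add(medium)
    if with_are_versions:
        for name in list(registry.media):
            base = registry.media[name]
            if not base.are_enriched:
                registry.add(are_enrich(base, registry, register=False))
    return registry


def load_media_tsv(
    nutrients_path: str | Path, categories_path: str | Path
) -> MediaRegistry:
    """Two-column TSV loader: (medium_name, nutrient_id) rows plus a
    sidecar (medium_name, category) file."""
    nutrients: Dict[str, set] = {}
    for line in Path(nutrients_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"expected 2 TSV columns, got {line!r}")
        nutrients.setdefault(parts[0], set()).add(parts[1])
    categories: Dict[str, str] = {}
    for line in Path(categories_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, category = line.split("\t")
        categories[name] = category
    registry = MediaRegistry()
    for name in sorted(nutrients):
        if name not in categories:
            raise ValueError(f"medium {name!r} missing from category sidecar")
        registry.add(
            Medium(
                name=name,
                nutrients=frozenset(nutrients[name]),
                category=categories[name],
                base_name=name,
            )
        )
    return registry


def are_enrich(
    medium: Medium, registry: MediaRegistry, *, register: bool = True
) -> Medium:
    """Return the ARE-enriched sibling of a base medium.

    Nutrients are unioned with the registry's ARE compounds, the name is
    suffixed ``+ARE`` and the base name preserved.  Enriching an already
    enriched medium is an error rather than a no-op, to keep the base /
    enriched pairing one-to-one.
    """
    if medium.are_enriched:
        raise ValueError(f"medium {medium.name!r} is already ARE-enriched")
    enriched = Medium(
        name=f"{medium.name}+ARE",
        nutrients=medium.nutrients | registry.are_compounds,
        category=medium.category,
        base_name=medium.base_name,
        are_enriched=True,
        mixtures=medium.mixtures,
    )
    if register:
        registry.add(enriched)
        return registry[enriched.name]
    return enriched


def validate_medium(
    medium: Medium, targets: TargetSet, registry: MediaRegistry
) -> Tuple[List[Violation], Dict[str, bool]]:
    """Check the no-target / no-mixture validity rules.

    Returns ``(violations, admissible)`` where ``violations`` holds one
    record per target compound found in the nutrients and per
    blacklisted mixture ingredient present, and ``admissible`` maps each
    target group (plus ``"all"``) to whether the medium may be used for
    that group's production analysis.  Validation is total: it never
    raises on any medium.
    """
    violations: List[Violation] = []
    blocked_groups: set = set()
    for group, members in targets.groups.items():
        for compound in sorted(members):
            if compound in medium.nutrients:
                violations.append(
                    Violation(
                        medium=medium.name,
                        kind="target_in_nutrients",
                        offender=compound,
                        group=group,
                    )
                )
                blocked_groups.add(group)
    for ingredient in sorted(medium.mixtures):
        if ingredient in registry.mixture_blacklist:
            violations.append(
                Violation(medium=medium.name, kind="mixture", offender=ingredient)
            )
            implied = registry.mixture_groups.get(ingredient)
            # An unmapped mixture has unknown content: block everything.
            blocked_groups |= implied if implied is not None else set(targets.groups)
    admissible = {g: g not in blocked_groups for g in targets.groups}
    admissible["all"] = not blocked_groups
    return violations, admissible


def ppm_by_medium_table(gems: Sequence[Gem], registry: MediaRegistry) -> pd.DataFrame:
    """Tidy (organism_id, medium, n_ppm) table over every gem x medium,
    plus a pseudo-medium ``unconstrained`` counting the metabolic
    potential."""
    rows = []
    for gem in gems:
        for name in registry.names():
            medium = registry[name]
            rows.append(
                {
                    "organism_id": gem.organism_id,
                    "medium": name,
                    "n_ppm": len(scope(gem, medium.nutrients).producible),
                }
            )
        rows.append(
            {
                "organism_id": gem.organism_id,
                "medium": "unconstrained",
                "n_ppm": len(unconstrained_ppm(gem)),
            }
        )
    return pd.DataFrame(rows, columns=["organism_id", "medium", "n_ppm"])


def media_dendrogram_input(
    gems: Sequence[Gem], registry: MediaRegistry
) -> pd.DataFrame:
    """Medium x metabolite matrix of producer counts.

    Entry (m, c) is the number of gems whose individual scope under
    medium m contains compound c — which compounds are producible under
    which constraint, and by how many organisms.  Community added value
    is deliberately excluded: the matrix describes what members make on
    their own.  Feeds Bray-Curtis + complete-linkage clustering of media.
    """
    per_medium_counts: Dict[str, Dict[str, int]] = {}
    all_compounds: set = set()
    for name in registry.names():
        medium = registry[name]
        counts: Dict[str, int] = {}
        for gem in gems:
            for compound in scope(gem, medium.nutrients).producible:
                counts[compound] = counts.get(compound, 0) + 1
        per_medium_counts[name] = counts
        all_compounds |= set(counts)
    columns = sorted(all_compounds)
    data = [
        [per_medium_counts[name].get(c, 0) for c in columns]
        for name in registry.names()
    ]
    return pd.DataFrame(data, index=registry.names(), columns=columns, dtype=int)
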