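"""The 30-compound target registry (TPPM) and production assessment.

Targets are end-product metabolites whose producibility is the focal
question: 17 proteinogenic amino acids (the standard 20 minus serine,
alanine and glutamate, which the artificial root exudates already
supply), eight B vitamins, and five phytohormones relevant to a
root-associated community.

Compound identifiers are MetaCyc-style where the mapping is well known;
the full id -> display-name mapping ships with the registry and every id
is overridable at load time, since different reconstruction pipelines
may emit different synonyms ("auxin" is registered as indole-3-acetate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .netcore import Gem, scope, unconstrained_ppm

__all__ = [
    "TargetSet",
    "TARGET_NAMES",
    "default_target_registry",
    "load_target_registry",
    "target_production",
    "production_fraction_matrix",
]

#: Best-effort MetaCyc-style id -> human-readable name for every default target.
TARGET_NAMES: Mapping[str, str] = {
    # 17 amino acids (20 standard minus serine, alanine, glutamate)
    "ARG": "L-arginine",
    "ASN": "L-asparagine",
    "L-ASPARTATE": "L-aspartate",
    "CYS": "L-cysteine",
    "GLN": "L-glutamine",
    "GLY": "glycine",
    "HIS": "L-histidine",
    "ILE": "L-isoleucine",
    "LEU": "L-leucine",
    "LYS": "L-lysine",
    "MET": "L-methionine",
    "PHE": "L-phenylalanine",
    "PRO": "L-proline",
    "THR": "L-threonine",
    "TRP": "L-tryptophan",
    "TYR": "L-tyrosine",
    "VAL": "L-valine",
    # 8 B vitamins
    "THIAMINE-PYROPHOSPHATE": "thiamine diphosphate (B1)",
    "RIBOFLAVIN": "riboflavin (B2)",
    "NIACINE": "nicotinate (B3)",
    "PANTOTHENATE": "(R)-pantothenate (B5)",
    "PYRIDOXINE": "pyridoxine (B6)",
    "BIOTIN": "biotin (B7)",
    "THF": "tetrahydrofolate (B9)",
    "ADENOSYLCOBALAMIN": "adenosylcobalamin (B12)",
    # 5 phytohormones
    "INDOLE-3-ACETATE": "auxin (indole-3-acetate)",
    "SALICYLATE": "salicylic acid",
    "ABSCISIC-ACID": "abscisic acid",
    "ETHYLENE-CMPD": "ethylene",
    "JASMONATE": "jasmonic acid",
}

_DEFAULT_GROUPS: Mapping[str, Tuple[str, ...]] = {
    "amino_acids": (
        "ARG", "ASN", "L-ASPARTATE", "CYS", "GLN", "GLY", "HIS", "ILE", "LEU",
        "LYS", "MET", "PHE", "PRO", "THR", "TRP", "TYR", "VAL",
    ),
    "vitamins": (
        "THIAMINE-PYROPHOSPHATE", "RIBOFLAVIN", "NIACINE", "PANTOTHENATE",
        "PYRIDOXINE", "BIOTIN", "THF", "ADENOSYLCOBALAMIN",
    ),
    "phytohormones": (
        "INDOLE-3-ACETATE", "SALICYLATE", "ABSCISIC-ACID", "ETHYLENE-CMPD",
        "JASMONATE",
    ),
}


@dataclass(frozen=True)
class TargetSet:
    """Ordered, disjoint groups of target compound ids."""

    groups: Mapping[str, Tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: set = set()
        for group, members in self.groups.items():
            if not members:
                raise ValueError(f"target group {group!r} is empty")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"targets shared between groups: {sorted(overlap)}")
            seen |= set(members)
        object.__setattr__(
            self, "groups", {g: tuple(m) for g, m in self.groups.items()}
        )

    def all_targets(self) -> Tuple[str, ...]:
        out: list = []
        for members in self.groups.values():
            out.extend(members)
        return tuple(out)

    def group_of(self, compound: str) -> Optional[str]:
        for group, members in self.groups.items():
            if compound in members:
                return group
        return None

    def __contains__(self, compound: str) -> bool:
        return self.group_of(compound) is not None

    def subset(self, group: str) -> "TargetSet":
        if group == "all":
            return self
        if group not in self.groups:
            raise KeyError(f"unknown target group {group!r}")
        return TargetSet(groups={group: self.groups[group]})

    def to_dict(self) -> dict:
        return {
            "groups": {g: list(m) for g, m in self.groups.items()},
            "names": {c: TARGET_NAMES.get(c, c) for c in self.all_targets()},
        }


def default_target_registry() -> TargetSet:
    """The canonical 30-target registry: 17 + 8 + 5 compounds."""
    return TargetSet(groups=_DEFAULT_GROUPS)


def load_target_registry(path: Union[str, Path]) -> TargetSet:
    """Load a (possibly overridden) registry from JSON: {"groups": {...}}."""
    raw = json.loads(Path(path).read_text())
    return TargetSet(groups={g: tuple(m) for g, m in raw["groups"].items()})


def target_production(
    gem: Gem,
    medium,  # Medium | "unconstrained"
    targets: TargetSet,
    *,
    registry=None,
) -> Dict[str, bool]:
    """Per-target producibility of one gem under one constraint.

    Constrained: membership of the gem's scope under the medium's
    nutrients.  Unconstrained: membership of the metabolic potential.
    When a registry is supplied, the medium must be admissible for every
    queried group; otherwise the call fails naming the offending targets.
    """
    if medium == "unconstrained":
        producible = unconstrained_ppm(gem)
    else:
        if registry is not None:
            from .media import validate_medium  # deferred: avoids import cycle

            violations, admissible = validate_medium(medium, targets, registry)
            bad_groups = [g for g in targets.groups if not admissible.get(g, False)]
            if bad_groups:
                offenders = sorted(
                    v.offender for v in violations if v.group in bad_groups or v.group is None
                )
                raise ValueError(
                    f"medium {medium.name!r} inadmissible for groups {bad_groups}"
                    f" (offending: {offenders})"
                )
        producible = scope(gem, medium.nutrients).producible
    return {t: (t in producible) for t in targets.all_targets()}


def production_fraction_matrix(
    gems: Sequence[Gem],
    media: Sequence,  # of Medium
    targets: TargetSet,
    *,
    registry=None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """(medium x target) matrix of producer fractions, with a mask.

    Each entry is the fraction of gems individually producing the target
    under the medium.  A cell whose medium is inadmissible for the
    target's group is *masked* (NaN in the fraction frame, True in the
    mask frame) rather than reported as 0 — the question is meaningless
    there, and a zero would silently poison downstream summaries.
    """
    from .media import validate_medium  # deferred: avoids import cycle

    target_ids = list(targets.all_targets())
    fractions = pd.DataFrame(
        index=[m.name for m in media], columns=target_ids, dtype=float
    )
    mask = pd.DataFrame(
        False, index=[m.name for m in media], columns=target_ids, dtype=bool
    )
    n = len(gems)
    for medium in media:
        if registry is not None:
            _violations, admissible = validate_medium(medium, targets, registry)
        else:
            admissible = {g: True for g in targets.groups}
        scopes = [scope(g, medium.nutrients).producible for g in gems]
        for t in target_ids:
            group = targets.group_of(t)
            if t in medium.nutrients or not admissible.get(group, True):
                fractions.loc[medium.name, t] = np.nan
                mask.loc[medium.name, t] = True
            else:
                fractions.loc[medium.name, t] = (
                    sum(1 for s in scopes if t in s) / n if n else 0.0
                )
    return fractions, mask
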