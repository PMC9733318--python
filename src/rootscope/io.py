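"""Readers and writers for the pipeline's interchange formats.

Networks travel as SBML Level 3 core (one document per organism),
phylogenies as newick, media and target registries as JSON, tables as
CSV.  Every file the pipeline writes begins with a provenance header
(tool version, seed, SHA-256 digests of the inputs) so a result can be
traced to the exact run that produced it.

SBML identifier handling: an SBML SId may not contain characters such
as ``-`` that are routine in MetaCyc-style compound ids, so ids are
written with an ``M_`` / ``R_`` prefix and any illegal character
escaped as ``__<codepoint>__``, and the inverse mapping is applied on
read.  Foreign SBML using the common ``M_`` / ``R_`` prefix convention
is therefore also read back to bare ids; beyond that, species ids are
taken verbatim — compartment suffixes included — because cross-organism
exchange presumes one shared namespace and silently rewriting ids would
corrupt community scopes.  Stoichiometry values are ignored (the model
is qualitative); the ``reversible`` attribute is honored; gene
associations (fbc) are ignored.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import libsbml
import pandas as pd

from . import __version__
from .media import MediaRegistry, Medium
from .netcore import Gem, Reaction
from .syncom import PhyloTree

__all__ = [
    "read_sbml",
    "read_sbml_with_report",
    "write_sbml",
    "read_community",
    "write_community",
    "read_newick",
    "write_newick",
    "write_media_json",
    "write_json",
    "write_csv",
    "provenance",
]

_ESCAPE = re.compile(r"[^A-Za-z0-9_]")
_UNESCAPE = re.compile(r"__(\d+)__")


def _encode_id(raw: str, prefix: str) -> str:
    return prefix + _ESCAPE.sub(lambda m: f"__{ord(m.group(0))}__", raw)


def _decode_id(sid: str, prefix: str) -> str:
    if sid.startswith(prefix):
        sid = sid[len(prefix):]
    return _UNESCAPE.sub(lambda m: chr(int(m.group(1))), sid)


# ---------------------------------------------------------------------------
# SBML


def read_sbml_with_report(path: str | Path) -> Tuple[Gem, Dict[str, int]]:
    """Read one SBML L3 document into a Gem, counting skips.

    A reaction without products cannot contribute to any scope and is
    skipped with a warning; the count is returned in the report.
    """
    path = Path(path)
    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise ValueError(
                f"SBML parse error in {path} line {err.getLine()}: "
                f"{err.getMessage().strip()}"
            )
    model = doc.getModel()
    if model is None:
        raise ValueError(f"{path} contains no SBML model")
    organism_id = _decode_id(model.getId(), "") if model.getId() else path.stem
    reactions: List[Reaction] = []
    n_skipped = 0
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        products = frozenset(
            _decode_id(rxn.getProduct(j).getSpecies(), "M_")
            for j in range(rxn.getNumProducts())
        )
        if not products:
            n_skipped += 1
            warnings.warn(
                f"reaction {rxn.getId()!r} in {path.name} has no products; skipped",
                stacklevel=2,
            )
            continue
        reactants = frozenset(
            _decode_id(rxn.getReactant(j).getSpecies(), "M_")
            for j in range(rxn.getNumReactants())
        )
        reactions.append(
            Reaction(
                id=_decode_id(rxn.getId(), "R_"),
                reactants=reactants,
                products=products,
                reversible=bool(rxn.getReversible()),
            )
        )
    gem = Gem(organism_id=organism_id, reactions=tuple(reactions))
    return gem, {"n_skipped_no_products": n_skipped}


def read_sbml(path: str | Path) -> Gem:
    gem, _report = read_sbml_with_report(path)
    return gem


def write_sbml(gem: Gem, path: str | Path) -> None:
    """Write a Gem as a deterministic SBML L3 core document."""
    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId(_encode_id(gem.organism_id, ""))
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    for met in sorted(gem.metabolites):
        sp = model.createSpecies()
        sp.setId(_encode_id(met, "M_"))
        sp.setName(met)
        sp.setCompartment("c")
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
    for rxn in gem.reactions:
        r = model.createReaction()
        r.setId(_encode_id(rxn.id, "R_"))
        r.setReversible(rxn.reversible)
        for met in sorted(rxn.reactants):
            sr = r.createReactant()
            sr.setSpecies(_encode_id(met, "M_"))
            sr.setStoichiometry(1.0)
            sr.setConstant(True)
        for met in sorted(rxn.products):
            sr = r.createProduct()
            sr.setSpecies(_encode_id(met, "M_"))
            sr.setStoichiometry(1.0)
            sr.setConstant(True)
    Path(path).write_text(libsbml.writeSBMLToString(doc))


def read_community(
    sbml_dir: str | Path, *, genomes_tsv: Optional[str | Path] = None
) -> List[Gem]:
    """Read every ``*.xml`` / ``*.sbml`` in a directory, sorted by name.

    An optional sidecar TSV (organism_id, genome_size_bp, phylum, class)
    attaches genome sizes and taxonomy, which SBML does not carry.
    """
    sbml_dir = Path(sbml_dir)
    paths = sorted(
        p for p in sbml_dir.iterdir() if p.suffix.lower() in (".xml", ".sbml")
    )
    if not paths:
        raise FileNotFoundError(f"no SBML files in {sbml_dir}")
    gems = [read_sbml(p) for p in paths]
    if genomes_tsv is not None:
        meta = pd.read_csv(genomes_tsv, sep="\t", comment="#").set_index("organism_id")
        from dataclasses import replace

        enriched = []
        for gem in gems:
            if gem.organism_id in meta.index:
                row = meta.loc[gem.organism_id]
                taxonomy = None
                if "phylum" in row.index and pd.notna(row.get("phylum")):
                    taxonomy = (str(row["phylum"]), str(row.get("class", "")))
                enriched.append(
                    replace(
                        gem,
                        genome_size_bp=int(row["genome_size_bp"]),
                        taxonomy=taxonomy,
                    )
                )
            else:
                enriched.append(gem)
        gems = enriched
    ids = [g.organism_id for g in gems]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate organism ids across SBML files")
    return gems


def write_community(gems: Sequence[Gem], out_dir: str | Path) -> None:
    """One SBML file per gem plus the genomes.tsv sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for gem in sorted(gems, key=lambda g: g.organism_id):
        write_sbml(gem, out_dir / f"{gem.organism_id}.xml")
        rows.append(
            {
                "organism_id": gem.organism_id,
                "genome_size_bp": gem.genome_size_bp,
                "phylum": gem.taxonomy[0] if gem.taxonomy else "",
                "class": gem.taxonomy[1] if gem.taxonomy else "",
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "genomes.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree.from_file(path)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


# ---------------------------------------------------------------------------
# Media / JSON / CSV with provenance


def write_media_json(registry: MediaRegistry, path: str | Path, **prov) -> None:
    payload = {
        "cofactors": sorted(registry.cofactors),
        "are_compounds": sorted(registry.are_compounds),
        "mixture_blacklist": sorted(registry.mixture_blacklist),
        "mixture_groups": {
            k: sorted(v) for k, v in sorted(registry.mixture_groups.items())
        },
        "media": [
            {
                "name": m.name,
                "category": m.category,
                "base_name": m.base_name,
                "are_enriched": m.are_enriched,
                # cofactors are re-added on load; strip them for a clean round trip
                "nutrients": sorted(m.nutrients - registry.cofactors)
                if m.nutrients - registry.cofactors
                else sorted(m.nutrients),
                "mixtures": sorted(m.mixtures),
            }
            for _, m in sorted(registry.media.items())
        ],
    }
    write_json(payload, path, **prov)


def provenance(
    *, seed: Optional[int] = None, inputs: Iterable[str | Path] = ()
) -> Dict[str, object]:
    digests = {}
    for p in inputs:
        p = Path(p)
        if p.is_file():
            digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    return {"tool": "rootscope", "version": __version__, "seed": seed, "inputs": digests}


def write_json(payload: Mapping, path: str | Path, **prov) -> None:
    """JSON with sorted keys and a leading provenance object."""
    body = {"_provenance": provenance(**prov)}
    body.update(payload)
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True) + "\n")


def write_csv(frame: pd.DataFrame, path: str | Path, *, index: bool = False, **prov) -> None:
    """CSV (UTF-8, comma, '.' decimal) prefixed with '#' provenance lines."""
    meta = provenance(**prov)
    lines = [
        f"# tool: {meta['tool']} {meta['version']}",
        f"# seed: {meta['seed']}",
    ]
    for name, digest in sorted(meta["inputs"].items()):  # type: ignore[union-attr]
        lines.append(f"# input: {name} sha256:{digest}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        frame.to_csv(fh, index=index)
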