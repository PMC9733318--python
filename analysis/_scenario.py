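"""Shared demo scenario for the analysis scripts.

One synthetic community ("demo193-mini": 20 organisms, 300 metabolites,
seed 20) with its phylogeny, a 3-poor / 2-rich media suite with ARE
siblings, and a 12-compound focal target set drawn from the community's
potential.  Script 01 writes it to scratch/demo/ in the interchange
formats; later scripts load it from disk, regenerating on demand so
each script also runs standalone.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

SEED = 20
ROOT = Path(__file__).resolve().parent.parent
DEMO_DIR = ROOT / "scratch" / "demo"
RESULTS = ROOT / "results"


def build():
    from rootscope.synthetic import (
        GeneratorParams,
        make_community,
        make_media_suite,
        make_target_set,
    )

    community = make_community(GeneratorParams(rng_seed=SEED))
    rng = np.random.default_rng(SEED + 101)
    registry = make_media_suite(community.universe, n_poor=3, n_rich=2, rng=rng)
    targets = make_target_set(
        community.gems, rng, exclude=community.minerals,
        seeds=registry["poor1"].nutrients,
    )
    return community, registry, targets


def write(community, registry, targets):
    from rootscope import io as rio

    (DEMO_DIR / "sbml").mkdir(parents=True, exist_ok=True)
    rio.write_community(community.gems, DEMO_DIR / "sbml")
    rio.write_newick(community.tree, DEMO_DIR / "tree.nwk")
    rio.write_media_json(registry, DEMO_DIR / "media.json", seed=SEED)
    rio.write_json(targets.to_dict(), DEMO_DIR / "targets.json", seed=SEED)


def load():
    """Load the demo scenario from disk, generating it first if needed."""
    from rootscope import io as rio
    from rootscope.media import load_media
    from rootscope.targets import TargetSet

    if not (DEMO_DIR / "media.json").exists():
        community, registry, targets = build()
        write(community, registry, targets)
        RESULTS.mkdir(exist_ok=True)
        return community.gems, community.tree, registry, targets

    import json

    gems = rio.read_community(DEMO_DIR / "sbml",
                              genomes_tsv=DEMO_DIR / "sbml" / "genomes.tsv")
    tree = rio.read_newick(DEMO_DIR / "tree.nwk")
    registry = load_media(DEMO_DIR / "media.json")
    raw = json.loads((DEMO_DIR / "targets.json").read_text())
    targets = TargetSet(groups={g: tuple(m) for g, m in raw["groups"].items()})
    RESULTS.mkdir(exist_ok=True)
    return gems, tree, registry, targets
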