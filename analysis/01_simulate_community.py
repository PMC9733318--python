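#!/usr/bin/env python
"""Generate the demo synthetic community and write its input files.

Produces scratch/demo/: one SBML network per organism (plus a
genomes.tsv sidecar with genome sizes and taxonomy), the newick
phylogeny, the media suite (poor/rich with ARE siblings) and the focal
target registry — exactly the formats the downstream scripts and the
CLI consume.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import _scenario


def main() -> None:
    community, registry, targets = _scenario.build()
    _scenario.write(community, registry, targets)

    n_rxn = [len(g.reactions) for g in community.gems]
    print(f"demo193-mini scenario (seed {_scenario.SEED}) -> {_scenario.DEMO_DIR}")
    print(f"  organisms: {len(community.gems)}  "
          f"reactions/organism: {min(n_rxn)}-{max(n_rxn)}")
    print(f"  metabolite universe: {len(community.universe)} "
          f"({len(community.minerals)} mineral seeds)")
    print(f"  media: {', '.join(registry.names())}")
    print(f"  targets: {len(targets.all_targets())} compounds in "
          f"{len(targets.groups)} groups")


if __name__ == "__main__":
    main()
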