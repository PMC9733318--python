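#!/usr/bin/env python
"""Which organisms can make the focal end products, and where.

Builds the medium x target matrix of producer fractions (the share of
organisms whose individual scope reaches each target under each
medium), masking cells where the medium already contains the target or
is inadmissible for its group, plus the unconstrained baseline.

Writes: results/target_fractions.csv, results/target_fractions.mask.csv
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import _scenario

import numpy as np
import pandas as pd

from rootscope import io as rio
from rootscope.netcore import unconstrained_ppm
from rootscope.targets import production_fraction_matrix


def main() -> None:
    gems, _tree, registry, targets = _scenario.load()
    media = [registry[name] for name in registry.names()]

    fractions, mask = production_fraction_matrix(
        gems, media, targets, registry=registry
    )
    uncon = {
        t: sum(1 for g in gems if t in unconstrained_ppm(g)) / len(gems)
        for t in targets.all_targets()
    }
    fractions.loc["unconstrained"] = pd.Series(uncon)
    mask.loc["unconstrained"] = False

    rio.write_csv(fractions.reset_index(names="medium"),
                  _scenario.RESULTS / "target_fractions.csv", seed=_scenario.SEED)
    rio.write_csv(mask.reset_index(names="medium"),
                  _scenario.RESULTS / "target_fractions.mask.csv",
                  seed=_scenario.SEED)

    n_targets = len(targets.all_targets())
    producible_somewhere = (fractions.fillna(0) > 0).any(axis=0).sum()
    print(f"Target production across {len(media)} media, {len(gems)} organisms:")
    print(f"  {producible_somewhere}/{n_targets} targets individually "
          "producible under at least one condition")
    print(f"  mean producer fraction, unconstrained: "
          f"{np.mean(list(uncon.values())):.2f}")
    by_cat = {}
    for m in media:
        key = ("rich" if m.category == "rich" else "poor",
               "ARE" if m.are_enriched else "base")
        by_cat.setdefault(key, []).append(
            np.nanmean(fractions.loc[m.name].to_numpy(dtype=float))
        )
    for (cat, are), vals in sorted(by_cat.items()):
        print(f"  mean producer fraction, {cat}/{are}: {np.mean(vals):.2f}")
    n_masked = int(mask.drop(index="unconstrained").to_numpy().sum())
    print(f"  masked (medium, target) cells: {n_masked}")


if __name__ == "__main__":
    main()
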