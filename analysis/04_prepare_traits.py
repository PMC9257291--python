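"""Assemble the species trait table, apply the missing-data filter, and
build the centred design matrix (log mass, log flock size, sqrt predators,
coloniality, activity, coloniality x mass interaction). Reports variance
inflation factors for the main effects.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA, RESULTS, ensure_dataset

from wingcontrast.traits import assemble_table, build_design, filter_missing, vif


def main():
    ensure_dataset()
    traits = pd.read_csv(DATA / "traits.csv")
    manual = pd.read_csv(RESULTS / "03_manual_scores.csv")
    table = assemble_table(traits, manual=manual)
    filtered, removed = filter_missing(table)
    design = build_design(filtered)
    vifs = vif(design)

    pd.DataFrame(design.X, columns=design.names, index=design.species_ids).assign(
        response=design.y
    ).to_csv(RESULTS / "04_design.csv")
    vifs.rename_axis("predictor").reset_index().to_csv(RESULTS / "04_vif.csv", index=False)

    print(f"removed {removed} species with missing traits; {design.n} retained")
    print(f"design columns: {design.names}")
    print(f"max VIF {vifs.max():.2f} (all < 1.5: {bool((vifs < 1.5).all())})")


if __name__ == "__main__":
    main()
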