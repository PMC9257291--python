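"""Generate the synthetic study dataset: a Yule tree set, species traits
with realistic missingness, museum wing images, and a 30-scorer vote panel.

Writes scratch/analysis_data/ (trees, traits, images, votes, ground truth)
and a dataset summary table under results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import ANALYSIS_SPEC, DATA, RESULTS, ensure_dataset


def main():
    ensure_dataset()
    traits = pd.read_csv(DATA / "traits.csv")
    manifest = pd.read_csv(DATA / "manifest.csv")
    trait_cols = ["mass_g", "flock_size", "colonial", "n_predators", "activity"]
    summary = pd.DataFrame(
        {
            "quantity": [
                "species",
                "species_with_missing_traits",
                "museum_species",
                "images",
                "museum_images",
                "scorers",
                "trees",
            ],
            "value": [
                len(traits),
                int(traits[trait_cols].isna().any(axis=1).sum()),
                int(traits["has_museum_image"].sum()),
                len(manifest),
                int((manifest["source"] == "museum").sum()),
                ANALYSIS_SPEC.n_scorers,
                ANALYSIS_SPEC.n_trees,
            ],
        }
    )
    summary.to_csv(RESULTS / "01_dataset_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"\ndataset written to {DATA}")


if __name__ == "__main__":
    main()
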