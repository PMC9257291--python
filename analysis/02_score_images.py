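"""RMS-contrast score the museum wing images.

Removes the key-colour background, converts to greyscale, and computes the
RMS contrast (sample SD of wing-pixel grey values) per image, then averages
within species. Also checks that truly contrasting wings score higher than
non-contrasting ones — the link between the imaging construct and the
scorers' task.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA, RESULTS, ensure_dataset

from wingcontrast.imaging import score_manifest, species_rms


def main():
    ensure_dataset()
    manifest = pd.read_csv(DATA / "manifest.csv").fillna({"path": ""})
    museum = manifest[(manifest["source"] == "museum") & (manifest["path"] != "")]
    per_image = score_manifest(museum, background="key:#FF00FF", root=DATA)
    per_species = species_rms(per_image)
    per_image.to_csv(RESULTS / "02_image_rms.csv", index=False)
    per_species.to_csv(RESULTS / "02_rms_scores.csv", index=False)

    merged = per_image.merge(museum[["image_id", "truth_contrasting"]], on="image_id")
    means = merged.groupby("truth_contrasting")["rms"].mean()
    print(f"{len(per_image)} museum images scored, {len(per_species)} species")
    print(f"mean RMS contrast: contrasting wings {means.get(True, float('nan')):.1f}, "
          f"non-contrasting {means.get(False, float('nan')):.1f}")


if __name__ == "__main__":
    main()
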