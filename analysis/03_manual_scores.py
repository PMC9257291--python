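"""Aggregate the 30-scorer vote panel into manual contrast scores.

An image's score is the number of scorers who classified it as contrasting
(0–30); a species' score is the mean over its images.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA, RESULTS, ensure_dataset

from wingcontrast.scoring import read_votes_csv, species_scores


def main():
    ensure_dataset()
    votes = read_votes_csv(DATA / "votes.csv")
    manifest = pd.read_csv(DATA / "manifest.csv")
    scores = species_scores(votes, manifest)
    scores.to_csv(RESULTS / "03_manual_scores.csv", index=False)
    print(f"{len(scores)} species scored by {votes.n_scorers} scorers")
    print(
        f"manual score mean {scores['manual_score'].mean():.2f}, "
        f"range {scores['manual_score'].min():.0f}-{scores['manual_score'].max():.0f}"
    )


if __name__ == "__main__":
    main()
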