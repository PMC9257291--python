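"""Manual contrast scores from a multi-scorer vote panel.

Each of S scorers classifies every image as contrasting (1) or
non-contrasting (0). An image's manual contrast score is the number of
contrasting votes it received (0..S); a species' score is the arithmetic
mean over its images. The canonical scale is the vote COUNT — with a
30-scorer panel scores range 0–30 — and a proportion accessor is provided
for convenience.

The design is complete by construction: every scorer scores every image, and
ragged panels are rejected rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class VoteMatrix:
    """Image x scorer binary classification matrix (1 = contrasting)."""

    image_ids: list
    scorer_ids: list
    votes: np.ndarray

    def __post_init__(self):
        self.votes = np.asarray(self.votes)
        if self.votes.shape != (len(self.image_ids), len(self.scorer_ids)):
            raise ValueError("votes shape must be (n_images, n_scorers)")
        if len(self.scorer_ids) < 1:
            raise ValueError("need at least one scorer")
        if not np.isin(self.votes, (0, 1)).all():
            raise ValueError("votes must be binary (0/1) with no missing entries")

    @property
    def n_scorers(self) -> int:
        return len(self.scorer_ids)

    def image_scores(self) -> pd.Series:
        """Count-scale manual score per image (0..S)."""
        return pd.Series(self.votes.sum(axis=1), index=pd.Index(self.image_ids, name="image_id"), name="manual_score")

    def image_proportions(self) -> pd.Series:
        """Proportion-scale score per image (0..1)."""
        return self.image_scores() / self.n_scorers


def score_image(votes_for_image) -> int:
    """Manual score of one image: the count of contrasting votes."""
    v = np.asarray(votes_for_image)
    if v.size < 1:
        raise ValueError("need at least one vote")
    if not np.isin(v, (0, 1)).all():
        raise ValueError("votes must be binary 0/1")
    return int(v.sum())


def score_species(image_scores) -> float:
    """Species score: arithmetic mean of its image scores."""
    s = np.asarray(image_scores, dtype=float)
    if s.size < 1:
        raise ValueError("species has no scored images")
    return float(s.mean())


def species_scores(votes: VoteMatrix, manifest: pd.DataFrame) -> pd.DataFrame:
    """Average image scores within species.

    ``manifest`` maps image_id -> species_id; every image in the vote matrix
    must appear exactly once. Returns (species_id, n_images, manual_score).
    """
    mapping = manifest.set_index("image_id")["species_id"]
    missing = [i for i in votes.image_ids if i not in mapping.index]
    if missing:
        raise ValueError(f"images missing from manifest: {missing[:5]}")
    per_image = votes.image_scores().to_frame()
    per_image["species_id"] = mapping.reindex(per_image.index).to_numpy()
    out = (
        per_image.groupby("species_id", sort=True)["manual_score"]
        .agg(["size", "mean"])
        .rename(columns={"size": "n_images", "mean": "manual_score"})
        .reset_index()
    )
    return out


def read_votes_csv(path) -> VoteMatrix:
    """Read votes from CSV: long (image_id, scorer_id, vote) or wide matrix.

    Wide format: first column image_id, remaining columns one per scorer.
    A ragged long table (a scorer missing some images) is an error.
    """
    df = pd.read_csv(path)
    if {"image_id", "scorer_id", "vote"}.issubset(df.columns):
        wide = df.pivot(index="image_id", columns="scorer_id", values="vote")
        if wide.isna().any().any():
            raise ValueError("ragged vote panel: some scorer/image pairs are missing")
        return VoteMatrix(list(wide.index), list(wide.columns), wide.to_numpy(dtype=int))
    first = df.columns[0]
    wide = df.set_index(first)
    if wide.isna().any().any():
        raise ValueError("missing votes in wide matrix")
    return VoteMatrix(list(wide.index), list(wide.columns), wide.to_numpy(dtype=int))


def write_votes_csv(votes: VoteMatrix, path) -> None:
    pd.DataFrame(votes.votes, index=pd.Index(votes.image_ids, name="image_id"), columns=votes.scorer_ids).to_csv(path)
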