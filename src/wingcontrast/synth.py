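"""Synthetic data generator: every input the pipeline needs, with known
ground truth.

The generator emulates the study's data structure at its real scale by
default — 1980 species (200 of them with at least one missing trait), 682
species carrying museum-style images of which 17 have missing traits (so
665 survive the filter), 30 scorers — with every count a parameter so tests
can shrink it. The generative model for the response is exactly the model
the inference assumes:

    y = X beta + u + e,  u ~ N(0, lambda * s2 * A),  e ~ N(0, (1-lambda) * s2 * I)

with A the unit-height tree covariance. Log body mass evolves by Brownian
motion on the same tree, so predictors carry phylogenetic signal, the
confounding the real analysis faces. Wing images are ellipses of coloured
patches on a removable key-colour background; an image is truly
"contrasting" when at least two colours each cover more than 5% of its
patches. Scorers vote the truth, flipped independently with a configurable
error rate. All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from wingcontrast.phylo import Phylogeny, simulate_yule, vcv_from_tree
from wingcontrast.scoring import VoteMatrix
from wingcontrast.traits import build_design

#: Table-2-scale fixed effects used as simulation defaults
#: (intercept, nocturnal, colonial, log_mass_c, log_flock_c, sqrt_pred_c,
#:  colonial x log_mass_c)
DEFAULT_BETA = {
    "intercept": 10.276,
    "nocturnal": -7.241,
    "colonial": 0.789,
    "log_mass_c": 0.700,
    "log_flock_c": 0.107,
    "sqrt_pred_c": 0.138,
    "colonial_x_log_mass_c": 0.973,
}

KEY_COLOUR = (255, 0, 255)  # magenta backdrop, removable by key matching


@dataclass(frozen=True)
class PatchSpec:
    """Layout of one synthetic wing image."""

    grid: int = 8                       # patch grid is grid x grid cells
    size: int = 64                      # image is size x size pixels
    colour_a: tuple = (40, 40, 40)      # dark patches
    colour_b: tuple = (235, 235, 235)   # light patches
    fraction_b: float = 0.5             # fraction of wing patches in colour_b
    with_alpha: bool = False            # emit RGBA with alpha mask instead of key colour


@dataclass(frozen=True)
class SimulationSpec:
    """Study-scale defaults for the synthetic dataset."""

    n_species: int = 1980
    n_missing: int = 200
    n_museum: int = 682
    n_museum_missing: int = 17          # leaves 665 museum species after filtering
    n_scorers: int = 30
    flip_rate: float = 0.1
    beta_true: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    lambda_true: float = 0.77
    sigma2_total: float = 25.0
    birth_rate: float = 1.0
    max_images_per_species: int = 3
    patch_grid: int = 8
    image_size: int = 64
    colonial_mass_slope: float = 0.0    # logit slope of coloniality on log mass
    n_trees: int = 100

    def __post_init__(self):
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")
        if self.sigma2_total < 0:
            raise ValueError("sigma2_total must be >= 0")
        if not 0.0 <= self.flip_rate <= 0.5:
            raise ValueError("flip_rate must be in [0, 0.5]")
        if self.n_museum > self.n_species:
            raise ValueError("museum count exceeds species count")
        if self.n_museum_missing > min(self.n_missing, self.n_museum):
            raise ValueError("museum missing count inconsistent with totals")
        if self.n_missing > self.n_species:
            raise ValueError("missing count exceeds species count")


@dataclass
class SyntheticDataset:
    """One generated dataset plus its lossless ground-truth record."""

    tree: Phylogeny
    trees: list
    traits: pd.DataFrame
    manifest: pd.DataFrame
    votes: VoteMatrix
    images: dict
    ground_truth: dict


def simulate_traits(tree: Phylogeny, spec: SimulationSpec, seed) -> pd.DataFrame:
    """Per-species predictors with study-style missingness.

    log body mass is Brownian on the tree; flock size log-normal; coloniality
    Bernoulli with an optional mass-dependent logit; predator richness
    Poisson; activity Bernoulli with a small nocturnal probability. Exactly
    ``n_missing`` species get >= 1 missing trait, ``n_museum_missing`` of
    them inside the museum subset.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = tree.tip_labels
    n = len(labels)
    if n != spec.n_species:
        raise ValueError(f"tree has {n} tips but spec.n_species = {spec.n_species}")

    A = vcv_from_tree(tree, scale=True).matrix
    L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    log_mass = 4.0 + 1.5 * (L @ rng.standard_normal(n))        # grams, ~55 g median
    flock = np.exp(rng.normal(1.5, 1.0, n))                    # mean flock size
    logit = -1.7 + spec.colonial_mass_slope * (log_mass - log_mass.mean())
    colonial = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(float)
    predators = rng.poisson(20.0, n).astype(float)
    activity = (rng.random(n) < 0.05).astype(float)

    museum = np.zeros(n, dtype=bool)
    museum[rng.choice(n, size=spec.n_museum, replace=False)] = True

    df = pd.DataFrame(
        {
            "species_id": labels,
            "mass_g": np.exp(log_mass),
            "flock_size": flock,
            "colonial": colonial,
            "n_predators": predators,
            "activity": activity,
            "has_museum_image": museum,
        }
    )

    mus_idx = np.flatnonzero(museum)
    non_idx = np.flatnonzero(~museum)
    chosen = np.concatenate(
        [
            rng.choice(mus_idx, size=spec.n_museum_missing, replace=False),
            rng.choice(non_idx, size=spec.n_missing - spec.n_museum_missing, replace=False),
        ]
    )
    trait_cols = ["mass_g", "flock_size", "colonial", "n_predators", "activity"]
    for i in chosen:
        k = int(rng.integers(1, 3))
        for col in rng.choice(trait_cols, size=k, replace=False):
            df.loc[i, col] = np.nan
    return df


def simulate_response(X, A, beta, lambda_true, sigma2_total, seed) -> np.ndarray:
    """Draw y = X beta + u + e with the stated variance split."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[1] != beta.size:
        raise ValueError("beta length does not match design columns")
    n = X.shape[0]
    A = np.asarray(A, dtype=float)
    if A.shape != (n, n):
        raise ValueError("covariance dimension does not match design rows")
    y = X @ beta
    if sigma2_total > 0:
        s2p = lambda_true * sigma2_total
        s2e = (1.0 - lambda_true) * sigma2_total
        if s2p > 0:
            L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
            y = y + np.sqrt(s2p) * (L @ rng.standard_normal(n))
        if s2e > 0:
            y = y + np.sqrt(s2e) * rng.standard_normal(n)
    return y


def generate_wing_image(patch_spec: PatchSpec, seed) -> tuple[np.ndarray, bool]:
    """Render one wing image and its truth label.

    The wing is an ellipse tiled by a grid of square patches in up to two
    colours, on a magenta key-colour background (or transparent, with
    ``with_alpha``). The truth label is "contrasting" iff at least two
    colours each cover more than 5% of the wing's patches.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g, size = patch_spec.grid, patch_spec.size
    if g < 2:
        raise ValueError("patch grid must be at least 2 x 2")

    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    ellipse = ((xx - cx) / (0.45 * size)) ** 2 + ((yy - cy) / (0.30 * size)) ** 2 <= 1.0

    # patches = grid cells whose centre lies inside the ellipse
    cell = size / g
    centres_y = (np.arange(g) + 0.5) * cell
    centres_x = (np.arange(g) + 0.5) * cell
    in_wing = (
        ((centres_x[None, :] - cx) / (0.45 * size)) ** 2
        + ((centres_y[:, None] - cy) / (0.30 * size)) ** 2
    ) <= 1.0
    wing_cells = np.argwhere(in_wing)
    n_cells = len(wing_cells)
    n_b = int(round(patch_spec.fraction_b * n_cells))
    b_cells = set(map(tuple, wing_cells[rng.choice(n_cells, size=n_b, replace=False)])) if n_b else set()

    frac_b = n_b / n_cells
    label = bool(min(frac_b, 1.0 - frac_b) > 0.05)

    img = np.empty((size, size, 3), dtype=np.uint8)
    img[:] = KEY_COLOUR
    colour_cell = np.empty((g, g, 3), dtype=np.uint8)
    colour_cell[:] = patch_spec.colour_a
    for (i, j) in b_cells:
        colour_cell[i, j] = patch_spec.colour_b
    cell_of_y = np.minimum((yy / cell).astype(int), g - 1)
    cell_of_x = np.minimum((xx / cell).astype(int), g - 1)
    img[ellipse] = colour_cell[cell_of_y[ellipse], cell_of_x[ellipse]]

    if patch_spec.with_alpha:
        rgba = np.dstack([img, np.where(ellipse, 255, 0).astype(np.uint8)])
        return rgba, label
    return img, label


def simulate_scorer_panel(truth_labels, n_scorers: int, flip_rate: float, seed, image_ids=None) -> VoteMatrix:
    """Each scorer votes the truth, flipped independently at ``flip_rate``."""
    if not 0.0 <= flip_rate <= 0.5:
        raise ValueError("flip_rate must be in [0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = np.asarray(truth_labels, dtype=int)[:, None]
    flips = rng.random((truth.shape[0], n_scorers)) < flip_rate
    votes = np.where(flips, 1 - truth, truth)
    if image_ids is None:
        image_ids = [f"img{i + 1:05d}" for i in range(truth.shape[0])]
    return VoteMatrix(list(image_ids), [f"scorer{j + 1:02d}" for j in range(n_scorers)], votes)


def generate_dataset(
    spec: SimulationSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    render_images: bool = True,
) -> SyntheticDataset:
    """Generate the full synthetic study: tree(s), traits, latent response,
    per-image truth labels, scorer votes, and museum wing images.

    Every species gets 1..max_images_per_species images with truth labels
    derived from its latent contrast (so the vote-based manual score tracks
    the generative linear model); pixel rasters are rendered only for
    museum-source images, the ones the RMS pipeline scores. If ``out_dir``
    is given, images, CSVs, Newick trees and ground_truth.json are written
    there; otherwise rasters stay in memory.
    """
    spec = spec or SimulationSpec()
    root = np.random.SeedSequence(seed)
    r_tree, r_traits, r_resp, r_img, r_votes, r_trees = (
        np.random.default_rng(s) for s in root.spawn(6)
    )

    tree = simulate_yule(spec.n_species, spec.birth_rate, r_tree)
    trees = [tree] + [
        simulate_yule(spec.n_species, spec.birth_rate, r_trees) for _ in range(max(spec.n_trees - 1, 0))
    ]
    traits = simulate_traits(tree, spec, r_traits)

    # latent contrast from the complete (pre-missingness) predictors
    complete = traits.fillna(traits.mean(numeric_only=True)).assign(_dummy=0.0)
    design = build_design(complete, response="_dummy")
    beta = np.array([spec.beta_true[nm] for nm in design.names])
    A = vcv_from_tree(tree, scale=True).reorder(design.species_ids).matrix
    latent = simulate_response(design.X, A, beta, spec.lambda_true, spec.sigma2_total, r_resp)
    p_contrast = np.clip(latent / spec.n_scorers, 0.0, 1.0)

    rows, labels, images = [], [], {}
    img_no = 0
    for sp, p, is_museum in zip(traits["species_id"], p_contrast, traits["has_museum_image"]):
        n_img = int(r_img.integers(1, spec.max_images_per_species + 1))
        for _ in range(n_img):
            img_no += 1
            image_id = f"img{img_no:05d}"
            truth = bool(r_img.random() < p)
            frac = float(r_img.uniform(0.2, 0.5)) if truth else float(r_img.uniform(0.0, 0.05))
            rows.append(
                {
                    "species_id": sp,
                    "image_id": image_id,
                    "source": "museum" if is_museum else "field",
                    "truth_contrasting": truth,
                    "path": f"images/{image_id}.png" if is_museum else "",
                }
            )
            labels.append(int(truth))
            if render_images and is_museum:
                pspec = PatchSpec(grid=spec.patch_grid, size=spec.image_size, fraction_b=frac)
                images[image_id], _ = generate_wing_image(pspec, r_img)
    manifest = pd.DataFrame(rows)
    votes = simulate_scorer_panel(labels, spec.n_scorers, spec.flip_rate, r_votes, manifest["image_id"])

    ground_truth = {
        "beta_true": {nm: float(b) for nm, b in zip(design.names, beta)},
        "lambda_true": spec.lambda_true,
        "sigma2_total": spec.sigma2_total,
        "latent_contrast": {sp: float(v) for sp, v in zip(design.species_ids, latent)},
        "seed": seed,
    }

    ds = SyntheticDataset(tree, trees, traits, manifest, votes, images, ground_truth)
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: SyntheticDataset, out: Path) -> None:
    from wingcontrast.phylo import write_tree_set
    from wingcontrast.scoring import write_votes_csv

    out.mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir(exist_ok=True)
    write_tree_set(ds.trees, out / "trees.nwk")
    ds.traits.to_csv(out / "traits.csv", index=False)
    ds.manifest.to_csv(out / "manifest.csv", index=False)
    write_votes_csv(ds.votes, out / "votes.csv")
    for image_id, arr in ds.images.items():
        Image.fromarray(arr).save(out / "images" / f"{image_id}.png")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(ds.ground_truth, fh, indent=1)
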