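"""RMS contrast of wing images.

A wing image is reduced to a single conspicuousness value in three steps:
the background is removed (alpha channel, or a uniform key colour within a
tolerance), the wing pixels are converted to real-valued greyscale, and the
RMS contrast — the sample standard deviation of the masked grey values —
is computed:

    RMS = [ 1/(n-1) * sum_i (x_i - xbar)^2 ]^(1/2)

where x_i is the grey value of wing pixel i. A uniform wing has RMS 0; a
half-black/half-white wing approaches the maximum for the 0–255 scale.
Downstream models use log(RMS), so a small epsilon guards the uniform case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

#: ITU-R BT.601 luma weights; the conventional RGB -> grey projection.
BT601_WEIGHTS = (0.299, 0.587, 0.114)

#: Floor added to RMS before the log for perfectly uniform wings.
LOG_EPS = 1e-6

#: Default Euclidean RGB distance below which a pixel counts as background.
DEFAULT_KEY_TOLERANCE = 10.0


class EmptyMaskError(ValueError):
    """Background removal left no wing pixels."""


class ImageFormatError(ValueError):
    """Image does not match the requested background specification."""


@dataclass(frozen=True)
class ContrastResult:
    """RMS contrast of one masked greyscale image.

    Attributes
    ----------
    rms : float
        Sample standard deviation of the masked grey values (0–255 scale).
    log_rms : float
        Natural log of ``rms`` (``log(rms + 1e-6)`` when rms is 0).
    n_pixels : int
        Number of wing (mask-true) pixels used.
    """

    rms: float
    log_rms: float
    n_pixels: int


def _as_array(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ImageFormatError(
            f"expected an H x W x 3 or H x W x 4 image, got shape {arr.shape}"
        )
    if arr.size == 0:
        raise ImageFormatError("empty image")
    return arr


def parse_background_spec(spec: str):
    """Parse a background spec string: ``"alpha"`` or ``"key:#RRGGBB"``."""
    if spec == "alpha":
        return "alpha"
    if spec.startswith("key:#") and len(spec) == len("key:#RRGGBB"):
        hexpart = spec[len("key:#"):]
        rgb = tuple(int(hexpart[i : i + 2], 16) for i in (0, 2, 4))
        return rgb
    raise ValueError(f"unrecognised background spec {spec!r}")


def remove_background(
    image,
    background: str | tuple[int, int, int] = "alpha",
    tolerance: float = DEFAULT_KEY_TOLERANCE,
) -> np.ndarray:
    """Boolean wing mask: True where the pixel is NOT background.

    Parameters
    ----------
    image : array-like or PIL.Image
        8-bit RGB or RGBA image.
    background : "alpha" or RGB triple (or a ``"key:#RRGGBB"`` string)
        With ``"alpha"`` the mask is alpha > 0. With a key colour, a pixel is
        background when its Euclidean RGB distance to the key is <= tolerance
        (museum backdrops are near-uniform, so a small tolerance suffices).
    tolerance : float
        Key-colour distance threshold, ignored for alpha masks. Must be >= 0.

    Raises
    ------
    EmptyMaskError
        If every pixel is background.
    ImageFormatError
        If ``"alpha"`` is requested on a 3-channel image.
    """
    arr = _as_array(image)
    if isinstance(background, str):
        background = parse_background_spec(background)
    if background == "alpha":
        if arr.shape[2] != 4:
            raise ImageFormatError("alpha background requested but image has no alpha channel")
        mask = arr[:, :, 3] > 0
    else:
        if tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        key = np.asarray(background, dtype=float)
        if key.shape != (3,):
            raise ValueError("key colour must be an RGB triple")
        dist = np.sqrt(((arr[:, :, :3].astype(float) - key) ** 2).sum(axis=2))
        mask = dist > tolerance
    if not mask.any():
        raise EmptyMaskError("background removal produced an empty mask")
    return mask


def to_grayscale(image, weights: tuple[float, float, float] = BT601_WEIGHTS) -> np.ndarray:
    """Real-valued greyscale (0–255) via a weighted RGB projection.

    Default weights are BT.601 luma (0.299 R + 0.587 G + 0.114 B); values are
    kept as floats, never re-quantised, since the RMS is computed on them.
    """
    arr = _as_array(image)
    w = np.asarray(weights, dtype=float)
    return arr[:, :, :3].astype(float) @ w


def rms_contrast(gray: np.ndarray, mask: np.ndarray | None = None) -> ContrastResult:
    """Sample standard deviation of masked grey values (the RMS contrast).

    Uses the n−1 denominator. Requires at least 2 masked pixels. A uniform
    wing yields rms 0 and ``log_rms = log(1e-6)`` with a warning, keeping such
    species in downstream models instead of silently dropping them.
    """
    gray = np.asarray(gray, dtype=float)
    if mask is None:
        mask = np.ones(gray.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != gray.shape:
        raise ValueError("mask shape must match image shape")
    vals = gray[mask]
    n = vals.size
    if n < 2:
        raise ValueError(f"insufficient pixels for RMS contrast (got {n}, need >= 2)")
    rms = float(np.std(vals, ddof=1))
    if rms == 0.0:
        warnings.warn("uniform wing: RMS contrast is 0; log uses epsilon floor", stacklevel=2)
        log_rms = float(np.log(LOG_EPS))
    else:
        log_rms = float(np.log(rms))
    return ContrastResult(rms=rms, log_rms=log_rms, n_pixels=int(n))


def score_image_file(
    path: str | Path,
    background: str = "alpha",
    tolerance: float = DEFAULT_KEY_TOLERANCE,
) -> ContrastResult:
    """Load one PNG/JPEG and return its RMS contrast."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGBA" if im.mode in ("RGBA", "LA", "PA") else "RGB"))
    mask = remove_background(arr, background, tolerance)
    return rms_contrast(to_grayscale(arr), mask)


def score_manifest(
    manifest: pd.DataFrame,
    background: str = "alpha",
    tolerance: float = DEFAULT_KEY_TOLERANCE,
    root: str | Path | None = None,
) -> pd.DataFrame:
    """Score every image in a manifest (species_id, image_id, path, source).

    Returns a frame with one row per image: species_id, image_id, n_pixels,
    rms, log_rms.
    """
    required = {"species_id", "image_id", "path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    rows = []
    for rec in manifest.itertuples(index=False):
        p = Path(rec.path) if root is None else Path(root) / rec.path
        res = score_image_file(p, background, tolerance)
        rows.append(
            {
                "species_id": rec.species_id,
                "image_id": rec.image_id,
                "n_pixels": res.n_pixels,
                "rms": res.rms,
                "log_rms": res.log_rms,
            }
        )
    return pd.DataFrame(rows)


def species_rms(image_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-species RMS: mean of per-image rms, then the log transform.

    Averaging precedes the log so a species' score is the log of its mean
    image contrast (mirrors the species-level averaging of manual scores).
    """
    grouped = image_scores.groupby("species_id", sort=True)["rms"].agg(["mean", "size"])
    out = grouped.rename(columns={"mean": "rms", "size": "n_images"}).reset_index()
    out["log_rms"] = np.where(out["rms"] > 0, np.log(out["rms"].where(out["rms"] > 0)), np.log(LOG_EPS))
    return out[["species_id", "n_images", "rms", "log_rms"]]
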