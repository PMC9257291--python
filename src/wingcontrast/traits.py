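"""Species trait table assembly, transforms, missing-data filter, and VIF.

Predictors: body mass (g, log-transformed), flock size (log), coloniality
(binary, non-colonial baseline), number of sympatric avian predators
(sqrt-transformed), activity time (binary, diurnal baseline), plus a
coloniality x log-mass interaction. Continuous predictors are centred after
the missing-data filter; logs are natural logs (recorded in the design
metadata, since slope scales depend on the base).

A species with any missing value among the five traits — or a missing
response — is removed before modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRAIT_COLUMNS = ["mass_g", "flock_size", "colonial", "n_predators", "activity"]

#: column names of the full design, in fixed order (intercept first)
FULL_TERMS = ["intercept", "nocturnal", "colonial", "log_mass_c", "log_flock_c", "sqrt_pred_c", "colonial_x_log_mass_c"]


@dataclass
class DesignMatrix:
    """Response + predictor matrix ready for phylogenetic regression.

    ``offsets`` records the centering constants so raw values can be
    recovered exactly; ``meta`` records transforms and baseline levels.
    """

    y: np.ndarray
    X: np.ndarray
    names: list[str]
    species_ids: list
    offsets: dict[str, float]
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.y)


def filter_missing(table: pd.DataFrame, response: str | None = "manual_score"):
    """Drop species with any missing trait (or missing response).

    Returns ``(filtered, removed_count)``. Idempotent: filtering twice
    removes nothing the second time. Cells that fail to parse as numbers are
    treated as missing.
    """
    cols = [c for c in TRAIT_COLUMNS if c in table.columns]
    check = table[cols].apply(pd.to_numeric, errors="coerce")
    keep = check.notna().all(axis=1)
    if response is not None and response in table.columns:
        keep &= pd.to_numeric(table[response], errors="coerce").notna()
    out = table.loc[keep].copy()
    return out, int(len(table) - len(out))


def build_design(
    table: pd.DataFrame,
    response: str = "manual_score",
    drop: set[str] | None = None,
) -> DesignMatrix:
    """Transform and centre the trait table into a regression design.

    Parameters
    ----------
    table : filtered species table (no missing values in used columns).
    response : ``"manual_score"`` or ``"log_rms"``.
    drop : optional subset of {"activity", "flock_size", "n_predators",
        "colonial", "mass_g"} to omit (the robustness variants). Dropping
        mass or coloniality also drops their interaction.
    """
    drop = set(drop or ())
    unknown = drop - set(TRAIT_COLUMNS)
    if unknown:
        raise ValueError(f"unknown predictors to drop: {sorted(unknown)}")
    if response not in table.columns:
        raise ValueError(f"response column {response!r} not in table")
    if len(table) < 2:
        raise ValueError("need at least 2 species to build a centred design")
    work = table.copy()
    for col, label in (("mass_g", "body mass"), ("flock_size", "flock size")):
        if col in drop:
            continue
        bad = work.loc[pd.to_numeric(work[col]) <= 0, "species_id"]
        if len(bad):
            raise ValueError(f"nonpositive {label} for species {list(bad[:5])}; log undefined")

    n = len(work)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    offsets: dict[str, float] = {}

    def centred(name: str, raw: np.ndarray) -> np.ndarray:
        mu = float(raw.mean())
        offsets[name] = mu
        return raw - mu

    if "activity" not in drop:
        cols["nocturnal"] = work["activity"].to_numpy(dtype=float)
    if "colonial" not in drop:
        cols["colonial"] = work["colonial"].to_numpy(dtype=float)
    if "mass_g" not in drop:
        cols["log_mass_c"] = centred("log_mass_c", np.log(work["mass_g"].to_numpy(dtype=float)))
    if "flock_size" not in drop:
        cols["log_flock_c"] = centred("log_flock_c", np.log(work["flock_size"].to_numpy(dtype=float)))
    if "n_predators" not in drop:
        cols["sqrt_pred_c"] = centred("sqrt_pred_c", np.sqrt(work["n_predators"].to_numpy(dtype=float)))
    if "colonial" not in drop and "mass_g" not in drop:
        cols["colonial_x_log_mass_c"] = cols["colonial"] * cols["log_mass_c"]

    names = [t for t in FULL_TERMS if t in cols]
    X = np.column_stack([cols[t] for t in names])
    for name in names:
        if name != "intercept" and np.ptp(X[:, names.index(name)]) == 0:
            warnings.warn(f"degenerate constant column {name!r}", stacklevel=2)
    y = work[response].to_numpy(dtype=float)
    meta = {
        "response": response,
        "log_base": "e",
        "baselines": {"activity": "diurnal", "colonial": "non-colonial"},
        "transforms": {"mass_g": "log", "flock_size": "log", "n_predators": "sqrt"},
        "dropped": sorted(drop),
    }
    return DesignMatrix(
        y=y, X=X, names=names, species_ids=list(work["species_id"]), offsets=offsets, meta=meta
    )


def vif(design: DesignMatrix) -> pd.Series:
    """Variance inflation factors for the main-effect predictors.

    VIF_j = 1 / (1 - R^2_j), R^2_j from an intercept-included OLS of
    predictor j on the other main effects. The interaction column is
    excluded (its centred components inflate VIF mechanically). A perfectly
    collinear column is reported as infinite with a warning.
    """
    main = [nm for nm in design.names if nm != "intercept" and "_x_" not in nm]
    if len(main) < 2:
        raise ValueError("VIF needs at least 2 main-effect predictors")
    idx = [design.names.index(nm) for nm in main]
    M = design.X[:, idx]
    if M.shape[0] <= M.shape[1]:
        raise ValueError("VIF needs more rows than predictors")
    out = {}
    for j, nm in enumerate(main):
        yj = M[:, j]
        Xj = np.column_stack([np.ones(len(yj)), np.delete(M, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ beta
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            warnings.warn(f"constant predictor {nm!r}: VIF undefined, reporting inf", stacklevel=2)
            out[nm] = np.inf
            continue
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"predictor {nm!r} perfectly collinear: VIF infinite", stacklevel=2)
            out[nm] = np.inf
        else:
            out[nm] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def assemble_table(
    traits: pd.DataFrame,
    manual: pd.DataFrame | None = None,
    rms: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join a traits CSV with manual and/or RMS score tables on species_id."""
    out = traits.copy()
    if manual is not None:
        out = out.merge(manual[["species_id", "manual_score"]], on="species_id", how="left")
    if rms is not None:
        out = out.merge(rms[["species_id", "log_rms"]], on="species_id", how="left")
    return out
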