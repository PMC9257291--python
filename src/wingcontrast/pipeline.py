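"""End-to-end run: synthesise (or load) data, score images, aggregate votes,
build the design, fit the phylogenetic mixed model over a tree set, and
write a results directory with a Table-style report.

Every output records the master seed and a hash of the resolved
configuration, so two runs with equal hashes are comparable byte for byte
(except timestamps in the log).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from wingcontrast import __version__
from wingcontrast.imaging import score_manifest, species_rms
from wingcontrast.pcmm import AveragedResult, MCMCSchedule, PriorSpec, fit_tree_set
from wingcontrast.phylo import read_tree_set
from wingcontrast.scoring import read_votes_csv, species_scores
from wingcontrast.synth import SimulationSpec, generate_dataset
from wingcontrast.traits import assemble_table, build_design, filter_missing, vif


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``synth`` (a SimulationSpec field dict) or ``inputs``
    (paths: traits, manifest, votes, trees, image_root) must be given.
    """

    out_dir: str
    synth: dict | None = None
    inputs: dict | None = None
    response: str = "manual_score"
    drop: list = field(default_factory=list)
    background: str = "key:#FF00FF"
    prior: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)
    k_trees: int = 5
    seed: int = 0

    def __post_init__(self):
        if (self.synth is None) == (self.inputs is None):
            raise ValueError("exactly one of synth / inputs must be provided")
        if self.response not in ("manual_score", "log_rms"):
            raise ValueError("response must be 'manual_score' or 'log_rms'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> AveragedResult:
    """Run all stages and write artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    t0 = time.time()

    def log(stage, msg):
        log_lines.append(f"[{time.time() - t0:8.2f}s] {stage}: {msg}")

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- data ---------------------------------------------------------
    if config.synth is not None:
        spec = SimulationSpec(**config.synth)
        ds = stage("synth")(lambda: generate_dataset(spec, seed=config.seed, out_dir=out / "data"))
        traits, manifest, votes = ds.traits, ds.manifest, ds.votes
        trees, image_root = ds.trees, out / "data"
        log("synth", f"{spec.n_species} species, {len(manifest)} images, {spec.n_trees} trees")
    else:
        paths = config.inputs
        traits = pd.read_csv(paths["traits"])
        manifest = pd.read_csv(paths["manifest"])
        if "path" in manifest.columns:
            manifest["path"] = manifest["path"].fillna("")
        votes = read_votes_csv(paths["votes"])
        trees = read_tree_set(paths["trees"])
        image_root = Path(paths.get("image_root", "."))
        log("load", f"{len(traits)} species, {len(manifest)} images, {len(trees)} trees")

    # --- imaging: RMS contrast for museum-source images ---------------
    museum = manifest[(manifest["source"] == "museum") & (manifest["path"] != "")]
    rms_tab = None
    if len(museum):
        per_image = stage("imaging")(
            lambda: score_manifest(museum, background=config.background, root=image_root)
        )
        per_image.to_csv(out / "image_scores.csv", index=False)
        rms_tab = species_rms(per_image)
        rms_tab.to_csv(out / "rms_scores.csv", index=False)
        log("imaging", f"{len(per_image)} museum images scored")

    # --- manual scoring ------------------------------------------------
    manual = stage("manual")(lambda: species_scores(votes, manifest))
    manual.to_csv(out / "manual_scores.csv", index=False)
    log("manual", f"{len(manual)} species scored by {votes.n_scorers} scorers")

    # --- trait table + design ------------------------------------------
    table = assemble_table(traits, manual=manual, rms=rms_tab)
    if config.response == "log_rms":
        table = table[table["log_rms"].notna()]
    filtered, removed = filter_missing(table, response=config.response)
    log("filter", f"removed {removed} species with missing data, retained {len(filtered)}")
    design = stage("design")(lambda: build_design(filtered, response=config.response, drop=set(config.drop)))
    pd.DataFrame(design.X, columns=design.names, index=design.species_ids).assign(
        response=design.y
    ).to_csv(out / "design.csv")
    vifs = vif(design)
    with open(out / "design_meta.json", "w") as fh:
        json.dump(
            {"offsets": design.offsets, "meta": design.meta, "vif": vifs.to_dict(), "n": design.n},
            fh,
            indent=1,
        )
    log("design", f"{design.n} species x {len(design.names)} columns; max VIF {vifs.max():.2f}")

    # --- model fitting over the tree set --------------------------------
    prior = PriorSpec(**config.prior)
    schedule = MCMCSchedule(**{"seed": config.seed, **config.schedule})
    result = stage("fit")(
        lambda: fit_tree_set(
            design.y,
            design.X,
            trees,
            k=min(config.k_trees, len(trees)),
            prior=prior,
            schedule=schedule,
            names=design.names,
            species_ids=design.species_ids,
            seed=config.seed,
        )
    )
    log("fit", f"{result.n_trees} trees averaged; lambda = {result.lambda_mean:.3f}")

    # --- outputs ---------------------------------------------------------
    per_tree = pd.DataFrame(
        [
            dict(zip(f.names, f.mean), lambda_mean=f.lambda_mean, tree=i)
            for i, f in enumerate(result.per_tree)
        ]
    )
    per_tree.to_csv(out / "per_tree_summaries.csv", index=False)
    averaged = pd.DataFrame(
        {
            "trait": result.names,
            "posterior_mean": result.mean,
            "se": result.se,
            "pMCMC": result.pmcmc,
            "ess": result.ess,
        }
    )
    averaged.to_csv(out / "averaged_result.csv", index=False)
    run_manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "lambda_mean": result.lambda_mean,
        "sigma2_phylo": result.sigma2_phylo,
        "sigma2_resid": result.sigma2_resid,
        "n_trees": result.n_trees,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=1)
    _write_report(out / "report.txt", result, config)
    _coefficient_plot(out / "coefficients.png", result)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return result


def _write_report(path, result: AveragedResult, config: RunConfig) -> None:
    lines = [
        f"wingcontrast {__version__}  seed={config.seed}  hash={config.config_hash()}",
        f"model averaging over {result.n_trees} trees  (response: {config.response})",
        f"phylogenetic signal lambda = {result.lambda_mean:.3f}",
        "",
        f"{'trait':<24}{'post.mean':>10}{'s.e.':>8}{'pMCMC':>8}{'ESS':>8}",
    ]
    for j, nm in enumerate(result.names):
        lines.append(
            f"{nm:<24}{result.mean[j]:>10.3f}{result.se[j]:>8.3f}{result.pmcmc[j]:>8.3f}{result.ess[j]:>8.0f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _coefficient_plot(path, result: AveragedResult) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [nm for nm in result.names if nm != "intercept"]
    idx = [result.names.index(nm) for nm in names]
    fig, ax = plt.subplots(figsize=(5, 0.5 * len(names) + 1))
    ax.errorbar(result.mean[idx], range(len(idx)), xerr=1.96 * result.se[idx], fmt="o", capsize=3)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(range(len(idx)), names)
    ax.set_xlabel("posterior mean (±1.96 s.e.)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
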