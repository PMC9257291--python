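"""Validate the manual contrast score against the objective RMS contrast.

Phylogenetic regression of the species manual score on its standardized
log-RMS contrast over the museum subset; reports the slope and the
per-draw Bayesian R^2. A strong positive slope with high R^2 shows the
human panel measures the same construct as the pixel statistic.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA, RESULTS, SEED, SHORT_CHAIN, ensure_dataset

from wingcontrast.pcmm import MCMCSchedule, validation_regression
from wingcontrast.phylo import read_tree_set, vcv_from_tree


def main():
    ensure_dataset()
    manual = pd.read_csv(RESULTS / "03_manual_scores.csv")
    rms = pd.read_csv(RESULTS / "02_rms_scores.csv")
    paired = manual.merge(rms[["species_id", "log_rms"]], on="species_id")
    tree = read_tree_set(DATA / "trees.nwk")[0]
    V = vcv_from_tree(tree, scale=True).reorder(list(paired["species_id"]))

    fit = validation_regression(
        paired["manual_score"], paired["log_rms"], V,
        schedule=MCMCSchedule(**SHORT_CHAIN, seed=SEED),
    )
    out = pd.DataFrame(
        {
            "term": fit.names,
            "posterior_mean": fit.mean.round(3),
            "ci_lower": fit.ci_lower.round(3),
            "ci_upper": fit.ci_upper.round(3),
            "pMCMC": fit.pmcmc.round(4),
        }
    )
    out.to_csv(RESULTS / "06_validation.csv", index=False)
    print(out.to_string(index=False))
    print(f"\nBayesian R^2 = {fit.draws['r2_mean']:.3f} over {len(paired)} museum species")


if __name__ == "__main__":
    main()
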