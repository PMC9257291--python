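"""Shared plumbing for the numbered analysis scripts.

The scripts run the pipeline at a reduced scale (400 species, 10 trees,
shortened chains) so the whole analysis re-runs in about a minute on one
CPU; every stage's computation lives in the ``wingcontrast`` package, the
scripts only narrate and write tables.
"""

from pathlib import Path

from wingcontrast.synth import SimulationSpec

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = ROOT / "scratch" / "analysis_data"

SEED = 2024

ANALYSIS_SPEC = SimulationSpec(
    n_species=400,
    n_missing=40,
    n_museum=140,
    n_museum_missing=6,
    n_trees=10,
)

SHORT_CHAIN = dict(n_iter=15_000, burn_in=1_500, thin=10)


def ensure_dataset():
    """Generate the analysis dataset if it is not on disk yet."""
    from wingcontrast.synth import generate_dataset

    RESULTS.mkdir(exist_ok=True)
    if not (DATA / "ground_truth.json").exists():
        generate_dataset(ANALYSIS_SPEC, seed=SEED, out_dir=DATA)
    return DATA
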