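"""The synthetic-data generator: traits, responses, images, scorer panels."""

import numpy as np
import pandas as pd
import pytest

from wingcontrast.imaging import remove_background, rms_contrast, to_grayscale
from wingcontrast.pcmm import MCMCSchedule, fit_mcmc
from wingcontrast.phylo import simulate_yule, vcv_from_tree
from wingcontrast.scoring import species_scores
from wingcontrast.synth import (
    KEY_COLOUR,
    PatchSpec,
    SimulationSpec,
    SyntheticDataset,
    generate_dataset,
    generate_wing_image,
    simulate_response,
    simulate_scorer_panel,
    simulate_traits,
)
from wingcontrast.traits import build_design, filter_missing

SMALL = SimulationSpec(
    n_species=120, n_missing=20, n_museum=40, n_museum_missing=5, n_trees=2
)


class TestTraits:
    def test_missingness_counts(self):
        tree = simulate_yule(120, 1.0, seed=1)
        t = simulate_traits(tree, SMALL, seed=2)
        assert len(t) == 120
        missing = t[["mass_g", "flock_size", "colonial", "n_predators", "activity"]].isna().any(axis=1)
        assert missing.sum() == 20
        assert (missing & t["has_museum_image"]).sum() == 5
        filtered, removed = filter_missing(t, response=None)
        assert removed == 20 and len(filtered) == 100
        assert filtered["has_museum_image"].sum() == 35

    def test_zero_missing_complete(self):
        spec = SimulationSpec(n_species=50, n_missing=0, n_museum=10, n_museum_missing=0, n_trees=1)
        t = simulate_traits(simulate_yule(50, 1.0, seed=3), spec, seed=4)
        assert not t.drop(columns=["species_id"]).isna().any().any()

    def test_deterministic(self):
        tree = simulate_yule(120, 1.0, seed=1)
        a = simulate_traits(tree, SMALL, seed=9)
        b = simulate_traits(tree, SMALL, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_tip_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            simulate_traits(simulate_yule(10, 1.0, seed=1), SMALL, seed=0)


class TestResponse:
    def test_noiseless_is_exact(self, vcv50, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        y = simulate_response(X, vcv50.matrix, [2.0, 1.0], 0.5, 0.0, 5)
        assert np.allclose(y, X @ [2.0, 1.0])

    @pytest.mark.parametrize("lam", [0.0, 1.0])
    def test_monte_carlo_covariance_oracle(self, lam):
        tree = simulate_yule(10, 1.0, seed=6)
        V = vcv_from_tree(tree, scale=True).matrix
        X = np.zeros((10, 1))
        rng = np.random.default_rng(7)
        reps = np.stack([simulate_response(X, V, [0.0], lam, 1.0, rng) for _ in range(5000)])
        emp = np.cov(reps.T)
        target = np.eye(10) if lam == 0.0 else V
        assert np.abs(emp - target).max() < 0.1

    def test_dimension_mismatch(self, vcv50):
        with pytest.raises(ValueError):
            simulate_response(np.ones((10, 1)), vcv50.matrix, [0.0], 0.5, 1.0, 0)


class TestWingImages:
    def test_two_colour_half_half_is_contrasting(self):
        img, label = generate_wing_image(PatchSpec(fraction_b=0.5), seed=1)
        assert label is True
        assert img.shape == (64, 64, 3)

    def test_single_colour_not_contrasting(self):
        _, label = generate_wing_image(PatchSpec(fraction_b=0.0), seed=1)
        assert label is False

    def test_five_percent_rule(self):
        # a second colour on <=5% of patches does not count as contrasting
        spec = PatchSpec(grid=10, size=100, fraction_b=0.04)
        _, label = generate_wing_image(spec, seed=2)
        assert label is False
        _, label2 = generate_wing_image(PatchSpec(grid=10, size=100, fraction_b=0.2), seed=2)
        assert label2 is True

    def test_alpha_variant_mask(self):
        img, _ = generate_wing_image(PatchSpec(fraction_b=0.5, with_alpha=True), seed=3)
        assert img.shape[2] == 4
        mask = remove_background(img, "alpha")
        assert 0 < mask.sum() < img.shape[0] * img.shape[1]

    def test_key_background_removable_and_grid_too_small(self):
        img, _ = generate_wing_image(PatchSpec(fraction_b=0.5), seed=4)
        mask = remove_background(img, KEY_COLOUR, tolerance=10)
        assert 0 < mask.sum() < img.shape[0] * img.shape[1]
        with pytest.raises(ValueError):
            generate_wing_image(PatchSpec(grid=1), seed=0)

    def test_contrast_separation(self):
        # truth-contrasting images have strictly higher mean RMS contrast
        rngs = range(10)
        def rms_of(frac, s):
            img, _ = generate_wing_image(PatchSpec(fraction_b=frac), seed=s)
            return rms_contrast(to_grayscale(img), remove_background(img, KEY_COLOUR)).rms
        hi = np.mean([rms_of(0.4, s) for s in rngs])
        lo = np.mean([rms_of(0.03, s) for s in rngs])
        assert hi > lo


class TestScorerPanel:
    def test_zero_flip_rate_unanimous(self):
        vm = simulate_scorer_panel([1, 0, 1], 30, 0.0, seed=1)
        assert set(vm.image_scores()) <= {0, 30}
        assert list(vm.image_scores()) == [30, 0, 30]

    def test_half_flip_rate_mean_near_half_panel(self):
        vm = simulate_scorer_panel(np.ones(400, dtype=int), 30, 0.5, seed=2)
        assert vm.image_scores().mean() == pytest.approx(15.0, rel=0.05)

    def test_deterministic(self):
        a = simulate_scorer_panel([1, 0, 1, 1], 10, 0.2, seed=3)
        b = simulate_scorer_panel([1, 0, 1, 1], 10, 0.2, seed=3)
        assert np.array_equal(a.votes, b.votes)

    def test_invalid_flip_rate(self):
        with pytest.raises(ValueError):
            simulate_scorer_panel([1], 5, 0.7, seed=0)


class TestDataset:
    def test_structure_and_determinism(self):
        ds = generate_dataset(SMALL, seed=11, render_images=False)
        assert isinstance(ds, SyntheticDataset)
        assert set(ds.traits["species_id"]) == set(ds.tree.tip_labels)
        assert len(ds.trees) == SMALL.n_trees
        assert len(ds.manifest) == len(ds.votes.image_ids)
        assert set(ds.ground_truth["beta_true"]) >= {"intercept", "log_mass_c"}
        ds2 = generate_dataset(SMALL, seed=11, render_images=False)
        pd.testing.assert_frame_equal(ds.traits, ds2.traits)
        assert np.array_equal(ds.votes.votes, ds2.votes.votes)

    def test_museum_images_rendered_and_written(self, tmp_path):
        spec = SimulationSpec(n_species=30, n_missing=0, n_museum=8, n_museum_missing=0, n_trees=1)
        ds = generate_dataset(spec, seed=12, out_dir=tmp_path)
        museum_imgs = ds.manifest[ds.manifest["source"] == "museum"]
        assert set(ds.images) == set(museum_imgs["image_id"])
        assert (tmp_path / "trees.nwk").exists()
        assert (tmp_path / "ground_truth.json").exists()
        assert all((tmp_path / p).exists() for p in museum_imgs["path"])

    def test_end_to_end_beta_recovery(self):
        # datasets run through scoring + trait prep + the mixed model recover
        # the generating coefficients inside their 95% credible intervals
        beta = {
            "intercept": 15.0,
            "nocturnal": -3.0,
            "colonial": 1.0,
            "log_mass_c": 1.0,
            "log_flock_c": 0.3,
            "sqrt_pred_c": 0.3,
            "colonial_x_log_mass_c": 0.8,
        }
        spec = SimulationSpec(
            n_species=200,
            n_missing=20,
            n_museum=60,
            n_museum_missing=5,
            flip_rate=0.0,
            beta_true=beta,
            lambda_true=0.5,
            sigma2_total=4.0,
            n_trees=1,
        )
        sched = MCMCSchedule(4000, 800, 5, seed=0)
        n_rep = 8
        covered = np.zeros(len(beta))
        for rep in range(n_rep):
            ds = generate_dataset(spec, seed=100 + rep, render_images=False)
            manual = species_scores(ds.votes, ds.manifest)
            table = ds.traits.merge(manual, on="species_id")
            filtered, _ = filter_missing(table)
            design = build_design(filtered)
            V = vcv_from_tree(ds.tree, scale=True).reorder(design.species_ids)
            fit = fit_mcmc(design.y, design.X, V, schedule=sched, names=design.names)
            truth = np.array([beta[nm] for nm in design.names])
            covered += (fit.ci_lower <= truth) & (truth <= fit.ci_upper)
        assert (covered >= n_rep - 2).all(), covered
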