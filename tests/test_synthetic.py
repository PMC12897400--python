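"""The synthetic study generator: trees, traits, assembly, wiring."""

import json

import numpy as np
import pytest

from phylostand.errors import ValidationError
from phylostand.io import load_plots, read_traits
from phylostand.phylo import patristic_distances, read_newick
from phylostand.synthetic import (
    SyntheticConfig,
    assemble_communities,
    generate_study,
    simulate_bm_traits,
    simulate_tree,
)


class TestSimulateTree:
    def test_two_tip_cherry_is_ultrametric(self):
        tree = simulate_tree(2, seed=1)
        depths = [leaf.distance_from_root() for leaf in tree.tree.leaf_node_iter()]
        assert depths[0] == pytest.approx(depths[1], rel=1e-10)

    @pytest.mark.parametrize("n", [2, 5, 17])
    def test_exact_tip_count_and_labels(self, n):
        tree = simulate_tree(n, seed=2)
        assert tree.n_tips == n
        assert len(set(tree.tips)) == n
        assert all(t.startswith("sp") for t in tree.tips)

    def test_ultrametric_within_tolerance(self):
        tree = simulate_tree(40, seed=3)
        depths = np.array(
            [leaf.distance_from_root() for leaf in tree.tree.leaf_node_iter()]
        )
        assert depths.std() / depths.mean() < 1e-10


class TestSimulateBMTraits:
    def test_zero_rate_collapses_to_root_value(self):
        tree = simulate_tree(10, seed=4)
        traits = simulate_bm_traits(tree, sigma2=0.0, root_value=3.5, seed=0)
        assert all(v == pytest.approx(3.5) for v in traits.values())

    def test_tip_variance_scales_with_depth(self):
        """Var(tip trait) across replicates = sigma2 * tip depth (BM)."""
        tree = simulate_tree(6, seed=5)
        tip = tree.tips[0]
        depth = next(
            leaf.distance_from_root()
            for leaf in tree.tree.leaf_node_iter()
            if leaf.taxon.label == tip
        )
        sigma2 = 0.7
        draws = [
            simulate_bm_traits(tree, sigma2=sigma2, seed=s)[tip] for s in range(1000)
        ]
        assert np.var(draws) == pytest.approx(sigma2 * depth, rel=0.10)


@pytest.fixture(scope="module")
def tree_and_traits():
    tree = simulate_tree(25, seed=6)
    traits = simulate_bm_traits(tree, sigma2=1.0, seed=7)
    return tree, traits


class TestAssembleCommunities:
    def test_richness_within_range(self, tree_and_traits):
        tree, traits = tree_and_traits
        config = SyntheticConfig(
            n_pool=25, n_plots=50, richness_range=(4, 9), seed=8
        )
        _, cm = assemble_communities(tree, traits, config)
        richness = cm.presence.sum(axis=1)
        assert richness.min() >= 4 and richness.max() <= 9

    def test_zero_strength_filtering_matches_neutral_mpd(self, tree_and_traits):
        """filter_strength = 0 degenerates to uniform sampling: mean MPD of
        the two regimes agrees within Monte-Carlo error."""
        tree, traits = tree_and_traits
        dist = patristic_distances(tree)
        means = {}
        for mode, strength in (("neutral", 5.0), ("filtering", 0.0)):
            config = SyntheticConfig(
                n_pool=25,
                n_plots=400,
                richness_range=(4, 9),
                assembly_mode=mode,
                filter_strength=strength,
                seed=9,
            )
            _, cm = assemble_communities(tree, traits, config)
            vals = []
            for row in cm.presence:
                idx = np.flatnonzero(row)
                sub = dist.submatrix([cm.species[i] for i in idx]).d
                k = len(idx)
                vals.append(sub.sum() / (k * (k - 1)))
            means[mode] = np.mean(vals)
        assert means["filtering"] == pytest.approx(means["neutral"], rel=0.05)

    def test_repulsion_k2_picks_most_distant_pair_from_start(self):
        """With k = 2 the greedy rule must add the species farthest from
        the randomly drawn start (brute-force check on a 10-tip tree)."""
        tree = simulate_tree(10, seed=10)
        traits = simulate_bm_traits(tree, seed=11)
        dist = patristic_distances(tree)
        config = SyntheticConfig(
            n_pool=10,
            n_plots=30,
            richness_range=(2, 2),
            assembly_mode="repulsion",
            seed=12,
        )
        _, cm = assemble_communities(tree, traits, config)
        for row in cm.presence:
            pair = [cm.species[i] for i in np.flatnonzero(row)]
            i, j = dist.index[pair[0]], dist.index[pair[1]]
            # one member must be the other's farthest partner
            assert (
                dist.d[i].max() == pytest.approx(dist.d[i, j])
                or dist.d[j].max() == pytest.approx(dist.d[j, i])
            )

    def test_richness_above_pool_rejected(self, tree_and_traits):
        tree, traits = tree_and_traits
        config = SyntheticConfig(n_pool=30, n_plots=5, richness_range=(4, 30), seed=0)
        with pytest.raises(ValidationError, match="pool"):
            assemble_communities(tree, traits, config)


class TestGenerateStudy:
    def test_deterministic_output_files(self, tmp_path):
        config = SyntheticConfig(n_pool=20, n_plots=25, richness_range=(3, 6), seed=21)
        a = generate_study(config, out_dir=tmp_path / "a")
        b = generate_study(config, out_dir=tmp_path / "b")
        for name in ("tree_list.csv", "covariates.csv", "traits.csv", "phylogeny.nwk", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_elevation_temperature_collinearity_built_in(self, small_study):
        cov = small_study.covariates
        r = np.corrcoef(np.log(cov["elevation_m"]), cov["mat_c"])[0, 1]
        assert abs(r) > 0.65
        assert small_study.ground_truth["elevation_mat_correlation"] == pytest.approx(r)

    def test_outputs_parse_through_pipeline_readers(self, tmp_path, small_study):
        import warnings

        paths = small_study.write(tmp_path)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # zero warnings at 100% coverage
            plots = load_plots(paths["tree_list"], paths["covariates"])
            traits = read_traits(paths["traits"])
            tree = read_newick(paths["phylogeny"])
        assert len(plots) == small_study.config.n_plots
        assert set(tree.tips) == set(traits.is_conifer)
        gt = json.loads(paths["ground_truth"].read_text())
        assert gt["config"]["seed"] == small_study.config.seed

    def test_conifer_flags_form_one_clade(self, small_study):
        flags = small_study.traits.is_conifer
        n_con = sum(flags.values())
        assert 0 < n_con < len(flags)
        # clade = all tips under a single node; verify monophyly via MRCA
        conifers = [sp for sp, v in flags.items() if v]
        mrca = small_study.tree.tree.mrca(taxon_labels=conifers)
        assert sorted(lf.taxon.label for lf in mrca.leaf_iter()) == sorted(conifers)

    def test_wired_path_coefficients_recovered_without_bias(self):
        """Fitting the generating DAG to emitted studies recovers every
        configured abiotic -> biotic coefficient within +/-0.1.

        Recovery is assessed on coefficients averaged over three replicate
        studies (500 plots each, study-scale 200-species pool) so the check
        targets generator bias rather than single-study sampling noise.
        """
        import phylostand as ps
        from phylostand.model_inference import assemble_plot_table, prepare_table
        from phylostand.sesmpd import ses_mpd
        from phylostand.synthetic import DEFAULT_PATH_COEFFICIENTS

        estimates = {k: [] for k in DEFAULT_PATH_COEFFICIENTS}
        for seed in (201, 202, 203):
            study = generate_study(SyntheticConfig(seed=seed, n_pool=200))
            results = ses_mpd(study.community, study.tree, n_rand=299, seed=seed)
            raw, _ = assemble_plot_table(study.plots, study.traits, results)
            # richness is wired on the linear scale, so fit it untransformed
            table = prepare_table(raw, {"richness": "identity"})
            fit = ps.fit_psem(ps.default_path_model(), table)
            for key in estimates:
                a, b = (s.strip() for s in key.split("->"))
                estimates[key].append(fit.coefficient(a, b))
        for key, truth in DEFAULT_PATH_COEFFICIENTS.items():
            assert np.mean(estimates[key]) == pytest.approx(truth, abs=0.1), key

    def test_invalid_config_lists_all_violations(self):
        config = SyntheticConfig(n_pool=1, birth_rate=-1, richness_range=(5, 99))
        with pytest.raises(ValidationError) as err:
            config.validate()
        for fragment in ("n_pool", "rate", "richness_range"):
            assert fragment in str(err.value)
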