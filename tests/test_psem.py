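"""DAG handling, d-separation basis sets, Fisher's C and pSEM fits."""

import numpy as np
import pandas as pd
import pytest

from _oracles import d_separated
from phylostand.errors import ValidationError
from phylostand.psem import (
    PathModel,
    basis_set,
    default_path_model,
    dsep_pvalues,
    fishers_c,
    fit_psem,
    indirect_effects,
    indirect_paths,
    total_effect,
)
from phylostand.synthetic import (
    DEFAULT_EXO_CORR,
    DEFAULT_SEM_COEFFICIENTS,
    simulate_dag_data,
)


class TestPathModel:
    def test_cycle_rejected(self):
        with pytest.raises(ValidationError, match="cycle"):
            PathModel(["a", "b"], [("a", "b"), ("b", "a")])

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            PathModel(["a", "b"], [("a", "b"), ("a", "b")])

    def test_from_spec_strings(self):
        m = PathModel.from_spec(
            {"nodes": ["a", "b", "c"], "edges": ["a -> b"], "covariances": ["b ~~ c"]}
        )
        assert m.directed_edges == [("a", "b")]
        assert m.free_covariances == [("b", "c")]


class TestBasisSet:
    def test_chain_yields_single_claim(self):
        m = PathModel(["x", "m", "y"], [("x", "m"), ("m", "y")])
        claims = basis_set(m)
        assert len(claims) == 1
        c = claims[0]
        assert {c.x, c.y} == {"x", "y"} and c.conditioning == ("m",)

    def test_complete_dag_has_empty_basis_set(self):
        m = PathModel(["a", "b", "c"], [("a", "b"), ("a", "c"), ("b", "c")])
        assert basis_set(m) == []

    def test_isolated_pair_has_unconditioned_claim(self):
        m = PathModel(["a", "b"], [])
        claims = basis_set(m)
        assert len(claims) == 1
        assert claims[0].conditioning == ()

    def test_free_covariance_removes_claim(self):
        m = PathModel(["a", "b"], [], [("a", "b")])
        assert basis_set(m) == []

    def test_claims_are_dseparations_on_random_dags(self):
        """Every basis-set claim must be an actual d-separation of the DAG
        (exhaustive path-blocking oracle, all DAGs sampled with <= 5 nodes)."""
        rng = np.random.default_rng(12)
        nodes = ["v1", "v2", "v3", "v4", "v5"]
        for _ in range(60):
            edges = [
                (nodes[i], nodes[j])
                for i in range(5)
                for j in range(i + 1, 5)
                if rng.random() < 0.4
            ]
            m = PathModel(nodes, edges)
            for claim in basis_set(m):
                assert d_separated(
                    nodes, edges, claim.x, claim.y, set(claim.conditioning)
                ), f"claim {claim} is not d-separated in {edges}"

    def test_every_nonadjacent_pair_claimed_once(self):
        m = default_path_model()
        claims = basis_set(m)
        adjacent = {frozenset(e) for e in m.directed_edges}
        free = {frozenset(c) for c in m.free_covariances}
        expected = {
            frozenset((a, b))
            for i, a in enumerate(m.nodes)
            for b in m.nodes[i + 1 :]
            if frozenset((a, b)) not in adjacent and frozenset((a, b)) not in free
        }
        assert {frozenset((c.x, c.y)) for c in claims} == expected
        assert len(claims) == len(expected)


class TestDsepPvalues:
    def test_perfect_dependence_has_tiny_p(self):
        x = np.linspace(-1, 1, 100)
        data = pd.DataFrame({"x": x, "y": x})
        m = PathModel(["x", "y"], [])
        (p,) = dsep_pvalues(basis_set(m), data)
        assert p < 1e-50

    def test_null_pvalues_are_uniform(self):
        """x ⟂ y truly -> claim p-values uniform on (0, 1)."""
        from scipy import stats

        rng = np.random.default_rng(13)
        claims = basis_set(PathModel(["x", "y"], []))
        pvals = []
        for _ in range(200):
            data = pd.DataFrame(
                {"x": rng.normal(size=300), "y": rng.normal(size=300)}
            )
            pvals.extend(dsep_pvalues(claims, data))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_claim_list(self):
        assert dsep_pvalues([], pd.DataFrame({"x": [1.0, 2.0]})) == []


class TestFishersC:
    def test_log_of_one_contributes_nothing(self):
        c, df, p = fishers_c([1.0, 1.0])
        assert c == pytest.approx(0.0)
        assert df == 4

    def test_half_half_closed_form(self):
        c, df, p = fishers_c([0.5, 0.5])
        assert c == pytest.approx(4 * np.log(2), rel=1e-12)
        assert df == 4
        assert p == pytest.approx(0.5966, abs=5e-4)

    def test_saturated_model(self):
        assert fishers_c([]) == (0.0, 0, 1.0)

    def test_zero_pvalue_rejected(self):
        with pytest.raises(ValidationError):
            fishers_c([0.0, 0.5])

    def test_order_invariant_and_monotone(self):
        c1, _, _ = fishers_c([0.2, 0.7, 0.4])
        c2, _, _ = fishers_c([0.7, 0.4, 0.2])
        assert c1 == pytest.approx(c2)
        c_smaller_p, _, _ = fishers_c([0.1, 0.7, 0.4])
        assert c_smaller_p > c1


class TestFitPsem:
    def simulate_chain(self, n=500, seed=14):
        rng = np.random.default_rng(seed)
        m = PathModel(["x", "m", "y"], [("x", "m"), ("m", "y")])
        data = simulate_dag_data(m, {"x -> m": 0.6, "m -> y": 0.5}, n, rng)
        return m, data

    def test_chain_recovery_and_fit(self):
        m, data = self.simulate_chain()
        res = fit_psem(m, data)
        assert res.coefficient("x", "m") == pytest.approx(0.6, abs=0.1)
        assert res.coefficient("m", "y") == pytest.approx(0.5, abs=0.1)
        assert res.p_value > 0.05  # the generating DAG is not rejected
        assert res.df == 2

    def test_deleted_edge_detected(self):
        m, data = self.simulate_chain()
        broken = PathModel(["x", "m", "y"], [("x", "m")])
        res = fit_psem(broken, data)
        assert res.p_value < 0.05

    def test_saturated_model_has_zero_c(self):
        m, data = self.simulate_chain()
        sat = PathModel(["x", "m", "y"], [("x", "m"), ("m", "y"), ("x", "y")])
        res = fit_psem(sat, data)
        assert res.fisher_c == 0.0 and res.df == 0 and res.p_value == 1.0

    def test_aic_counts_parameters(self):
        m, data = self.simulate_chain()
        res = fit_psem(m, data)
        # two submodels, each: 1 slope + intercept + error variance
        assert res.n_params == 6
        assert res.aic == pytest.approx(res.fisher_c + 12)

    def test_pruning_removes_spurious_edge(self):
        rng = np.random.default_rng(15)
        m = PathModel(["x", "z", "y"], [("x", "y"), ("z", "y")])
        data = simulate_dag_data(m, {"x -> y": 0.5, "z -> y": 0.0}, 400, rng)
        res = fit_psem(m, data, prune=True)
        assert ("z", "y") in res.removed_edges
        assert res.coefficient("x", "y") == pytest.approx(0.5, abs=0.1)

    def test_total_effect_matches_marginal_slope_on_chain(self):
        """With no confounding, direct + indirect equals the marginal
        regression slope of the target on the source."""
        m, data = self.simulate_chain(n=2000, seed=16)
        res = fit_psem(m, data)
        marginal = np.polyfit(data["x"], data["y"], 1)[0]
        assert total_effect(res, "x", "y") == pytest.approx(marginal, abs=0.02)


class TestIndirectEffects:
    def fitted_default(self):
        rng = np.random.default_rng(17)
        m = default_path_model()
        data = simulate_dag_data(m, DEFAULT_SEM_COEFFICIENTS, 3000, rng, DEFAULT_EXO_CORR)
        return fit_psem(m, data)

    def test_single_path_product(self):
        rng = np.random.default_rng(18)
        m = PathModel(["a", "b", "c"], [("a", "b"), ("b", "c")])
        data = simulate_dag_data(m, {"a -> b": 0.5, "b -> c": -0.4}, 4000, rng)
        res = fit_psem(m, data)
        assert indirect_effects(res, "a", "c") == pytest.approx(-0.2, abs=0.05)

    def test_parallel_paths_sum(self):
        res = self.fitted_default()
        paths = indirect_paths(res, "elevation", "ses")
        assert len(paths) == 3  # via richness, cwm_sla, cwm_mh
        expected = sum(prod for _, prod in paths)
        assert indirect_effects(res, "elevation", "ses") == pytest.approx(expected)

    def test_no_directed_path_gives_zero(self):
        res = self.fitted_default()
        assert indirect_effects(res, "ses", "elevation") == 0.0

    def test_mediated_product_matches_hand_computation(self):
        res = self.fitted_default()
        via_sla = res.coefficient("elevation", "cwm_sla") * res.coefficient(
            "cwm_sla", "ses"
        )
        paths = dict(indirect_paths(res, "elevation", "ses"))
        assert paths[("elevation", "cwm_sla", "ses")] == pytest.approx(via_sla)
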