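"""Composite likelihood, ECM fitting, AIC selection, bootstrap machinery."""

import numpy as np
import pytest

from parapop.demography import (
    FitResult,
    ScenarioSet,
    bootstrap_ci,
    compare_models_aic,
    composite_loglik,
    expected_sfs,
    fit_model,
    generations_to_years,
    hierarchical_selection,
)
from parapop.errors import ValidationError
from parapop.models import DemographicModel, FreeParameter, Population, SplitEvent
from parapop.sfs import JointSFS
from parapop.study import backbone_trio_model, best_split_model, simulate_split_sfs


def single_pop_model(n_dip=2):
    return DemographicModel(
        populations=[Population("A", 10_000.0, 0.0, n_dip)],
        mutation_rate=0.355e-8,
        locus_length=10_000,
    )


class TestExpectedSfs:
    def test_single_population_probabilities_proportional_to_one_over_i(self):
        p = expected_sfs(single_pop_model(), 8000, seed=1)
        expect = (1 / np.arange(1, 4)) / (1 / np.arange(1, 4)).sum()
        assert np.abs(p[1:-1] - expect).max() < 0.02

    def test_probabilities_sum_to_one_over_polymorphic_cells(self):
        p = expected_sfs(best_split_model(), 500, seed=3)
        assert np.isclose(p.sum(), 1.0)
        assert p[0, 0] == 0 and p[-1, -1] == 0

    def test_symmetric_island_model_invariant_under_label_swap(self):
        m = DemographicModel(
            populations=[Population("A", 10_000.0, 0.0, 2), Population("B", 10_000.0, 0.0, 2)],
            splits=[SplitEvent(100_000.0, "B", "A")],
            migration={("A", "B"): 5e-5, ("B", "A"): 5e-5},
        )
        p = np.zeros((5, 5))
        for s in range(4):
            p += expected_sfs(m, 4000, seed=s)
        p /= 4
        assert np.abs(p - p.T).max() < 0.01

    def test_old_split_concentrates_mass_on_private_and_fixed_cells(self):
        def shared_mass(t):
            m = best_split_model(split_time=t, free_split=False)
            p = expected_sfs(m, 3000, seed=2)
            private = p[0, :].sum() + p[:, 0].sum() + p[-1, :].sum() + p[:, -1].sum()
            return 1.0 - private
        assert shared_mass(60_000.0) < shared_mass(1_000.0)


class TestCompositeLoglik:
    def test_arithmetic_example(self):
        # counts 4 and 2 on two polymorphic cells, both probability 0.5
        obs = JointSFS(pop_labels=["A"], sample_sizes=[3], counts=np.array([0, 4, 2, 0]))
        lnl = composite_loglik(obs, np.array([0.0, 0.5, 0.5, 0.0]))
        assert lnl == pytest.approx(6 * np.log(0.5))  # -4.1589

    def test_maximal_when_probabilities_proportional_to_counts(self):
        obs = JointSFS(
            pop_labels=["A"], sample_sizes=[4], counts=np.array([0, 30, 12, 8, 0])
        )
        p_mle = np.array([0.0, 30 / 50, 12 / 50, 8 / 50, 0.0])
        best = composite_loglik(obs, p_mle)
        rng = np.random.default_rng(0)
        for _ in range(20):
            q = rng.dirichlet(np.ones(3))
            assert composite_loglik(obs, np.array([0.0, *q, 0.0])) <= best + 1e-9

    def test_invariant_under_cell_enumeration_order(self):
        counts = np.array([[0, 3, 1], [2, 5, 0], [1, 0, 0]])
        obs = JointSFS(pop_labels=["A", "B"], sample_sizes=[2, 2], counts=counts)
        obs_t = JointSFS(pop_labels=["B", "A"], sample_sizes=[2, 2], counts=counts.T)
        p = np.array([[0.0, 0.2, 0.1], [0.25, 0.3, 0.05], [0.1, 0.0, 0.0]])
        assert np.isclose(composite_loglik(obs, p), composite_loglik(obs_t, p.T))

    def test_shape_mismatch_raises(self):
        obs = JointSFS(pop_labels=["A"], sample_sizes=[2], counts=np.array([0, 4, 2]))
        with pytest.raises(ValidationError):
            composite_loglik(obs, np.array([0.5, 0.5]))


class TestFitModel:
    def test_ecm_matches_brute_force_grid_argmax(self):
        obs = simulate_split_sfs(1500, seed=21)
        model = best_split_model()
        fit = fit_model(obs, model, n_starts=4, n_sims=1000, seed=3)
        # brute-force oracle on the same common-random-number surface
        ss = np.random.SeedSequence(3)
        eval_seed = int(ss.generate_state(21)[-1] % 2**31)
        grid = np.logspace(np.log10(500), np.log10(50_000), 60)
        lls = [
            composite_loglik(
                obs, expected_sfs(model.with_params({"split_time:are": t}), 1000, eval_seed)
            )
            for t in grid
        ]
        t_grid = grid[int(np.argmax(lls))]
        t_ecm = fit.params["split_time:are"]
        # same optimum location up to Monte-Carlo flatness of the surface
        # (bounds span two decades; agreement within 0.15 log10 units)
        assert abs(np.log10(t_grid) - np.log10(t_ecm)) < 0.15

    def test_best_of_starts_contract(self):
        obs = simulate_split_sfs(300, seed=8)
        fit = fit_model(obs, best_split_model(), n_starts=2, n_sims=300, seed=9)
        assert np.isclose(fit.loglik, max(fit.start_logliks))
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)

    def test_mismatched_observation_rejected(self):
        obs = JointSFS(pop_labels=["X"], sample_sizes=[4], counts=np.zeros(5, dtype=int))
        with pytest.raises(ValidationError):
            fit_model(obs, best_split_model(), n_starts=1, n_sims=100, seed=0)


class TestAicComparison:
    def fr(self, model_id, loglik, k, data_hash="h"):
        return FitResult(
            model_id=model_id, params={}, loglik=loglik, k=k,
            aic=2 * k - 2 * loglik, n_starts=1, converged=True, seed=0,
            data_hash=data_hash,
        )

    def test_lower_aic_wins_despite_lower_likelihood(self):
        a = self.fr("simple", -100.0, 3)  # AIC 206
        b = self.fr("complex", -99.0, 5)  # AIC 208
        ranked = compare_models_aic([b, a])
        assert ranked[0].model_id == "simple"

    def test_tie_broken_by_k_then_model_id(self):
        a = self.fr("zeta", -100.0, 3)
        b = self.fr("alpha", -99.0, 4)  # same AIC 206
        assert compare_models_aic([a, b])[0].model_id == "zeta"  # smaller k
        c = self.fr("alpha", -100.0, 3)
        assert compare_models_aic([a, c])[0].model_id == "alpha"  # id tie-break

    def test_single_fit_and_mixed_data_rejected(self):
        with pytest.raises(ValidationError):
            compare_models_aic([self.fr("a", -1.0, 1)])
        with pytest.raises(ValidationError):
            compare_models_aic([self.fr("a", -1.0, 1), self.fr("b", -1.0, 1, "other")])


class TestHierarchicalSelection:
    def test_single_candidate_per_step_is_selected_with_trace(self):
        obs = simulate_split_sfs(300, seed=4)
        steps = [ScenarioSet("only", [best_split_model()])]
        winners, trace = hierarchical_selection(steps, [obs], n_starts=1, n_sims=300, seed=1)
        assert winners[0].model_id == "split_gene_flow"
        assert trace[0]["selected"] and trace[0]["step"] == "only"

    def test_candidate_referencing_pruned_population_rejected(self):
        # data generated under the plain split model; a rival candidate adds an
        # unsampled refugium population with a tiny deep ancestral size, loses
        # step 1, and the refugium is pruned — a step-2 candidate that still
        # references it contradicts the step-1 decision
        obs = simulate_split_sfs(800, seed=4)

        def with_refugium(model_id):
            m = best_split_model()
            m.model_id = model_id
            m.populations.append(Population("REFUGIUM", 500.0))
            m.splits.append(SplitEvent(30_000.0, "LSa", "REFUGIUM"))
            return m

        m_plain = best_split_model()
        m_plain.model_id = "plain"
        steps = [
            ScenarioSet("s1", [m_plain, with_refugium("with_refugium")]),
            ScenarioSet("s2", [with_refugium("still_uses_refugium")]),
        ]
        with pytest.raises(ValidationError, match="pruned"):
            hierarchical_selection(
                steps, [obs, obs], n_starts=2, n_sims=500, max_cycles=4, seed=2
            )

    def test_step_count_must_match_observations(self):
        with pytest.raises(ValidationError):
            hierarchical_selection([ScenarioSet("s", [best_split_model()])], [])


class TestBootstrap:
    def test_zero_replicates_and_nonconverged_refused(self):
        obs = simulate_split_sfs(200, seed=5)
        fit = fit_model(obs, best_split_model(), n_starts=1, n_sims=200, max_cycles=3, seed=1)
        with pytest.raises(ValidationError):
            bootstrap_ci(fit, obs, n_boot=0, seed=1)
        bad = FitResult(
            model_id="x", params=dict(fit.params), loglik=fit.loglik, k=fit.k,
            aic=fit.aic, n_starts=1, converged=False, seed=0,
            data_hash=fit.data_hash, model=fit.model,
        )
        with pytest.raises(ValidationError):
            bootstrap_ci(bad, obs, n_boot=2, seed=1)

    def test_level_returns_percentiles_of_bootstrap_distribution(self):
        obs = simulate_split_sfs(400, seed=6)
        fit = fit_model(obs, best_split_model(), n_starts=1, n_sims=400, max_cycles=5, seed=2)
        ci, draws = bootstrap_ci(
            fit, obs, n_boot=8, level=0.95, seed=3, n_starts=1, n_sims=400, max_cycles=3
        )
        d = draws["split_time:are"]
        lo, hi = ci["split_time:are"]
        assert lo == pytest.approx(np.percentile(d, 2.5))
        assert hi == pytest.approx(np.percentile(d, 97.5))


class TestGenerationsToYears:
    def test_study_range_conversion(self):
        assert generations_to_years(6007, 2) == 12_014
        assert generations_to_years(6007, 1) == 6007
        assert generations_to_years(0, 2) == 0
        assert generations_to_years(6007, (1, 2)) == (6007, 12_014)

    def test_nonpositive_generation_time_rejected(self):
        with pytest.raises(ValidationError):
            generations_to_years(10, 0)
        with pytest.raises(ValidationError):
            generations_to_years(-1, 2)
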