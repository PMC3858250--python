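"""Signature construction: ranking, CV cutpoint, PC1 weights, frozen scoring."""

import numpy as np
import pytest

from mrsig.cohort import SimulationConfig, simulate_cohort
from mrsig.containers import ExpressionMatrix
from mrsig.coxph import GeneScreenResult, cox_univariate
from mrsig.screening import zcut_for_p
from mrsig.signature import (
    SignatureModel,
    compute_mrs,
    cv_select_threshold,
    fit_signature,
    rank_genes,
)

from conftest import make_outcomes


def _result(gene, z):
    return GeneScreenResult(gene_id=gene, beta=z, se=1.0, z=z, p=0.5, analysis="cox")


class TestRankGenes:
    def test_orders_by_absolute_z(self):
        ranked = rank_genes([_result("g1", 2.1), _result("g2", -3.5), _result("g3", 0.4)])
        assert [r.gene_id for r in ranked] == ["g2", "g1", "g3"]

    def test_ties_broken_lexicographically(self):
        ranked = rank_genes([_result("b", -2.0), _result("a", 2.0), _result("c", 2.0)])
        assert [r.gene_id for r in ranked] == ["a", "b", "c"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_genes([])


@pytest.fixture(scope="module")
def trained():
    config = SimulationConfig(
        n_samples=150, n_genes=300, n_prognostic=15, effect_size=0.6, seed=21
    )
    cohort = simulate_cohort(config)
    zcut = zcut_for_p(1e-3)
    model = fit_signature(cohort.expression, cohort.outcomes_dss, cutpoint=zcut)
    return config, cohort, model


class TestFitSignature:
    def test_rank_one_submatrix_recovers_latent_direction(self):
        rng = np.random.default_rng(6)
        n, g = 40, 8
        latent = rng.standard_normal(n)
        loadings = rng.uniform(0.5, 1.5, g)
        values = np.outer(loadings, latent) + 1e-9 * rng.standard_normal((g, n))
        matrix = ExpressionMatrix(
            [f"g{i}" for i in range(g)], [f"s{i}" for i in range(n)], values
        )
        t = np.maximum(rng.exponential(np.exp(-0.8 * latent)), 1e-9)
        outcomes = make_outcomes(t, np.ones(n, dtype=int))
        model = fit_signature(matrix, outcomes, cutpoint=0.0)
        # standardized rows all equal +-latent, so PC1 loadings are uniform
        scores = np.array([s.mrs for s in compute_mrs(model, matrix)])
        cos = abs(np.corrcoef(scores, latent)[0, 1])
        assert cos > 0.999

    def test_training_score_has_positive_cox_coefficient(self, trained):
        _, cohort, model = trained
        scores = compute_mrs(model, cohort.expression)
        fit = cox_univariate([s.mrs for s in scores], cohort.outcomes_dss)
        assert fit.beta > 0

    def test_weight_modes_agree_on_the_supervised_direction(self):
        agree = 0
        for seed in range(8):
            config = SimulationConfig(
                n_samples=150, n_genes=200, n_prognostic=15, effect_size=0.6, seed=seed
            )
            cohort = simulate_cohort(config)
            zcut = zcut_for_p(1e-2)
            m_pc = fit_signature(cohort.expression, cohort.outcomes_dss, zcut, "pc1")
            m_co = fit_signature(cohort.expression, cohort.outcomes_dss, zcut, "coef")
            s_pc = [s.mrs for s in compute_mrs(m_pc, cohort.expression)]
            s_co = [s.mrs for s in compute_mrs(m_co, cohort.expression)]
            agree += np.corrcoef(s_pc, s_co)[0, 1] >= 0.8
        assert agree >= 7

    def test_impossible_cutpoint_instructs_smaller(self, trained):
        _, cohort, _ = trained
        with pytest.raises(ValueError, match="smaller cutpoint"):
            fit_signature(cohort.expression, cohort.outcomes_dss, cutpoint=50.0)

    def test_threshold_is_exact_training_median(self, trained):
        _, cohort, model = trained
        scores = np.array([s.mrs for s in compute_mrs(model, cohort.expression)])
        assert model.mrs_threshold == pytest.approx(np.median(scores), abs=1e-12)

    def test_single_gene_signature_is_standardized_expression(self):
        config = SimulationConfig(
            n_samples=100, n_genes=50, n_prognostic=1, effect_size=1.0,
            latent_correlation=1.0, seed=5,
        )
        cohort = simulate_cohort(config)
        screen_z = zcut_for_p(1e-4)
        model = fit_signature(cohort.expression, cohort.outcomes_dss, screen_z)
        if len(model.selected_genes) == 1:
            g = model.selected_genes[0]
            x = cohort.expression.gene_row(g)
            z = (x - x.mean()) / x.std()
            mrs = np.array([s.mrs for s in compute_mrs(model, cohort.expression)])
            assert abs(np.corrcoef(mrs, z)[0, 1]) == pytest.approx(1.0, abs=1e-9)


class TestComputeMrs:
    def test_even_median_split_is_exact_half(self, trained):
        _, cohort, model = trained
        scores = compute_mrs(model, cohort.expression)
        n = len(scores)
        assert n % 2 == 0
        high = sum(s.group == "high" for s in scores)
        assert high == n // 2  # median split with distinct scores

    def test_expression_at_centers_scores_zero(self, trained):
        _, _, model = trained
        matrix = ExpressionMatrix(
            list(model.selected_genes), ["s0"], model.center[:, None].copy()
        )
        score = compute_mrs(model, matrix)[0]
        assert score.mrs == pytest.approx(0.0, abs=1e-12)

    def test_score_tied_with_threshold_goes_low(self):
        model = SignatureModel(
            endpoint="dss",
            selected_genes=("g",),
            center=np.array([0.0]),
            scale=np.array([1.0]),
            weights=np.array([1.0]),
            weight_mode="coef",
            orientation=+1,
            mrs_threshold=2.0,
        )
        matrix = ExpressionMatrix(["g"], ["a", "b"], np.array([[2.0, 2.5]]))
        groups = [s.group for s in compute_mrs(model, matrix)]
        assert groups == ["low", "high"]  # exact tie is low

    def test_scoring_is_bitwise_deterministic(self, trained):
        _, cohort, model = trained
        a = compute_mrs(model, cohort.expression)
        b = compute_mrs(model, cohort.expression)
        assert [s.mrs for s in a] == [s.mrs for s in b]

    def test_missing_genes_listed(self, trained):
        _, cohort, model = trained
        pruned = cohort.expression.subset_genes(
            [g for g in cohort.expression.gene_ids if g not in model.selected_genes[:2]]
        )
        with pytest.raises(KeyError, match=model.selected_genes[0]):
            compute_mrs(model, pruned)


class TestModelSerialization:
    def test_json_round_trip(self, trained):
        _, cohort, model = trained
        restored = SignatureModel.from_dict(model.to_dict())
        assert restored.selected_genes == model.selected_genes
        a = [s.mrs for s in compute_mrs(model, cohort.expression)]
        b = [s.mrs for s in compute_mrs(restored, cohort.expression)]
        assert a == b


class TestCvSelectThreshold:
    def test_single_candidate_returned(self, trained):
        _, cohort, _ = trained
        zcut, meta = cv_select_threshold(
            cohort.expression, cohort.outcomes_dss, p_grid=(1e-3,), seed=1
        )
        assert zcut == pytest.approx(zcut_for_p(1e-3))
        assert meta["chosen_p"] == 1e-3

    def test_deterministic_given_seed(self, trained):
        _, cohort, _ = trained
        a = cv_select_threshold(cohort.expression, cohort.outcomes_dss, seed=3)
        b = cv_select_threshold(cohort.expression, cohort.outcomes_dss, seed=3)
        assert a[0] == b[0] and a[1] == b[1]

    def test_signal_beats_null_cv_statistic(self):
        """The CV objective at the chosen cutpoint is larger on planted cohorts
        than on matched null cohorts (majority of seeds)."""
        wins = 0
        for seed in range(6):
            kw = dict(n_samples=120, n_genes=150, seed=seed)
            planted = simulate_cohort(
                SimulationConfig(n_prognostic=15, effect_size=0.7, **kw)
            )
            null = simulate_cohort(
                SimulationConfig(n_prognostic=0, effect_size=0.0, **kw)
            )
            _, meta_p = cv_select_threshold(
                planted.expression, planted.outcomes_dss, seed=seed
            )
            _, meta_n = cv_select_threshold(
                null.expression, null.outcomes_dss, seed=seed
            )
            wins += max(meta_p["cv_statistic"]) > max(meta_n["cv_statistic"])
        assert wins >= 5

    def test_chosen_cutpoint_admits_planted_genes(self, trained):
        config, cohort, _ = trained
        zcut, _ = cv_select_threshold(cohort.expression, cohort.outcomes_dss, seed=2)
        model = fit_signature(cohort.expression, cohort.outcomes_dss, zcut)
        planted = set(cohort.truth)
        assert len(planted & set(model.selected_genes)) >= len(planted) / 2
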