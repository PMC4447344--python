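import numpy as np
import pytest

from qbdspace import (
    QuadraticResponseSurface,
    StepwiseQuadraticRSM,
    alpha_sweep,
    design_matrix,
    ols_fit,
    stepwise_select,
)
from qbdspace.datasets import default_synthetic_spec, generate_synthetic
from qbdspace.rsm import TERMS, DesignCache, FitError, stepwise_batch, term_matrix

from conftest import STUDY_COEFS, STUDY_R2, STUDY_TERM_SETS


class TestDesignMatrix:
    def test_empty_terms_is_intercept_column(self):
        X = design_matrix(np.array([[0.5, -1.0, 0.0]]), terms=())
        np.testing.assert_array_equal(X, [[1.0]])

    def test_interaction_and_square_columns(self):
        row = design_matrix(np.array([[1.0, -1.0, 0.0]]))
        # columns: 1, X1, X2, X3, X1X2, X1X3, X2X3, X1^2, X2^2, X3^2
        np.testing.assert_allclose(row[0], [1, 1, -1, 0, -1, 0, 0, 1, 1, 0])

    def test_study_run4_cross_terms(self, design):
        coded = design.coded_settings()
        F = term_matrix(coded)
        # run 4: 1 h, 10 g/g, 3 extractions -> coded (-1/3, 1, 1)
        assert F[3, TERMS.index("X2X3")] == pytest.approx(1.0)
        assert F[3, TERMS.index("X1X3")] == pytest.approx(-1.0 / 3.0)


class TestOLS:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            X = rng.uniform(-1, 1, size=(15, 3))
            y = rng.normal(size=15)
            terms = tuple(rng.choice(TERMS, size=rng.integers(1, 8), replace=False))
            model = QuadraticResponseSurface(terms=terms).fit(X, y)
            A = design_matrix(X, terms=model.terms_)
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            assert model.intercept_ == pytest.approx(beta[0], abs=1e-8)
            np.testing.assert_allclose(model.coef_, beta[1:], atol=1e-8)

    def test_matches_statsmodels_inference(self, design):
        sm = pytest.importorskip("statsmodels.api")
        terms = STUDY_TERM_SETS["danshensu"]
        model = ols_fit(design, "danshensu", terms)
        A = design_matrix(design.coded_settings(), terms=model.terms_)
        ref = sm.OLS(design.response("danshensu"), A).fit()
        np.testing.assert_allclose(
            np.r_[model.intercept_, model.coef_], ref.params, atol=1e-10
        )
        np.testing.assert_allclose(model.pvalues_, ref.pvalues[1:], atol=1e-10)
        assert model.r2_ == pytest.approx(ref.rsquared, abs=1e-10)
        assert model.r2_adj_ == pytest.approx(ref.rsquared_adj, abs=1e-10)

    def test_four_point_hand_solution(self):
        X = np.array([[-1, 0, 0], [0, 0, 0], [0, 0, 0], [1, 0, 0]], dtype=float)
        y = np.array([1.0, 2.0, 2.2, 3.0])
        m = QuadraticResponseSurface(terms=("X1",)).fit(X, y)
        assert m.coef_[0] == pytest.approx(1.0)
        assert m.intercept_ == pytest.approx(2.05)

    def test_noiseless_interpolation_recovers_coefficients(self, design):
        coded = design.coded_settings()
        truth = np.array([5.0, 1.0, -0.5, 2.0, 0.3, 0.0, 0.0, 0.0, -0.7, 0.4])
        y = np.column_stack([np.ones(len(coded)), term_matrix(coded)]) @ truth
        terms = ("X1", "X2", "X3", "X1X2", "X2^2", "X3^2")
        m = QuadraticResponseSurface(terms=terms).fit(coded, y)
        assert m.r2_ == pytest.approx(1.0, abs=1e-12)
        assert m.sse_ == pytest.approx(0.0, abs=1e-18)
        expected = {"X1": 1.0, "X2": -0.5, "X3": 2.0, "X1X2": 0.3, "X2^2": -0.7, "X3^2": 0.4}
        for t, c in zip(m.terms_, m.coef_):
            assert c == pytest.approx(expected[t], abs=1e-10)

    def test_rank_deficiency_raises(self):
        X = np.zeros((8, 3))
        X[:, 0] = np.linspace(-1, 1, 8)
        with pytest.raises(FitError):
            # X2 and X3 are identically zero -> collinear with each other
            QuadraticResponseSurface(terms=("X1", "X2", "X3")).fit(X, np.arange(8.0))


class TestCriteria:
    def test_press_matches_explicit_leave_one_out(self, design):
        for cqa, terms in STUDY_TERM_SETS.items():
            m = ols_fit(design, cqa, terms)
            coded = design.coded_settings()
            y = design.response(cqa)
            press = 0.0
            for i in range(len(y)):
                keep = np.arange(len(y)) != i
                mi = QuadraticResponseSurface(terms=terms).fit(coded[keep], y[keep])
                press += (y[i] - mi.predict(coded[i][None])[0]) ** 2
            assert m.press_ == pytest.approx(press, abs=1e-8, rel=1e-8)

    def test_perfect_and_intercept_only_fits(self, design):
        coded = design.coded_settings()
        y = 2.0 + 3.0 * coded[:, 0]
        perfect = QuadraticResponseSurface(terms=("X1",)).fit(coded, y)
        assert perfect.r2_ == pytest.approx(1.0)
        assert perfect.r2_adj_ == pytest.approx(1.0)
        null = QuadraticResponseSurface(terms=()).fit(coded, design.response("danshensu"))
        assert null.r2_ == pytest.approx(0.0, abs=1e-12)

    def test_adjusted_below_r2(self, design):
        for cqa, terms in STUDY_TERM_SETS.items():
            m = ols_fit(design, cqa, terms)
            assert m.r2_adj_ <= m.r2_
            assert m.r2_pred_ <= m.r2_


class TestStudyReproduction:
    @pytest.mark.parametrize("cqa", sorted(STUDY_TERM_SETS))
    def test_published_coefficients_reproduced(self, design, cqa):
        m = ols_fit(design, cqa, STUDY_TERM_SETS[cqa])
        tol = 0.5 if cqa == "dry_matter" else 0.005
        printed = STUDY_COEFS[cqa]
        assert m.intercept_ == pytest.approx(printed["Constant"], abs=tol)
        for t, c in zip(m.terms_, m.coef_):
            assert c == pytest.approx(printed[t], abs=tol), t
        r2, r2_adj = STUDY_R2[cqa]
        assert m.r2_ == pytest.approx(r2, abs=0.002)
        assert m.r2_adj_ == pytest.approx(r2_adj, abs=0.002)


class TestStepwise:
    def test_alpha_one_keeps_full_basis(self, design):
        m = stepwise_select(design, "danshensu", 1.0)
        assert set(m.terms_) == set(TERMS)

    @pytest.mark.parametrize("alpha", [0.05, 0.35, 0.5])
    def test_noiseless_single_effect_selected(self, design, alpha):
        coded = design.coded_settings()
        y = 2.0 + 3.0 * coded[:, 0]
        m = StepwiseQuadraticRSM(alpha=alpha).fit(coded, y)
        assert m.terms_ == ("X1",)
        assert m.coef_[0] == pytest.approx(3.0, abs=1e-10)

    @pytest.mark.parametrize("cqa", sorted(STUDY_TERM_SETS))
    def test_study_term_sets_selected_at_alpha_035(self, design, cqa):
        m = stepwise_select(design, cqa, 0.35)
        assert set(m.terms_) == set(STUDY_TERM_SETS[cqa])

    def test_selection_is_a_fixed_point(self, design):
        """No included term would be removed, no excluded one admitted."""
        for cqa in design.cqa_names:
            m = stepwise_select(design, cqa, 0.35)
            assert np.all(m.pvalues_ <= 0.35)
            included = set(m.terms_)
            for t in TERMS:
                if t in included:
                    continue
                trial = ols_fit(design, cqa, m.terms_ + (t,))
                p = trial.pvalues_[trial.terms_.index(t)]
                assert p >= 0.35, (cqa, t, p)

    def test_batch_agrees_with_single_fits(self, design):
        """The grouped engine and one-at-a-time stepwise take the same path."""
        rng = np.random.default_rng(11)
        coded = design.coded_settings()
        cache = DesignCache(coded)
        y0 = design.response("salvianolic_acid_B")
        Y = y0[:, None] * (1 + rng.normal(0, 0.06, size=(15, 64)))
        masks = stepwise_batch(cache, Y, 0.35, 0.35)
        for j in range(Y.shape[1]):
            single = StepwiseQuadraticRSM(alpha=0.35).fit(coded, Y[:, j])
            selected = {TERMS[i] for i in range(9) if (int(masks[j]) >> i) & 1}
            assert selected == set(single.terms_)


class TestAlphaSweep:
    def test_zero_noise_single_sim_equals_point_fit(self):
        spec = default_synthetic_spec(seed=3, noise_rsd=0.0)
        table = generate_synthetic(spec)
        frame = alpha_sweep(table, [0.35], n_sims=1, seed=0)
        for name in table.cqa_names:
            direct = stepwise_select(table, name, 0.35)
            row = frame[(frame.cqa == name)].iloc[0]
            assert row.r2 == pytest.approx(direct.r2_, abs=1e-12)
            assert row.aic == pytest.approx(direct.aic_, abs=1e-9)
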