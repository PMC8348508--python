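"""OLS fitting, validation statistics, Y-scrambling and applicability domain."""

import numpy as np
import pandas as pd
import pytest

from xaqsar.exceptions import (
    SchemaError,
    SingularDesignError,
    UndefinedStatisticError,
)
from xaqsar.synthetic import PlantedTableSpec, gen_planted_table, gen_study_set
from xaqsar.validation import (
    MLRModel,
    ccc,
    external_stats,
    fit_mlr,
    mae,
    predict,
    published_model,
    q2_lmo,
    q2_loo,
    r2,
    rmse,
    validate_model,
    williams_ad,
    y_scramble,
)


def planted(seed=0, n=40, p_decoy=2, sigma=0.0, betas=(3.0, -1.0)):
    return gen_planted_table(
        PlantedTableSpec(n=n, p_decoy=p_decoy, sigma=sigma, betas=betas, beta0=2.0,
                         seed=seed)
    )


class TestFitPredict:
    def test_noiseless_coefficients_recovered(self):
        X, y, names, beta = planted()
        model = fit_mlr(X[names], y)
        assert model.intercept == pytest.approx(2.0, abs=1e-10)
        assert model.coef == pytest.approx([3.0, -1.0], abs=1e-10)

    def test_agrees_with_statsmodels(self):
        """Coefficients and standard errors cross-checked against an
        independent OLS implementation."""
        import statsmodels.api as sm

        X, y, names, _ = planted(seed=3, sigma=0.4)
        model = fit_mlr(X[names], y)
        reference = sm.OLS(y, sm.add_constant(X[names])).fit()
        assert model.intercept == pytest.approx(reference.params.iloc[0])
        assert model.coef == pytest.approx(reference.params.iloc[1:].to_numpy())
        assert model.se_intercept == pytest.approx(reference.bse.iloc[0])
        assert model.se_coef == pytest.approx(reference.bse.iloc[1:].to_numpy())

    def test_constant_response_gives_zero_slopes(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        model = fit_mlr(X, np.full(20, 5.5))
        assert model.intercept == pytest.approx(5.5)
        assert model.coef == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_identity_descriptor(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        model = fit_mlr(pd.DataFrame({"x": x}), x)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        assert model.coef[0] == pytest.approx(1.0)

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "twice_a": 2 * a})
        with pytest.raises(SingularDesignError):
            fit_mlr(X, a + 1)

    def test_predict_requires_model_columns(self):
        model = published_model()
        with pytest.raises(SchemaError):
            predict(model, pd.DataFrame({"ringCplus_sumpc": [1.0]}))

    def test_duplicated_row_duplicates_prediction(self):
        X, y, names, _ = planted(seed=4)
        model = fit_mlr(X[names], y)
        row = X[names].iloc[[0]]
        twice = pd.concat([row, row])
        assert predict(model, twice)[0] == predict(model, twice)[1]


class TestPublishedModel:
    def test_all_zero_descriptors_predict_intercept(self):
        model = published_model()
        X = pd.DataFrame([dict.fromkeys(model.names, 0.0)])
        assert predict(model, X)[0] == pytest.approx(6.176)

    def test_coefficients_as_printed(self):
        model = published_model()
        coef = dict(zip(model.names, model.coef))
        assert coef["fClamdN5B"] == 1.197
        assert coef["fsp2Csp2O8B"] == -0.9
        assert model.p == 6

    def test_single_unit_descriptor_arithmetic(self):
        model = published_model()
        X = pd.DataFrame([dict.fromkeys(model.names, 0.0)])
        X["ringCplus_sumpc"] = 1.0
        assert predict(model, X)[0] == pytest.approx(6.176 + 1.513)


class TestScalarStats:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r2(y, y) == pytest.approx(1.0)
        assert rmse(y, y) == 0.0
        assert mae(y, y) == 0.0
        assert ccc(y, y) == pytest.approx(1.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_ccc_hand_computed_example(self):
        # y=(1,2,3), yhat=(2,3,4): cov=2/3, vars=2/3, bias^2=1 -> 4/7
        assert ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(UndefinedStatisticError):
            ccc([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_ccc_bounded_by_pearson(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            y = rng.normal(size=30)
            yhat = 0.5 * y + rng.normal(0, 0.5, 30)
            assert abs(ccc(y, yhat)) <= abs(np.corrcoef(y, yhat)[0, 1]) + 1e-12


class TestCrossValidation:
    def test_press_identity_matches_explicit_refits(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = pd.Series(rng.normal(size=30))
        loo = q2_loo(X, y)
        press = 0.0
        for i in range(30):
            keep = np.arange(30) != i
            model = fit_mlr(X[keep], y[keep])
            pred = predict(model, X.iloc[[i]])[0]
            press += (y.iloc[i] - pred) ** 2
            assert loo.predictions[i] == pytest.approx(pred, abs=1e-10)
        q2_refit = 1 - press / np.sum((y - y.mean()) ** 2)
        assert loo.q2 == pytest.approx(q2_refit, abs=1e-10)

    def test_perfect_linear_data(self):
        X, y, names, _ = planted()
        assert q2_loo(X[names], y).q2 == pytest.approx(1.0, abs=1e-10)

    def test_q2_never_exceeds_r2(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            X = pd.DataFrame(rng.normal(size=(30, 3)))
            y = rng.normal(size=30)
            model = fit_mlr(X, y)
            r2_tr = r2(y, predict(model, X))
            assert q2_loo(X, y).q2 <= r2_tr + 1e-12

    def test_lmo_reduces_to_loo_with_singleton_groups(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        y = pd.Series(rng.normal(size=12))
        groups = [[i] for i in range(12)]
        assert q2_lmo(X, y, groups=groups) == pytest.approx(
            q2_loo(X, y).q2, abs=1e-10
        )

    def test_lmo_noiseless_and_deterministic(self):
        X, y, names, _ = planted(n=50)
        value = q2_lmo(X[names], y, leave_fraction=0.3, iterations=50, seed=3)
        assert value == pytest.approx(1.0, abs=1e-8)
        again = q2_lmo(X[names], y, leave_fraction=0.3, iterations=50, seed=3)
        assert value == again

    def test_lmo_too_small_groups_rejected(self):
        X, y, names, _ = planted(n=9, p_decoy=0, betas=(1.0, 2.0, 3.0, 4.0, 5.0))
        with pytest.raises(ValueError):
            q2_lmo(X[names], y, leave_fraction=0.5, iterations=3, seed=0)


class TestExternalStats:
    def test_perfect_external_predictions(self):
        X, y, names, _ = planted(seed=11, n=60)
        model = fit_mlr(X[names][:40], y[:40])
        stats = external_stats(model, X[names][40:], y[40:], y[:40])
        for key in ("Q2_F1", "Q2_F2", "Q2_F3", "CCC_ex", "R2_ex", "k", "k_prime"):
            assert stats[key] == pytest.approx(1.0, abs=1e-8), key

    def test_constant_shift_detected_as_bias(self):
        X, y, names, _ = planted(seed=12, n=60)
        model = fit_mlr(X[names][:40], y[:40])
        y_shifted = y[40:] + 1.5
        stats = external_stats(model, X[names][40:], y_shifted, y[:40])
        assert stats["Q2_F1"] < 1.0 - 1e-6
        assert abs(stats["k"] - 1.0) > 1e-3
        assert stats["R2_ex"] == pytest.approx(1.0)  # correlation unharmed

    def test_formulas_against_direct_evaluation(self):
        rng = np.random.default_rng(13)
        X, y, names, _ = planted(seed=13, n=80, sigma=0.5)
        model = fit_mlr(X[names][:60], y[:60])
        y_ext = y[60:].to_numpy()
        yhat = predict(model, X[names][60:])
        stats = external_stats(model, X[names][60:], y_ext, y[:60])
        y_tr = y[:60].to_numpy()
        press = np.sum((y_ext - yhat) ** 2)
        assert stats["Q2_F1"] == pytest.approx(
            1 - press / np.sum((y_ext - y_tr.mean()) ** 2)
        )
        assert stats["Q2_F2"] == pytest.approx(
            1 - press / np.sum((y_ext - y_ext.mean()) ** 2)
        )
        assert stats["Q2_F3"] == pytest.approx(
            1 - (press / len(y_ext)) / (np.var(y_tr))
        )
        assert stats["k"] == pytest.approx(np.sum(y_ext * yhat) / np.sum(y_ext**2))


class TestYScramble:
    def test_deterministic_table(self):
        X, y, names, _ = planted(seed=14, n=50, sigma=0.3)
        a = y_scramble(X[names], y, n_iter=100, seed=5)
        b = y_scramble(X[names], y, n_iter=100, seed=5)
        assert a.table.equals(b.table)

    def test_no_iteration_reproduces_the_real_model(self):
        X, y, names, _ = planted(seed=15, n=40, sigma=0.0)
        result = y_scramble(X[names], y, n_iter=100, seed=6)
        # the unscrambled fit is exact (R2=1); identity permutations are
        # excluded so no scrambled round can reach it
        assert result.r2_max < 1.0 - 1e-9

    def test_strong_model_scrambles_to_noise(self):
        X, y, names, _ = planted(seed=16, n=300, p_decoy=0, sigma=0.3,
                                 betas=(1.5, 0.5, 1.2, -1.0, -1.1, -0.9))
        result = y_scramble(X[names], y, n_iter=100, seed=7)
        assert result.r2_mean < 0.1

    def test_scrambled_r2_shrinks_with_sample_size(self):
        means = []
        for n in (100, 300):
            X, y, names, _ = planted(seed=17, n=n, p_decoy=0, sigma=0.3,
                                     betas=(1.5, 0.5, 1.2, -1.0, -1.1, -0.9))
            means.append(y_scramble(X[names], y, n_iter=100, seed=8).r2_mean)
        assert means[1] < means[0]


class TestWilliamsAD:
    def test_h_star_formula(self):
        X, y, names, _ = planted(seed=18, n=60, sigma=0.2)
        model = fit_mlr(X[names], y)
        ad = williams_ad(model, X[names], y)
        assert ad.h_star == pytest.approx(3 * (2 + 1) / 60)

    def test_training_leverages_sum_to_p_plus_one(self):
        X, y, names, _ = planted(seed=19, n=50, sigma=0.2)
        model = fit_mlr(X[names], y)
        ad = williams_ad(model, X[names], y)
        lev = ad.table.loc[ad.table["set"] == "train", "leverage"]
        assert lev.sum() == pytest.approx(len(names) + 1)
        assert ((lev >= 0) & (lev <= 1)).all()

    def test_intercept_only_model_has_uniform_leverage(self):
        y = np.arange(10.0)
        model = MLRModel(
            names=(), intercept=y.mean(), coef=np.empty(0),
            se_intercept=0.0, se_coef=np.empty(0), n_train=10, s=1.0,
        )
        ad = williams_ad(model, np.empty((10, 0)), y)
        assert ad.table["leverage"].to_numpy() == pytest.approx(np.full(10, 0.1))

    def test_outlier_flagging(self):
        X, y, names, _ = planted(seed=20, n=50, sigma=0.1)
        y = y.copy()
        y.iloc[0] += 10.0  # gross response outlier
        model = fit_mlr(X[names], y)
        ad = williams_ad(model, X[names], y, resid_cut=2.5)
        assert bool(ad.table.iloc[0]["outlier"])


class TestFullReport:
    def test_pipeline_recovers_planted_coefficients_within_3_se(self):
        """End-to-end on synthetic molecules: activities planted from the
        published model are recovered by the descriptor + OLS pipeline."""
        from xaqsar.descriptors import named_descriptor_set, compute_matrix
        from xaqsar.molgraph import parse_molecule

        frame = gen_study_set(300, seed=21, noise_sd=0.3)
        mols = [parse_molecule(s) for s in frame.smiles]
        X = compute_matrix(mols, named_descriptor_set()[:6], ids=frame.id.tolist())
        y = 9.0 - np.log10(frame.ki_nM.to_numpy())
        model = fit_mlr(X, y)
        reference = published_model()
        for name, est, se in zip(model.names, model.coef, model.se_coef):
            true = reference.coef[list(reference.names).index(name)]
            assert abs(est - true) < 3 * se, name

    def test_report_contains_full_statistic_block(self):
        X, y, names, _ = planted(seed=22, n=80, sigma=0.3)
        model, report = validate_model(
            X[names][:60], y[:60], X[names][60:], y[60:],
            lmo_iterations=20, yscr_iterations=100, seed=1,
        )
        expected = {
            "R2_tr", "R2_adj", "RMSE_tr", "MAE_tr", "s", "F", "CCC_tr",
            "Q2_LOO", "RMSE_cv", "CCC_cv", "Q2_LMO", "R2_Yscr", "Q2_Yscr",
            "Kxy", "RMSE_ex", "MAE_ex", "R2_ex", "Q2_F1", "Q2_F2", "Q2_F3",
            "CCC_ex", "Ro2", "Ro2_prime", "k", "k_prime", "h_star",
        }
        assert expected <= set(report.stats)
        for key in ("R2_tr", "Q2_LOO", "Q2_LMO", "Q2_F1", "Q2_F2", "Q2_F3"):
            assert report.stats[key] <= 1.0
        assert report.stats["RMSE_tr"] >= 0
        assert -1.0 <= report.stats["CCC_tr"] <= 1.0
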