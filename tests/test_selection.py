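"""Univariate Cox screen, LASSO refinement and the learner registry."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

import ithsig as it
from ithsig.selection import (
    LEARNER_REGISTRY,
    _patient_level,
    cv_folds,
    fit_learner,
)


def partial_loglik_oracle(beta, x, time, event):
    """Direct Breslow/Efron partial log-likelihood for untied data,
    written from the definition (no ties in the toy sets used)."""
    ll = 0.0
    for i in np.flatnonzero(event):
        at_risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def planted_cohort(seed, n_patients, n_genes=100, n_planted=10, beta=0.5,
                   regions=1):
    cfg = it.SyntheticConfig(
        n_patients=n_patients, regions_per_patient=regions,
        archetypes=[it.GeneArchetype("Q4-like", n_genes, mu=6.0, tau=1.0,
                                     sigma=0.2)],
        planted=it.PlantedSignature(tuple(range(n_planted)),
                                    tuple([beta] * n_planted)),
        baseline_hazard=5e-4, censor_rate=0.3, seed=seed,
    )
    return it.generate_cohort(cfg)


class TestUnivariateCox:
    def test_wald_matches_partial_likelihood_oracle_on_toys(self):
        rng = np.random.default_rng(0)
        for rep in range(5):
            n = 8
            x = rng.normal(size=n)
            time = np.sort(rng.exponential(1, n)) + rng.random(n) * 1e-3
            event = np.ones(n, int)  # uncensored, untied
            expr = pd.DataFrame([x], index=["g"],
                                columns=[f"P{i}" for i in range(n)])
            surv = pd.DataFrame({"time": time, "event": event},
                                index=expr.columns)
            # screen requires >= 10 events, so call the fitter directly
            from ithsig._cox import cox_univariate_batch

            fit = cox_univariate_batch(x[:, None], time, event)
            res = minimize_scalar(
                lambda b: -partial_loglik_oracle(b, x, time, event),
                bounds=(-20, 20), method="bounded",
                options={"xatol": 1e-12},
            )
            assert fit["log_hr"][0] == pytest.approx(res.x, abs=1e-6)
            # oracle SE from the numerical second derivative at the optimum
            h = 1e-4
            d2 = (
                partial_loglik_oracle(res.x + h, x, time, event)
                - 2 * partial_loglik_oracle(res.x, x, time, event)
                + partial_loglik_oracle(res.x - h, x, time, event)
            ) / h**2
            assert fit["se"][0] == pytest.approx(1 / np.sqrt(-d2), rel=1e-4)

    def test_null_type_i_error_calibrated(self):
        # 2000 independent null genes: selected fraction ~ alpha
        rng = np.random.default_rng(202)
        n, G = 200, 2000
        expr = pd.DataFrame(
            rng.normal(size=(G, n)),
            index=[f"g{i}" for i in range(G)],
            columns=[f"P{i}" for i in range(n)],
        )
        surv = pd.DataFrame(
            {"time": rng.exponential(100, n),
             "event": (rng.random(n) < 0.7).astype(int)},
            index=expr.columns,
        )
        res, selected = it.univariate_cox(expr, surv)
        frac = len(selected) / G
        assert abs(frac - 0.05) < 0.015

    def test_true_linear_predictor_is_highly_significant(self):
        cohort, truth = planted_cohort(3, 300)
        expr = cohort.patient_mean_expression()
        lp_gene = truth.linear_predictor.reindex(expr.columns)
        expr.loc["true_lp"] = lp_gene.to_numpy()
        res, selected = it.univariate_cox(expr, cohort.survival)
        assert res.loc["true_lp", "p"] < 1e-6
        assert "true_lp" in selected

    def test_constant_gene_flagged_and_excluded(self):
        rng = np.random.default_rng(5)
        n = 60
        expr = pd.DataFrame(
            {"flat": np.ones(n), "ok": rng.normal(size=n)},
            index=[f"P{i}" for i in range(n)],
        ).T
        surv = pd.DataFrame(
            {"time": rng.exponential(10, n),
             "event": (rng.random(n) < 0.8).astype(int)},
            index=expr.columns,
        )
        res, selected = it.univariate_cox(expr, surv)
        assert not res.loc["flat", "converged"]
        assert "flat" not in selected
        assert res.attrs["n_nonconverged"] == 1


class TestCVFolds:
    def test_depends_only_on_k_seed_and_order(self):
        ids = [f"P{i}" for i in range(40)]
        a = cv_folds(ids, 5, 123)
        b = cv_folds(ids, 5, 123)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, cv_folds(ids, 5, 124))
        assert not np.array_equal(a, cv_folds(ids[::-1], 5, 123))

    def test_folds_are_balanced_partition(self):
        folds = cv_folds([f"P{i}" for i in range(43)], 5, 7)
        sizes = np.bincount(folds, minlength=5)
        assert sizes.sum() == 43
        assert sizes.max() - sizes.min() <= 1


class TestLassoRefine:
    def test_planted_signature_recovery(self):
        cohort, truth = planted_cohort(0, 400, n_genes=500)
        expr = cohort.patient_mean_expression()
        res, sel = it.univariate_cox(expr, cohort.survival)
        genes, table = it.lasso_refine(expr.loc[sel], cohort.survival, seed=123)
        planted = set(truth.betas.index)
        assert len(set(genes) & planted) >= 8
        assert len(set(genes) - planted) <= 15

    def test_duplicated_column_does_not_beat_original(self):
        cohort, _ = planted_cohort(1, 200, n_genes=60)
        expr = cohort.patient_mean_expression()
        res, sel = it.univariate_cox(expr, cohort.survival)
        base_genes, base_table = it.lasso_refine(
            expr.loc[sel], cohort.survival, seed=123
        )
        dup = expr.loc[sel].copy()
        dup.loc["dup_of_first"] = dup.iloc[0]
        dup_genes, dup_table = it.lasso_refine(dup, cohort.survival, seed=123)
        best = base_table["mean_cv_cindex"].max()
        best_dup = dup_table["mean_cv_cindex"].max()
        assert best_dup <= best + 0.02  # collinearity buys no real signal

    def test_reproducible_given_seed(self):
        cohort, _ = planted_cohort(2, 150, n_genes=80)
        expr = cohort.patient_mean_expression()
        _, sel = it.univariate_cox(expr, cohort.survival)
        a, _ = it.lasso_refine(expr.loc[sel], cohort.survival, seed=9)
        b, _ = it.lasso_refine(expr.loc[sel], cohort.survival, seed=9)
        assert a == b


@pytest.fixture(scope="module")
def training():
    cohort, truth = planted_cohort(4, 200, n_genes=15, n_planted=5, beta=0.8)
    X, surv = _patient_level(cohort, list(cohort.genes))
    return X, surv, truth


class TestLearners:
    def test_unavailable_learner_names_registry(self, training):
        X, surv, _ = training
        with pytest.raises(ValueError, match="available"):
            fit_learner(LEARNER_REGISTRY["CoxBoost"], X, surv)

    def test_declared_defaults_match_stated_parameters(self):
        assert LEARNER_REGISTRY["RSF"].params["n_estimators"] == 1000
        gbm = LEARNER_REGISTRY["GBM"].params
        assert gbm["n_estimators"] == 10_000
        assert gbm["learning_rate"] == 0.001
        assert gbm["max_depth"] == 3
        assert gbm["min_samples_leaf"] == 10
        assert LEARNER_REGISTRY["Enet"].params["alpha_grid"] == tuple(
            np.round(np.arange(0.1, 1.0, 0.1), 1)
        )
        assert LEARNER_REGISTRY["CoxBoost"].params == {
            "maxstepno": 500, "K": 10, "type": "verweij"
        }

    def test_stepcox_forward_picks_the_signal_gene_first(self):
        rng = np.random.default_rng(11)
        n = 150
        signal = rng.normal(size=n)
        X = pd.DataFrame(
            {"signal": signal,
             "noise1": rng.normal(size=n),
             "noise2": rng.normal(size=n)},
            index=[f"P{i}" for i in range(n)],
        )
        t = rng.exponential(np.exp(-1.5 * signal)) * 365 + 1
        surv = pd.DataFrame(
            {"time": t, "event": np.ones(n, int)}, index=X.index
        )
        fl = fit_learner(LEARNER_REGISTRY["StepCoxForward"], X, surv)
        nz = fl.coefficients[fl.coefficients != 0]
        assert "signal" in nz.index
        assert abs(nz["signal"]) == nz.abs().max()

    def test_ridge_weak_penalty_approaches_unpenalized_cox(self):
        rng = np.random.default_rng(12)
        n = 300
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        t = rng.exponential(np.exp(-(0.9 * x1 - 0.4 * x2))) * 100 + 1
        surv = pd.DataFrame({"time": t, "event": np.ones(n, int)},
                            index=[f"P{i}" for i in range(n)])
        X = pd.DataFrame({"x1": x1, "x2": x2}, index=surv.index)
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        from ithsig._cox import coxph_fit
        from ithsig.selection import _standardize, _sksurv_y

        Z = _standardize(X)
        weak = CoxPHSurvivalAnalysis(alpha=1e-8)
        weak.fit(Z.to_numpy(), _sksurv_y(surv))
        exact = coxph_fit(Z.to_numpy(), t, np.ones(n, int))
        np.testing.assert_allclose(weak.coef_, exact.beta, atol=1e-4)

    def test_learners_score_higher_risk_higher(self, training):
        X, surv, truth = training
        for name in ("StepCoxForward", "Ridge", "LassoCV", "RSF"):
            fl = fit_learner(LEARNER_REGISTRY[name], X, surv, seed=123)
            assert fl.train_cindex >= 0.5
            pred = fl.predict(X)
            assert it.harrell_cindex(pred, surv) >= 0.5

    def test_null_training_gives_cindex_near_half(self):
        # permuted survival: held-out discrimination collapses to chance
        cohort, _ = planted_cohort(6, 600, n_genes=12, n_planted=4)
        X, surv = _patient_level(cohort, list(cohort.genes))
        rng = np.random.default_rng(77)
        perm = surv.copy()
        perm[["time", "event"]] = perm[["time", "event"]].to_numpy()[
            rng.permutation(len(perm))
        ]
        tr, te = X.index[:200], X.index[200:]
        for name in ("Ridge", "RSF"):
            fl = fit_learner(LEARNER_REGISTRY[name], X.loc[tr],
                             perm.loc[tr], seed=123)
            pred = fl.predict(X.loc[te])
            c = (0.5 if np.ptp(pred.to_numpy()) == 0
                 else it.harrell_cindex(pred, perm.loc[te]))
            assert abs(c - 0.5) < 0.06

    def test_signature_export_round_trips_through_scoring(self, training):
        X, surv, _ = training
        fl = fit_learner(LEARNER_REGISTRY["Ridge"], X, surv, seed=123)
        signature = fl.to_signature("ridge_sig")
        assert signature is not None
        assert len(signature) == fl.n_selected
        rsf = fit_learner(LEARNER_REGISTRY["RSF"], X, surv, seed=123)
        assert rsf.to_signature() is None
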