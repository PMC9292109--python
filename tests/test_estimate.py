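"""Partial correlations, CI tests, effect estimation, prediction and CV."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special

import cpcausal as cp
from cpcausal.errors import EstimationError

from conftest import oriented_true_bivariate, oriented_true_total


def _table(**cols):
    return cp.VariableTable(pd.DataFrame(cols), state="raw")


class TestPartialCorrelation:
    def test_identical_columns_give_unit_correlation(self):
        x = np.arange(10.0)
        t = _table(x=x, y=x.copy(), z=np.random.default_rng(0).normal(size=10))
        assert cp.partial_correlation(t, "x", "y") == pytest.approx(1.0)

    def test_unconditional_case_is_pearson(self):
        rng = np.random.default_rng(1)
        t = _table(x=rng.normal(size=200), y=rng.normal(size=200))
        assert cp.partial_correlation(t, "x", "y") == pytest.approx(
            np.corrcoef(t["x"], t["y"])[0, 1]
        )

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        t = _table(x=rng.normal(size=50), y=rng.normal(size=50),
                   z=rng.normal(size=50))
        assert cp.partial_correlation(t, "x", "y", {"z"}) == pytest.approx(
            cp.partial_correlation(t, "y", "x", {"z"}), abs=1e-14
        )

    def test_single_conditioner_matches_recursive_formula(self):
        """Independent oracle: r_xy.z = (r_xy - r_xz r_yz) / sqrt(...)."""
        rng = np.random.default_rng(3)
        z = rng.normal(size=500)
        x = 0.8 * z + rng.normal(size=500)
        y = -0.5 * z + rng.normal(size=500)
        t = _table(x=x, y=y, z=z)

        def r(a, b):
            return np.corrcoef(t[a], t[b])[0, 1]

        expected = (r("x", "y") - r("x", "z") * r("y", "z")) / math.sqrt(
            (1 - r("x", "z") ** 2) * (1 - r("y", "z") ** 2)
        )
        assert cp.partial_correlation(t, "x", "y", {"z"}) == pytest.approx(
            expected, abs=1e-12
        )

    def test_mediator_conditioning_kills_chain_correlation(self):
        rng = np.random.default_rng(4)
        n = 10_000
        x = rng.normal(size=n)
        m = 1.5 * x + rng.normal(size=n)
        y = 2.0 * m + rng.normal(size=n)
        t = _table(x=x, m=m, y=y)
        assert abs(cp.partial_correlation(t, "x", "y", {"m"})) < 0.05
        assert cp.partial_correlation(t, "x", "y") > 0.5

    def test_rank_deficient_conditioning_is_an_error(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=30)
        t = _table(x=rng.normal(size=30), y=rng.normal(size=30),
                   z1=z, z2=2 * z)
        with pytest.raises(EstimationError, match="rank"):
            cp.partial_correlation(t, "x", "y", {"z1", "z2"})

    def test_too_small_sample_is_an_error(self):
        t = _table(x=[1.0, 2, 3, 4], y=[2.0, 1, 4, 3], z=[0.0, 1, 0, 1])
        with pytest.raises(EstimationError, match="too small"):
            cp.partial_correlation(t, "x", "y", {"z"})


class TestFisherZ:
    def test_null_correlation_has_p_one(self):
        assert cp.fisher_z_test(0.0, 100) == pytest.approx(1.0)

    def test_sign_symmetric(self):
        assert cp.fisher_z_test(0.2, 300, 5) == cp.fisher_z_test(-0.2, 300, 5)

    def test_closed_form_against_independent_cdf(self):
        # erfc-based normal tail, computed without scipy.stats
        for r, n, k in [(0.2, 300, 5), (0.18, 300, 5), (0.05, 50, 0)]:
            z = math.atanh(r) * math.sqrt(n - k - 3)
            expected = float(special.erfc(abs(z) / math.sqrt(2.0)))
            assert cp.fisher_z_test(r, n, k) == pytest.approx(expected,
                                                              rel=1e-12)

    def test_degenerate_correlation_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert cp.fisher_z_test(1.0, 50) == 0.0

    def test_sample_size_precondition(self):
        with pytest.raises(EstimationError):
            cp.fisher_z_test(0.5, 8, 5)


class TestImpliedIndependenceTests:
    def test_empty_statement_list(self, std20k):
        assert cp.test_implied_independencies(std20k, []) == []

    def test_null_model_rarely_rejects(self, std20k, graph):
        results = cp.test_implied_independencies(
            std20k, cp.implied_independencies(graph)
        )
        assert len(results) == 11
        assert sum(r.rejected for r in results) <= 1

    def test_alpha_changes_flags_not_correlations(self, std20k, graph):
        statements = cp.implied_independencies(graph)
        loose = cp.test_implied_independencies(std20k, statements, alpha=0.5)
        strict = cp.test_implied_independencies(std20k, statements,
                                                alpha=1e-6)
        for a, b in zip(loose, strict):
            assert a.r == b.r and a.p == b.p
            assert a.rejected == (a.p < 0.5)
            assert b.rejected == (b.p < 1e-6)

    def test_requires_standardized_table(self, cohort20k):
        with pytest.raises(EstimationError, match="standardized"):
            cp.test_implied_independencies(cohort20k.table, [])


class TestEstimateEffect:
    def test_outcome_regressed_on_itself_copy(self, config):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {c: rng.normal(size=40) for c in config.graph.observed}
        )
        df["SCALE"] = df["GMFM"]
        std = cp.standardize_and_orient(cp.VariableTable(df), config)
        est = cp.estimate_effect(std, config, "SCALE", "bivariate")
        assert est.beta == pytest.approx(1.0)
        assert est.adjustment == frozenset()

    def test_total_effect_recovery_on_simulated_cohort(
        self, std20k, sem, config
    ):
        for exposure in ("Strength", "Spasticity", "GDI", "DMC"):
            est = cp.estimate_effect(std20k, config, exposure, "total")
            truth = oriented_true_total(sem, config, exposure)
            assert est.beta == pytest.approx(truth, abs=0.03), exposure

    def test_estimate_invariant_across_minimal_adjustment_sets(
        self, std20k, sem, config
    ):
        """Any minimal valid set identifies the same total effect."""
        res = cp.adjustment_sets(config.graph, "Spasticity", "GMFM", "total")
        betas = []
        for z in res.sets:
            cols = ["Spasticity"] + sorted(z)
            import statsmodels.api as sm

            fit = sm.OLS(
                std20k["GMFM"].to_numpy(),
                sm.add_constant(std20k.data[cols]),
            ).fit()
            betas.append(float(fit.params["Spasticity"]))
        assert max(betas) - min(betas) < 0.02

    def test_confidence_interval_shape(self, std20k, config):
        est = cp.estimate_effect(std20k, config, "GDI", "total")
        assert est.ci95[0] == pytest.approx(est.beta - 1.96 * est.se, abs=1e-4)
        assert est.ci95[1] > est.ci95[0]


class TestEffectTable:
    def test_all_exposures_and_three_effect_types(self, std20k, config):
        estimates, over, failures = cp.effect_table(std20k, config)
        assert not failures
        assert len(estimates) == len(config.exposures) * 3
        assert set(over) == set(config.exposures)

    def test_gait_total_equals_direct_exactly(self, std20k, config):
        estimates, _, _ = cp.effect_table(std20k, config)
        by_key = {(e.exposure, e.effect_type): e for e in estimates}
        total = by_key[("GDI", "total")]
        direct = by_key[("GDI", "direct")]
        assert total.adjustment == direct.adjustment
        assert total.beta == pytest.approx(direct.beta, abs=1e-12)

    def test_bivariate_matches_total_only_without_open_backdoor(
        self, std20k, sem, config
    ):
        for exposure in config.exposures:
            biv = oriented_true_bivariate(sem, config, exposure)
            tot = oriented_true_total(sem, config, exposure)
            open_path = cp.has_open_noncausal_path(
                config.graph, exposure, "GMFM"
            )
            if open_path:
                assert abs(biv - tot) > 1e-6, exposure
            else:
                assert biv == pytest.approx(tot, abs=1e-12), exposure

    def test_unconfounded_sem_bivariate_equals_total(self):
        # a confounder-free chain: bivariate slope is the total effect
        g = cp.CausalGraph("XMY", [("X", "M"), ("M", "Y")])
        cfg = cp.ModelConfig(
            "chain", g,
            {n: cp.VariableMeta(n, "exposure" if n != "Y" else "outcome", "")
             for n in "XMY"},
            outcome="Y",
        )
        spec = cp.SEMSpec(g, {("X", "M"): 1.2, ("M", "Y"): 0.7},
                          {n: 1.0 for n in "XMY"}, seed=10)
        std = cp.standardize_and_orient(cp.simulate(spec, 20_000).table, cfg)
        tot = cp.estimate_effect(std, cfg, "X", "total")
        biv = cp.estimate_effect(std, cfg, "X", "bivariate")
        se = math.hypot(tot.se, biv.se)
        assert abs(tot.beta - biv.beta) < 4 * se


class TestPredictiveModel:
    def test_recovers_structural_coefficients(self, cohort20k, sem, config):
        """Regressing on all observed predictors recovers the outcome's
        structural equation; torsions (no direct edge) get ~0 weight."""
        fitted = cp.predictive_model(cohort20k.table, config)
        for var in config.exposures:
            raw_beta = sem.edge_coefficients.get((var, "GMFM"), 0.0)
            # predictive units negate contracture degrees
            expected = -raw_beta if var in ("AnkleDF", "KneeExt", "Popliteal",
                                            "HipExt") else raw_beta
            assert abs(fitted.beta[var] - expected) < 3 * fitted.se[var] + 1e-9, var

    def test_exact_fit_on_deterministic_outcome(self, config):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {c: rng.normal(size=200) for c in config.graph.observed}
        )
        df["GMFM"] = 5.0 + 2.0 * df["SCALE"] - 1.0 * df["TibRot"]
        fitted = cp.predictive_model(cp.VariableTable(df), config)
        assert fitted.intercept == pytest.approx(5.0, abs=1e-8)
        assert fitted.beta["SCALE"] == pytest.approx(2.0, abs=1e-8)
        assert fitted.beta["Age"] == pytest.approx(0.0, abs=1e-8)


class TestCrossValidation:
    def test_noiseless_linear_outcome_predicts_perfectly(self, config):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {c: rng.normal(size=120) for c in config.graph.observed}
        )
        df["GMFM"] = 1.0 + 0.5 * df["Strength"] + 0.2 * df["GDI"]
        cv = cp.cross_validate(cp.VariableTable(df), config, k=10, seed=1)
        assert cv.r2_oos == pytest.approx(1.0, abs=1e-6)
        assert cv.mae == pytest.approx(0.0, abs=1e-6)

    def test_every_subject_predicted_once_and_folds_balanced(self, config):
        cohort = cp.cohort_fixture("II", n=105, seed=2)
        cv = cp.cross_validate(cohort.table, config, k=10, seed=3)
        assert cv.predictions["y_pred"].notna().all()
        sizes = cv.predictions["fold"].value_counts()
        assert len(sizes) == 10 and sizes.max() - sizes.min() <= 1

    def test_seed_stability_of_out_of_sample_r2(self, config):
        cohort = cp.cohort_fixture("II", n=300, seed=4)
        r2 = [
            cp.cross_validate(cohort.table, config, k=10, seed=s).r2_oos
            for s in (5, 6)
        ]
        assert abs(r2[0] - r2[1]) < 0.05

    def test_too_many_folds_rejected(self, config):
        cohort = cp.cohort_fixture("II", n=5, seed=0)
        with pytest.raises(EstimationError, match="folds"):
            cp.cross_validate(cohort.table, config, k=10)
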