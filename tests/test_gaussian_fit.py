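"""Multilevel Gaussian scalar-on-function fit: oracles and invariants."""

import numpy as np
import pytest

from lvfda import BasisSpec, FitOptions, SyntheticConfig, fit_sofr_gaussian, generate_cohort
from lvfda.data import SCALAR_COVARIATES
from lvfda.sofr import RankDeficiencyError, build_gaussian_design

from conftest import SMALL_SCALARS


def ridge_oracle(design, lambdas_by_block):
    """Closed-form generalized-ridge solution on the package's design."""
    C, q, p = design.C, design.q, design.p
    pen = np.zeros(q + p)
    for b in design.blocks:
        pen[b.sl] = lambdas_by_block[b.name]
    A = C.T @ C + np.diag(pen)
    return np.linalg.solve(A, C.T @ design.y)


def beta_from_w(design, term, w):
    tm = design.term_maps[term]
    idx = np.concatenate([tm.fixed_idx, tm.rand_idx])
    T = np.hstack([tm.T_fixed, tm.T_rand])
    return design.basis @ (T @ w[idx])


class TestRidgeEquivalence:
    def test_fixed_lambda_fit_matches_closed_form(self, small_cohort):
        lam = {"torsion": 5.0, "gls": 50.0, "rv_free_wall": 2.0}
        opts = FitOptions(scalar_terms=SMALL_SCALARS, fixed_lambda=lam,
                          fixed_random_intercept_ratio=3.0)
        fit = fit_sofr_gaussian(small_cohort, BasisSpec(), opts)
        design = build_gaussian_design(small_cohort, BasisSpec(), opts)
        w = ridge_oracle(design, {**lam, "patient": 3.0})
        for term in lam:
            np.testing.assert_allclose(
                fit.functional_terms[term].beta, beta_from_w(design, term, w),
                atol=1e-8,
            )
        for name in SMALL_SCALARS:
            col, _, s = design.scalar_cols[name]
            assert fit.scalar(name).estimate == pytest.approx(w[col] / s, abs=1e-8)

    def test_constant_response_recovers_intercept(self, small_cohort, small_options):
        import copy

        cohort = copy.deepcopy(small_cohort)
        cohort.sbp[:] = 100.0
        fit = fit_sofr_gaussian(cohort, options=small_options)
        assert fit.scalar("intercept").estimate == pytest.approx(100.0, abs=1e-8)
        for name in SMALL_SCALARS:
            assert fit.scalar(name).estimate == pytest.approx(0.0, abs=1e-8)
        for fc in fit.functional_terms.values():
            np.testing.assert_allclose(fc.beta, 0.0, atol=1e-8)
        assert fit.variance_explained == 1.0


class TestOLSOracle:
    def test_noise_free_data_recovers_ols_solution(self):
        # no random effects, no noise, beta == 0; huge functional penalty;
        # generating effects restricted to the fitted covariates
        cfg = SyntheticConfig(
            n_patients=30, seed=4, sigma_b=0.0, sigma_eps=1e-6,
            functional_effects={}, occasion_slope=-1.5,
            scalar_effects={"age": -0.30, "ultrafiltrate": -0.001,
                            "ivc_diameter": 1.33, "sex": 1.4},
        )
        cohort = generate_cohort(cfg, seed=77)
        huge = {t: 1e9 for t in ("torsion", "gls", "rv_free_wall")}
        opts = FitOptions(scalar_terms=SMALL_SCALARS, fixed_lambda=huge,
                          fixed_random_intercept_ratio=1e9)
        fit = fit_sofr_gaussian(cohort, options=opts)
        design = build_gaussian_design(cohort, BasisSpec(), opts)
        w = ridge_oracle(design, {**huge, "patient": 1e9})
        for name in SMALL_SCALARS:
            col, _, s = design.scalar_cols[name]
            assert fit.scalar(name).estimate == pytest.approx(w[col] / s, abs=1e-8)
            # and the OLS solution recovers the generating truth
            truth = cfg.scalar_effects[name]
            assert fit.scalar(name).estimate == pytest.approx(truth, abs=1e-3)


class TestMixedModelCrossCheck:
    def test_matches_statsmodels_mixedlm(self):
        """With no functional terms the model is a standard random-intercept
        LMM; REML estimates must agree with an independent implementation."""
        smf = pytest.importorskip("statsmodels.formula.api")
        import pandas as pd

        cfg = SyntheticConfig(seed=5, functional_effects={})
        cohort = generate_cohort(cfg, seed=21)
        fit = fit_sofr_gaussian(cohort, options=FitOptions(functional_terms=()))

        rows = []
        for i, sid in enumerate(cohort.subjects):
            for s in range(3):
                for o in range(7):
                    rows.append(dict(
                        sid=sid, occ=o, y=cohort.sbp[i, s, o],
                        **{c: cohort.covariates[c].iloc[i] for c in SCALAR_COVARIATES},
                    ))
        df = pd.DataFrame(rows)
        formula = ("y ~ C(occ) + ultrafiltrate + sex + age + hypertension + "
                   "diabetes + ivc_diameter + dialysis_vintage + lv_mass_indexed")
        ref = smf.mixedlm(formula, df, groups=df["sid"]).fit(reml=True)

        for name in SCALAR_COVARIATES:
            t = fit.scalar(name)
            assert t.estimate == pytest.approx(ref.params[name], rel=1e-5, abs=1e-8)
            assert t.se == pytest.approx(ref.bse[name], rel=1e-3)
        assert fit.sigma_eps == pytest.approx(np.sqrt(ref.scale), rel=1e-4)
        assert fit.sigma_b == pytest.approx(
            np.sqrt(ref.cov_re.iloc[0, 0]), rel=1e-3
        )


class TestPenaltyLimits:
    def test_huge_penalty_forces_linear_beta(self, small_cohort):
        opts = FitOptions(
            scalar_terms=SMALL_SCALARS,
            fixed_lambda={"torsion": 1e10, "gls": 1e10, "rv_free_wall": 1e10},
        )
        fit = fit_sofr_gaussian(small_cohort, options=opts)
        # the wiggly (penalized) component is annihilated: the basis
        # coefficients collapse onto the penalty null space, i.e. they are
        # linear in coefficient index
        coefs = fit.functional_terms["torsion"].coefs
        scale = 1 + np.max(np.abs(coefs))
        assert np.max(np.abs(np.diff(coefs, 2))) < 1e-6 * scale

    def test_infinite_penalty_drops_term(self, small_cohort):
        opts = FitOptions(scalar_terms=SMALL_SCALARS,
                          fixed_lambda={"gls": np.inf})
        fit = fit_sofr_gaussian(small_cohort, options=opts)
        np.testing.assert_array_equal(fit.functional_terms["gls"].beta, 0.0)
        assert fit.global_p["gls"] == 1.0


class TestErrorsAndRandomEffects:
    def test_constant_covariate_raises_informative_error(self, small_cohort):
        import copy

        cohort = copy.deepcopy(small_cohort)
        cohort.covariates["age"] = 50.0
        with pytest.raises(RankDeficiencyError, match="age"):
            fit_sofr_gaussian(cohort, options=FitOptions(scalar_terms=SMALL_SCALARS))

    def test_blups_approach_patient_means_when_noise_vanishes(self):
        # with sigma_eps tiny and strong patient effects, the random
        # intercepts must essentially reproduce each patient's offset
        cfg = SyntheticConfig(n_patients=25, seed=6, sigma_b=12.0, sigma_eps=0.05,
                              functional_effects={})
        cohort = generate_cohort(cfg, seed=13)
        fit = fit_sofr_gaussian(
            cohort, options=FitOptions(scalar_terms=SMALL_SCALARS,
                                       functional_terms=()))
        resid_by_patient = (cohort.sbp.reshape(25, -1).mean(axis=1)
                            - np.asarray(fit.fitted).reshape(25, -1).mean(axis=1)
                            + np.asarray(fit.random_effects))
        np.testing.assert_allclose(
            np.asarray(fit.random_effects), resid_by_patient, atol=0.05
        )

    def test_variance_explained_between_zero_and_one(self, study_cohort):
        fit = fit_sofr_gaussian(study_cohort)
        assert 0.0 <= fit.variance_explained <= 1.0
        assert fit.sigma_b >= 0 and fit.sigma_eps > 0
        for t in fit.scalar_terms:
            assert t.ci_low <= t.estimate <= t.ci_high
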