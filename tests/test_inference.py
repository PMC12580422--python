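"""Confidence bands, global tests and the cluster bootstrap."""

import numpy as np
import pytest

from lvfda import (
    FitOptions,
    SyntheticConfig,
    bootstrap_band,
    fit_sofr_gaussian,
    generate_cohort,
    pointwise_band,
)
from lvfda.simulate import default_torsion_effect

# one functional term and a reduced scalar set keep per-fit cost low enough
# for the replicated simulations
FAST_OPTS = FitOptions(functional_terms=("torsion",), scalar_terms=("age",),
                       include_occasion=False)
NULL_CFG = SyntheticConfig(n_patients=30, occasion_slope=0.0, functional_effects={})


def _null_cohort(seed):
    return generate_cohort(NULL_CFG, seed=seed)


def _strong_cfg(scale=20.0):
    """A cohort with an unambiguous torsion effect: the between-patient
    signal SD of the functional term is several times the patient-level
    noise SD."""
    return SyntheticConfig(
        n_patients=40, occasion_slope=0.0, sigma_b=2.0, sigma_eps=4.0,
        scalar_effects={"age": -0.30},
        functional_effects={"torsion": scale * default_torsion_effect()},
    )


class TestPointwiseBand:
    def test_band_is_monotone_in_level(self, study_cohort):
        fit = fit_sofr_gaussian(study_cohort)
        narrow = pointwise_band(fit, "torsion", level=0.6827)
        wide = pointwise_band(fit, "torsion", level=0.95)
        assert np.all(narrow.lower >= wide.lower - 1e-12)
        assert np.all(narrow.upper <= wide.upper + 1e-12)
        assert np.all(wide.lower <= wide.upper)

    def test_band_centered_on_estimate(self, study_cohort):
        fit = fit_sofr_gaussian(study_cohort)
        band = pointwise_band(fit, "gls")
        fc = fit.functional_terms["gls"]
        np.testing.assert_allclose((band.lower + band.upper) / 2, fc.beta, atol=1e-10)

    def test_unknown_term_raises_key_error(self, study_cohort):
        fit = fit_sofr_gaussian(study_cohort)
        with pytest.raises(KeyError):
            pointwise_band(fit, "no_such_term")

    def test_se_scales_with_residual_noise(self):
        """Halving the residual SD roughly halves the pointwise SEs at a
        fixed design and fixed smoothing."""
        lam = {"torsion": 10.0}
        ses = {}
        for noise, tag in ((8.0, "hi"), (4.0, "lo")):
            cfg = SyntheticConfig(n_patients=50, occasion_slope=0.0, sigma_b=0.0,
                                  sigma_eps=noise, functional_effects={},
                                  scalar_effects={"age": -0.30})
            cohort = generate_cohort(cfg, seed=99)
            fit = fit_sofr_gaussian(
                cohort,
                options=FitOptions(functional_terms=("torsion",),
                                   scalar_terms=("age",), include_occasion=False,
                                   fixed_lambda=lam,
                                   fixed_random_intercept_ratio=np.inf),
            )
            ses[tag] = fit.functional_terms["torsion"].se
        ratio = ses["hi"] / ses["lo"]
        assert np.all(ratio > 1.6) and np.all(ratio < 2.4)


class TestGlobalPvalue:
    def test_invariant_to_covariate_rescaling(self):
        cohort = generate_cohort(_strong_cfg(), seed=31)
        fit1 = fit_sofr_gaussian(cohort, options=FAST_OPTS)
        import copy

        scaled = copy.deepcopy(cohort)
        scaled.curves["torsion"] = 10.0 * scaled.curves["torsion"]
        fit2 = fit_sofr_gaussian(scaled, options=FAST_OPTS)
        p1, p2 = fit1.global_p["torsion"], fit2.global_p["torsion"]
        assert p1 == pytest.approx(p2, rel=0.02, abs=1e-6)

    def test_strong_effect_rejected_with_high_power(self):
        rejections = 0
        for seed in range(25):
            cohort = generate_cohort(_strong_cfg(scale=25.0), seed=1000 + seed)
            fit = fit_sofr_gaussian(cohort, options=FAST_OPTS)
            if fit.global_p["torsion"] < 0.001:
                rejections += 1
        assert rejections >= 23

    def test_band_and_global_test_agree_on_strong_effects(self):
        agree = 0
        for seed in range(12):
            cohort = generate_cohort(_strong_cfg(scale=25.0), seed=500 + seed)
            fit = fit_sofr_gaussian(cohort, options=FAST_OPTS)
            band = pointwise_band(fit, "torsion")
            excludes = np.mean((band.lower > 0) | (band.upper < 0))
            if excludes > 0.5:
                agree += int(fit.global_p["torsion"] < 0.05)
            else:
                agree += 1
        assert agree >= 11


class TestBootstrap:
    def test_same_seed_gives_identical_band(self, small_cohort):
        kw = dict(term="torsion", B=60, seed=7, options=FAST_OPTS)
        b1 = bootstrap_band(small_cohort, **kw)
        b2 = bootstrap_band(small_cohort, **kw)
        np.testing.assert_array_equal(b1.lower, b2.lower)
        np.testing.assert_array_equal(b1.upper, b2.upper)

    def test_band_requires_minimum_replicates(self, small_cohort):
        with pytest.raises(ValueError):
            bootstrap_band(small_cohort, B=10, seed=1)

    def test_band_stabilizes_with_more_replicates(self):
        # percentile-quantile noise shrinks as B grows; with the shared
        # seed the first 200 replicates coincide, so the band edges may
        # move by at most a modest fraction of the model SE
        cohort = generate_cohort(NULL_CFG, seed=404)
        fit = fit_sofr_gaussian(cohort, options=FAST_OPTS)
        se = np.maximum(fit.functional_terms["torsion"].se, 1e-12)
        b200 = bootstrap_band(cohort, term="torsion", B=200, seed=3, options=FAST_OPTS)
        b400 = bootstrap_band(cohort, term="torsion", B=400, seed=3, options=FAST_OPTS)
        change = np.maximum(np.abs(b200.lower - b400.lower),
                            np.abs(b200.upper - b400.upper))
        assert np.max(change / se) < 0.5

    def test_null_bootstrap_band_covers_zero(self):
        cfg = SyntheticConfig(n_patients=40, occasion_slope=0.0,
                              functional_effects={})
        covered_cohorts = 0
        for seed in range(10):
            cohort = generate_cohort(cfg, seed=4200 + seed)
            band = bootstrap_band(cohort, term="torsion", B=100, seed=seed,
                                  options=FAST_OPTS, refit_smoothing=True)
            frac = np.mean((band.lower <= 0) & (0 <= band.upper))
            covered_cohorts += int(frac >= 0.9)
        assert covered_cohorts >= 9
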