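"""Binomial scalar-on-function mortality model: oracles and errors."""

import math

import numpy as np
import pytest
from scipy.special import logit

from lvfda import BasisSpec, SyntheticConfig, fit_sofr_binomial, generate_cohort
from lvfda.sofr import SeparationError, binomial_options, build_binomial_design


@pytest.fixture(scope="module")
def event_cohort():
    """A 70-patient cohort with a workable number of deaths."""
    cohort = generate_cohort(SyntheticConfig(seed=9), seed=13)
    assert 3 <= cohort.death.sum() <= 20
    return cohort


class TestInterceptOnly:
    def test_all_terms_dropped_gives_logit_event_rate(self, event_cohort):
        opts = binomial_options(
            fixed_lambda={"gls": math.inf, "torsion": math.inf}
        )
        fit = fit_sofr_binomial(event_cohort, options=opts)
        expected = float(logit(event_cohort.death.mean()))
        assert fit.scalar("intercept").estimate == pytest.approx(expected, abs=1e-8)
        for term in ("gls", "torsion"):
            np.testing.assert_array_equal(fit.functional_terms[term].beta, 0.0)


class TestUnpenalizedMLE:
    def test_zero_penalty_matches_newton_oracle(self, event_cohort):
        spec = BasisSpec(n_basis=4)
        opts = binomial_options(fixed_lambda={"gls": 0.0, "torsion": 0.0})
        fit = fit_sofr_binomial(event_cohort, spec, opts)

        design, y = build_binomial_design(event_cohort, spec, opts)
        C = design.C
        # independent Newton-Raphson maximum-likelihood oracle
        w = np.zeros(C.shape[1])
        for _ in range(200):
            mu = 1.0 / (1.0 + np.exp(-(C @ w)))
            grad = C.T @ (y - mu)
            H = C.T @ (C * (mu * (1 - mu))[:, None])
            step = np.linalg.solve(H, grad)
            w = w + step
            if np.max(np.abs(step)) < 1e-12:
                break
        for term in ("gls", "torsion"):
            tm = design.term_maps[term]
            beta_oracle = design.basis @ w[tm.fixed_idx]
            np.testing.assert_allclose(
                fit.functional_terms[term].beta, beta_oracle, atol=1e-6
            )

    def test_matches_statsmodels_logit(self, event_cohort):
        sm = pytest.importorskip("statsmodels.api")
        spec = BasisSpec(n_basis=4)
        opts = binomial_options(fixed_lambda={"gls": 0.0, "torsion": 0.0})
        fit = fit_sofr_binomial(event_cohort, spec, opts)
        design, y = build_binomial_design(event_cohort, spec, opts)
        ref = sm.Logit(y, design.C).fit(disp=False, method="newton")
        for term in ("gls", "torsion"):
            tm = design.term_maps[term]
            np.testing.assert_allclose(
                fit.functional_terms[term].beta,
                design.basis @ ref.params[tm.fixed_idx],
                atol=1e-5,
            )


class TestErrors:
    def test_no_events_rejected(self, event_cohort):
        import copy

        cohort = copy.deepcopy(event_cohort)
        cohort.death[:] = 0
        with pytest.raises(ValueError, match="event"):
            fit_sofr_binomial(cohort)

    def test_complete_separation_detected(self):
        """Labels generated by thresholding a functional summary are
        perfectly separable; the unpenalized fit must say so."""
        cfg = SyntheticConfig(n_patients=60, seed=3)
        cohort = generate_cohort(cfg, seed=5)
        score = cohort.curves["torsion"].mean(axis=1)
        cohort.death = (score > np.median(score)).astype(int)
        opts = binomial_options(fixed_lambda={"gls": 0.0, "torsion": 0.0})
        with pytest.raises(SeparationError):
            fit_sofr_binomial(cohort, BasisSpec(n_basis=4), opts)


class TestPenalizedFit:
    def test_reml_fit_reports_sane_inference(self, event_cohort):
        fit = fit_sofr_binomial(event_cohort)
        assert fit.family == "binomial"
        assert np.isfinite(fit.aic)
        assert 0 < fit.edf_total < 2 * fit.spec.n_basis + 1
        for term, p in fit.global_p.items():
            assert 0.0 <= p <= 1.0
        for fc in fit.functional_terms.values():
            assert np.all(fc.se >= 0)

    def test_age_adjustment_changes_aic_and_adds_term(self, event_cohort):
        fit = fit_sofr_binomial(event_cohort, options=binomial_options(age_adjusted=True))
        assert any(t.name == "age" for t in fit.scalar_terms)
        assert np.isfinite(fit.aic)

    def test_matches_mgcv_reference(self, event_cohort, tmp_path):
        """Independent cross-check of the whole penalized-logit pipeline
        against mgcv's REML smoothing selection on the same data."""
        import shutil
        import subprocess

        rscript = shutil.which("Rscript")
        if rscript is None:
            pytest.skip("Rscript not available")
        np.savetxt(tmp_path / "gls.csv", event_cohort.curves["gls"], delimiter=",")
        np.savetxt(tmp_path / "tor.csv", event_cohort.curves["torsion"], delimiter=",")
        np.savetxt(tmp_path / "death.csv", event_cohort.death, delimiter=",")
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(mgcv))
            args <- commandArgs(trailingOnly=TRUE)
            gls <- as.matrix(read.csv(file.path(args[1], 'gls.csv'), header=FALSE))
            tor <- as.matrix(read.csv(file.path(args[1], 'tor.csv'), header=FALSE))
            death <- scan(file.path(args[1], 'death.csv'), quiet=TRUE)
            n <- nrow(gls); L <- ncol(gls)
            tg <- matrix(seq(0, 1, length=L), n, L, byrow=TRUE)
            w <- rep(1/(L-1), L); w[1] <- w[L] <- 0.5/(L-1)
            W <- matrix(w, n, L, byrow=TRUE)
            glsc <- sweep(gls, 2, colMeans(gls)); torc <- sweep(tor, 2, colMeans(tor))
            fit <- gam(death ~ s(tg, by=glsc*W, bs='ps', k=9)
                              + s(tg, by=torc*W, bs='ps', k=9),
                       family=binomial, method='REML')
            cat(deviance(fit), '\\n')
            """
        )
        out = subprocess.run(
            [rscript, str(script), str(tmp_path)], capture_output=True, text=True,
            timeout=240,
        )
        assert out.returncode == 0, out.stderr
        dev_ref = float(out.stdout.strip().split()[-1])
        fit = fit_sofr_binomial(event_cohort)
        mu = np.clip(np.asarray(fit.fitted), 1e-12, 1 - 1e-12)
        y = event_cohort.death
        dev = -2 * float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
        assert dev == pytest.approx(dev_ref, rel=0.10)
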