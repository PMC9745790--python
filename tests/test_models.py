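"""Model fitting: MLE behaviour, Wald inference, derived abundance quantities."""

import numpy as np
import pytest
from scipy.stats import binom, nbinom, poisson

from nmix import (
    ModelSpec, NMixture, RoyleNichols, SimulationConfig, fit_model,
    parse_model_label, simulate_survey,
)
from tests.conftest import DET_TRUTH, STATE_TRUTH, TOP_DET, TOP_STATE


def make_fit_stub(coef, se, state_covariates=()):
    """An NMixture with fitted attributes set by hand, for closed-form identities."""
    m = NMixture("poisson", state_covariates=state_covariates)
    m.coef_ = np.asarray(coef, float)
    m.se_ = np.asarray(se, float)
    m.vcov_ = np.diag(np.asarray(se, float) ** 2)
    m.coef_names_ = [f"c{i}" for i in range(len(coef))]
    return m


class TestFitStructure:
    @pytest.mark.parametrize("mixture, n_null, n_top", [
        ("poisson", 2, 7), ("nb", 3, 8), ("zip", 3, 8),
    ])
    def test_parameter_counts_and_aic_identity(self, study_survey, mixture, n_null, n_top):
        counts, covs, _ = study_survey
        null = NMixture(mixture).fit(counts)
        top = NMixture(mixture, state_covariates=TOP_STATE,
                       det_covariates=TOP_DET).fit(counts, covs)
        assert null.n_params_ == n_null and top.n_params_ == n_top
        for m in (null, top):
            assert m.aic_ == pytest.approx(-2 * m.loglik_ + 2 * m.n_params_, abs=1e-12)
            assert len(m.coef_) == m.n_params_

    def test_vcov_symmetric_psd(self, top_fit):
        v = top_fit.vcov_
        assert np.allclose(v, v.T)
        assert (np.linalg.eigvalsh(v) > -1e-10).all()

    def test_mle_beats_zero_start_and_perturbations(self, top_fit):
        engine = top_fit.engine_
        best = engine.negloglik(top_fit.coef_)
        assert best <= engine.negloglik(np.zeros(engine.n_params)) + 1e-8
        rng = np.random.default_rng(42)
        for _ in range(100):
            theta = top_fit.coef_ + rng.normal(scale=0.3, size=engine.n_params)
            assert engine.negloglik(theta) >= best - 1e-8

    def test_collinear_formula_refused(self, study_survey):
        counts, covs, _ = study_survey
        data = covs.data.copy()
        data["mixed_twin"] = data["mixed"] * 1.0
        from nmix import SiteCovariates
        covs2 = SiteCovariates(data, standardized=True)
        m = NMixture("poisson", state_covariates=("mixed", "mixed_twin"))
        with pytest.raises(ValueError, match="correlated"):
            m.fit(counts, covs2)

    def test_unstandardized_covariates_refused(self, study_survey, raw_covs):
        counts, _, _ = study_survey
        m = NMixture("poisson", state_covariates=("a",))
        with pytest.raises(ValueError, match="standardized"):
            m.fit(counts, raw_covs)

    def test_sklearn_param_protocol(self):
        m = NMixture("zip", state_covariates=("a",), K=50)
        params = m.get_params()
        assert params["mixture"] == "zip" and params["K"] == 50
        clone = NMixture(**params)
        assert clone.get_params() == params


class TestRecovery:
    def test_estimates_recover_simulation_truth(self):
        """At a large design (500 sites) the MLE lands within ~2 SEs of truth."""
        cfg = SimulationConfig(n_sites=500, seed=1)
        counts, covs, truth = simulate_survey(cfg)
        m = NMixture("poisson", state_covariates=TOP_STATE,
                     det_covariates=TOP_DET).fit(counts, covs)
        assert m.converged_
        truth_vec = (
            [STATE_TRUTH["intercept"]] + [STATE_TRUTH[c] for c in TOP_STATE]
            + [DET_TRUTH["intercept"]] + [DET_TRUTH[c] for c in TOP_DET]
        )
        err = np.abs(m.coef_ - np.array(truth_vec))
        assert (err < 2.5 * m.se_).all()


class TestDerivedQuantities:
    def test_mean_site_abundance_identity(self):
        m = make_fit_stub([0.0, 0.0], [0.0, 0.0])
        lam, se, ci = m.mean_site_abundance()
        assert (lam, se) == (1.0, 0.0) and ci == (1.0, 1.0)

    def test_mean_site_abundance_delta_method_arithmetic(self):
        # intercept 0.95 (SE 0.25) -> 2.586 +/- 0.646, the lambda the model
        # reports for abundance at average covariates
        m = make_fit_stub([0.95, -2.44], [0.25, 0.11])
        lam, se, _ = m.mean_site_abundance()
        assert lam == pytest.approx(np.exp(0.95), abs=1e-12)
        assert se == pytest.approx(np.exp(0.95) * 0.25, abs=1e-12)

    def test_c_hat_inflates_interval(self):
        m = make_fit_stub([0.95, -2.44], [0.25, 0.11])
        _, se_plain, ci_plain = m.mean_site_abundance()
        _, se_infl, ci_infl = m.mean_site_abundance(c_hat=1.31)
        assert se_infl == pytest.approx(se_plain * np.sqrt(1.31))
        assert ci_infl[0] < ci_plain[0] < ci_plain[1] < ci_infl[1]
        # under-dispersion never shrinks the interval
        assert m.mean_site_abundance(c_hat=0.8)[1] == se_plain

    def test_detection_estimate_identity(self):
        m = make_fit_stub([0.3, 0.0], [0.1, 0.0])
        p, se = m.detection_estimate()
        assert (p, se) == (0.5, 0.0)

    def test_log_scale_ci_convention(self):
        # lambda 1.62, SE 0.34 -> log-scale CI back-transforms to ~(1.08, 2.44)
        lam_hat, se_lam = 1.62, 0.34
        m = make_fit_stub([np.log(lam_hat), 0.0], [se_lam / lam_hat, 0.0])
        _, _, ci = m.mean_site_abundance()
        assert ci[0] == pytest.approx(1.08, abs=0.01)
        assert ci[1] == pytest.approx(2.44, abs=0.01)

    def test_response_curve_identities(self, top_fit):
        curve = top_fit.response_curve("mixed", [-1.0, 0.0, 1.0])
        lam0, _, _ = top_fit.mean_site_abundance()
        assert curve.loc[1, "lambda"] == pytest.approx(lam0, rel=1e-12)
        b0 = top_fit.coef_[0]
        bj = top_fit.coef_[1 + list(TOP_STATE).index("mixed")]
        assert curve.loc[2, "lambda"] == pytest.approx(np.exp(b0 + bj), rel=1e-12)
        if bj > 0:
            assert curve["lambda"].is_monotonic_increasing
        assert (curve["lo"] <= curve["lambda"]).all() and (curve["lambda"] <= curve["hi"]).all()

    def test_response_curve_unknown_covariate(self, top_fit):
        with pytest.raises(KeyError):
            top_fit.response_curve("ruggedness", [0.0])


class TestEmpiricalBayes:
    def test_posterior_matches_brute_force(self, top_fit, study_survey):
        counts, _, _ = study_survey
        eb = top_fit.eb_site_abundance()
        i = 5
        lam, p = top_fit.fitted_lambda_[i], top_fit.fitted_p_[i]
        y = counts.counts[i]
        yv = y[~np.isnan(y)]
        grid = np.arange(top_fit.engine_.K + 1)
        post = poisson.pmf(grid, lam)
        for yt in yv:
            post = post * binom.pmf(yt, grid, p)
        post /= post.sum()
        assert eb["eb_mode"].iloc[i] == grid[post.argmax()]
        assert eb["eb_mean"].iloc[i] == pytest.approx(post @ grid, abs=1e-12)

    def test_all_zero_site_with_high_detection_has_mode_zero(self):
        from nmix import CountMatrix
        counts = CountMatrix(np.zeros((4, 10)), list("abcd"), 10, 1)
        m = NMixture("poisson", K=60)
        m.fit(counts)
        # tiny lambda fitted to all-zero data: posterior mass collapses at 0
        assert (m.eb_site_abundance()["eb_mode"] == 0).all()


class TestRoyleNichols:
    def test_null_rn_and_nmixture_intervals_overlap(self, study_survey):
        counts, _, _ = study_survey
        rn = RoyleNichols().fit(counts)
        nm = NMixture("poisson").fit(counts)
        assert rn.converged_ and nm.converged_
        _, _, ci_rn = rn.mean_site_abundance()
        _, _, ci_nm = nm.mean_site_abundance()
        assert max(ci_rn[0], ci_nm[0]) < min(ci_rn[1], ci_nm[1])

    def test_nb_simulation_recovers_dispersion_scale(self):
        cfg = SimulationConfig(n_sites=400, seed=9, mixture="nb", nb_alpha=1.0)
        counts, covs, _ = simulate_survey(cfg)
        m = NMixture("nb", state_covariates=TOP_STATE,
                     det_covariates=TOP_DET).fit(counts, covs)
        assert m.converged_ and 0.3 < m.nb_alpha_ < 3.0


class TestModelSpec:
    def test_label_round_trip(self):
        spec = ModelSpec("poisson", ("sal.forest", "mixed"), ("fruit_density",))
        assert parse_model_label(spec.label).label == spec.label

    def test_fit_model_dispatches_rn(self, study_survey):
        counts, _, _ = study_survey
        fitted = fit_model(ModelSpec("rn"), counts)
        assert isinstance(fitted, RoyleNichols)
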