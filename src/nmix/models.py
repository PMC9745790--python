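"""Maximum-likelihood estimators for N-mixture and Royle-Nichols models.

:class:`NMixture` and :class:`RoyleNichols` follow the scikit-learn estimator
protocol (constructor parameters, ``fit``, ``get_params``/``set_params``,
fitted attributes with a trailing underscore) but take the field's natural
inputs: a :class:`~nmix.containers.CountMatrix` and a
:class:`~nmix.containers.SiteCovariates` table.

Coefficients live on the link scales — log for mean site abundance lambda,
logit for detection probability p — so with Z-standardized covariates
exp(beta_0) is the mean site abundance at average covariate values.  Wald
standard errors come from the inverse of the numerically evaluated observed
information at the MLE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess

from .containers import CountMatrix, SiteCovariates
from .likelihood import MIXTURES, NMixEngine, RNEngine
from .survey import collinearity_screen

__all__ = ["ModelSpec", "NMixture", "RoyleNichols", "fit_model", "fit_model_set"]

_Z975 = norm.ppf(0.975)


@dataclass
class ModelSpec:
    """A model formula: mixture plus covariate lists for abundance and detection.

    Empty covariate lists are the constant "(.)" models.
    """

    mixture: str = "poisson"
    state_covariates: tuple = ()
    det_covariates: tuple = ()
    K: int | None = None

    def __post_init__(self):
        self.mixture = self.mixture.lower()
        if self.mixture not in MIXTURES + ("rn",):
            raise ValueError(f"unknown mixture {self.mixture!r}")
        self.state_covariates = tuple(self.state_covariates)
        self.det_covariates = tuple(self.det_covariates)

    @property
    def label(self) -> str:
        det = "+".join(self.det_covariates) or "."
        state = "+".join(self.state_covariates) or "."
        return f"p({det})lambda({state})"


def _wald_table(names, coef, se):
    z = np.divide(coef, se, out=np.full_like(coef, np.nan), where=se > 0)
    p = 2 * norm.sf(np.abs(z))
    return pd.DataFrame(
        {"estimate": coef, "se": se, "z": z, "p_value": p}, index=names
    )


class _FittedMixin:
    """Shared derived quantities for fitted abundance models."""

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise AttributeError("model is not fitted yet; call fit() first")

    def mean_site_abundance(self, c_hat: float | None = None):
        """Mean site abundance exp(beta_0) with delta-method SE and 95% CI.

        With standardized covariates this is abundance at average covariate
        values.  If an overdispersion estimate ``c_hat`` > 1 is supplied, the
        intercept SE is inflated by sqrt(c_hat) before the interval is built.
        The CI is normal on the log scale, back-transformed.
        """
        self._check_fitted()
        i = self._state_intercept_index
        b0 = self.coef_[i]
        se0 = self.se_[i]
        if c_hat is not None:
            se0 = se0 * np.sqrt(max(float(c_hat), 1.0))
        lam = float(np.exp(b0))
        se = lam * se0
        ci = (float(np.exp(b0 - _Z975 * se0)), float(np.exp(b0 + _Z975 * se0)))
        return lam, float(se), ci

    def summary(self) -> pd.DataFrame:
        self._check_fitted()
        return _wald_table(self.coef_names_, self.coef_, self.se_)


class NMixture(BaseEstimator, _FittedMixin):
    """Binomial N-mixture model with Poisson, NB or ZIP abundance mixture.

    Parameters
    ----------
    mixture : {"poisson", "nb", "zip"}
    state_covariates : sequence of str
        Covariate names on log(lambda); empty = constant abundance.
    det_covariates : sequence of str
        Covariate names on logit(p); empty = constant detection.
    K : int, optional
        Latent-count truncation bound (default: max observed count + 100).
    collinearity_threshold : float or None
        Refuse to fit a formula whose covariates contain a pair with
        |Pearson r| at or above this value (None disables the guard).
    tol : float
        Convergence tolerance on the objective/gradient.
    n_random_starts : int
        Extra random restarts around the deterministic all-zeros start.
    random_state : int or None
        Seed for the optional restarts.

    Attributes
    ----------
    coef_, se_, vcov_, pvalues_ : link-scale estimates and Wald inference
    loglik_, aic_, n_params_, converged_
    fitted_lambda_, fitted_p_ : per-site values at the MLE
    nb_alpha_, zip_psi_ : natural-scale nuisance parameters where applicable
    """

    def __init__(self, mixture="poisson", state_covariates=(), det_covariates=(),
                 K=None, collinearity_threshold=0.7, tol=1e-8, maxiter=1000,
                 n_random_starts=0, random_state=None):
        self.mixture = mixture
        self.state_covariates = state_covariates
        self.det_covariates = det_covariates
        self.K = K
        self.collinearity_threshold = collinearity_threshold
        self.tol = tol
        self.maxiter = maxiter
        self.n_random_starts = n_random_starts
        self.random_state = random_state

    # ------------------------------------------------------------------
    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(self.mixture, tuple(self.state_covariates),
                         tuple(self.det_covariates), self.K)

    @property
    def _state_intercept_index(self) -> int:
        return 0

    def _design(self, counts: CountMatrix, covariates: SiteCovariates | None):
        state = tuple(self.state_covariates)
        det = tuple(self.det_covariates)
        if (state or det) and covariates is None:
            raise ValueError("covariates required for a covariate model")
        if covariates is not None and (state or det):
            if not covariates.standardized:
                raise ValueError(
                    "covariates must be Z-standardized before fitting "
                    "(use SiteCovariates.standardize())"
                )
            if len(covariates.data) != counts.n_sites:
                raise ValueError("covariate rows do not match count-matrix sites")
            thr = self.collinearity_threshold
            if thr is not None:
                flagged = collinearity_screen(covariates, thr)
                for a, b, r in flagged:
                    for group in (state, det):
                        if a in group and b in group:
                            raise ValueError(
                                f"refusing formula: covariates {a!r} and {b!r} are "
                                f"strongly correlated (|r| = {abs(r):.2f} >= {thr})"
                            )
            Xs = covariates.matrix(state)
            Xd = covariates.matrix(det)
        else:
            R = counts.n_sites
            Xs = np.ones((R, 1))
            Xd = np.ones((R, 1))
        return Xs, Xd

    def _coef_names(self):
        names = ["lam_(Intercept)"] + [f"lam_{c}" for c in self.state_covariates]
        names += ["p_(Intercept)"] + [f"p_{c}" for c in self.det_covariates]
        if self.mixture == "nb":
            names += ["log_alpha"]
        elif self.mixture == "zip":
            names += ["logit_psi"]
        return names

    def fit(self, counts: CountMatrix, covariates: SiteCovariates | None = None,
            start: np.ndarray | None = None, compute_se: bool = True):
        """Maximise the marginal likelihood from a deterministic all-zeros start.

        ``compute_se=False`` skips the numerical Hessian (useful inside
        bootstrap loops where only the point fit is needed).
        """
        Xs, Xd = self._design(counts, covariates)
        engine = NMixEngine(counts, Xs, Xd, self.mixture, self.K)
        x0 = np.zeros(engine.n_params) if start is None else np.asarray(start, float)

        def _minimize(x):
            return optimize.minimize(
                engine.negloglik, x, method="BFGS",
                options={"gtol": self.tol, "maxiter": self.maxiter},
            )

        res = _minimize(x0)
        if not res.success:
            # one restart from the candidate optimum: resets the Hessian
            # approximation, which finite-difference noise can corrupt
            res2 = _minimize(res.x)
            if res2.fun <= res.fun:
                res = res2
        if self.n_random_starts:
            rng = np.random.default_rng(self.random_state)
            for _ in range(self.n_random_starts):
                alt = _minimize(x0 + rng.normal(scale=0.5, size=engine.n_params))
                if alt.fun < res.fun - 1e-10:
                    res = alt

        theta = res.x
        self.engine_ = engine
        self.coef_ = theta
        self.coef_names_ = self._coef_names()
        self.loglik_ = -res.fun
        self.n_params_ = engine.n_params
        self.aic_ = 2 * res.fun + 2 * engine.n_params
        # finite-difference gradients bottom out near sqrt(eps)*|f|; accept a
        # stationary point whose gradient is at that noise floor
        gtol_eff = 100 * np.sqrt(np.finfo(float).eps) * (1 + abs(res.fun))
        self.converged_ = bool(res.success or np.abs(res.jac).max() < gtol_eff)
        if not self.converged_:
            warnings.warn(f"optimizer did not report convergence: {res.message}")

        if compute_se:
            H = approx_hess(theta, engine.negloglik)
            H = 0.5 * (H + H.T)
            try:
                vcov = np.linalg.inv(H)
                if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) <= 0):
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                warnings.warn("singular observed information; standard errors undefined")
                vcov = np.full((engine.n_params, engine.n_params), np.nan)
        else:
            vcov = np.full((engine.n_params, engine.n_params), np.nan)
        self.vcov_ = vcov
        self.se_ = np.sqrt(np.abs(np.diag(vcov)))
        with np.errstate(invalid="ignore"):
            z = self.coef_ / self.se_
        self.zvalues_ = z
        self.pvalues_ = 2 * norm.sf(np.abs(z))

        lam, p = engine.lam_p(theta)
        self.fitted_lambda_ = lam
        self.fitted_p_ = p
        _, _, extra = engine.unpack(theta)
        self.nb_alpha_ = float(np.exp(extra[0])) if self.mixture == "nb" else None
        self.zip_psi_ = float(expit(extra[0])) if self.mixture == "zip" else None
        self._counts = counts
        self._covariates = covariates
        return self

    # -- derived quantities -------------------------------------------
    def detection_estimate(self):
        """Detection probability at average covariates: logistic(alpha_0), delta-method SE."""
        self._check_fitted()
        i = len(self.state_covariates) + 1
        a0, se0 = self.coef_[i], self.se_[i]
        p = float(expit(a0))
        return p, float(p * (1 - p) * se0)

    def eb_site_abundance(self, counts: CountMatrix | None = None) -> pd.DataFrame:
        """Empirical-Bayes posterior mode and mean of latent N per site.

        The posterior is P(N_i = n | y_i) evaluated at the MLE, normalised over
        n = max(y_i)..K.  The mode is the value mapped in relative-abundance
        maps; the mean is also returned.
        """
        self._check_fitted()
        counts = self._counts if counts is None else counts
        post = self.engine_.eb_posterior(self.coef_)
        grid = self.engine_.Ngrid
        mode = grid[post.argmax(axis=1)]
        mean = post @ grid
        return pd.DataFrame(
            {"site_id": counts.site_ids, "eb_mode": mode, "eb_mean": mean}
        ).set_index("site_id")

    def response_curve(self, covariate: str, grid, c_hat: float | None = None) -> pd.DataFrame:
        """Predicted lambda along one standardized covariate, others at 0.

        lambda(x) = exp(beta_0 + beta_cov * x); the 95% CI is the delta-method
        (normal) interval on the linear predictor, back-transformed, optionally
        inflated by sqrt(c_hat).
        """
        self._check_fitted()
        if covariate not in self.state_covariates:
            raise KeyError(f"{covariate!r} is not in the abundance formula")
        j = 1 + list(self.state_covariates).index(covariate)
        grid = np.asarray(grid, dtype=float)
        eta = self.coef_[0] + self.coef_[j] * grid
        # var(beta0 + x*betaj) from the joint vcov
        v = (self.vcov_[0, 0] + grid**2 * self.vcov_[j, j]
             + 2 * grid * self.vcov_[0, j])
        se = np.sqrt(np.maximum(v, 0))
        if c_hat is not None:
            se = se * np.sqrt(max(float(c_hat), 1.0))
        return pd.DataFrame({
            "x": grid,
            "lambda": np.exp(eta),
            "lo": np.exp(eta - _Z975 * se),
            "hi": np.exp(eta + _Z975 * se),
        })

    def simulate(self, rng: np.random.Generator) -> CountMatrix:
        """Draw one dataset from the fitted model (same design and missingness)."""
        self._check_fitted()
        counts = self._counts
        R = counts.n_sites
        lam, p = self.fitted_lambda_, self.fitted_p_
        if self.mixture == "poisson":
            N = rng.poisson(lam)
        elif self.mixture == "nb":
            a = self.nb_alpha_
            N = rng.negative_binomial(a, a / (a + lam))
        else:
            N = np.where(rng.random(R) < self.zip_psi_, 0, rng.poisson(lam))
        y = np.full(counts.counts.shape, np.nan)
        pres = counts.present
        for i in range(R):
            cells = pres[i]
            y[i, cells] = rng.binomial(N[i], p[i], size=cells.sum())
        return CountMatrix(y, list(counts.site_ids), counts.n_occasions,
                           counts.n_replicates, layout=counts.layout)

    def expected_counts(self) -> np.ndarray:
        """Expected count per surveyed cell, E[y_it] = lambda_i * p_i (ZIP: x(1-psi))."""
        self._check_fitted()
        lam = self.fitted_lambda_
        if self.mixture == "zip":
            lam = lam * (1 - self.zip_psi_)
        mu = lam[:, None] * self.fitted_p_[:, None]
        return np.where(self._counts.present, mu, np.nan)

    def cell_variance(self) -> np.ndarray:
        """Var(y_it) under the fitted mixture: E[N] p (1-p) + Var(N) p^2."""
        self._check_fitted()
        lam, p = self.fitted_lambda_, self.fitted_p_
        if self.mixture == "poisson":
            EN, VN = lam, lam
        elif self.mixture == "nb":
            EN, VN = lam, lam + lam**2 / self.nb_alpha_
        else:
            psi = self.zip_psi_
            EN = (1 - psi) * lam
            VN = (1 - psi) * (lam + lam**2) - EN**2
        v = (EN * p * (1 - p) + VN * p**2)[:, None]
        v = np.broadcast_to(v, self._counts.counts.shape)
        return np.where(self._counts.present, v, np.nan)


class RoyleNichols(BaseEstimator, _FittedMixin):
    """Royle-Nichols abundance-induced-heterogeneity model (intercept-only).

    Counts are collapsed to detection/non-detection; abundance is Poisson
    and one individual is detected with probability r per occasion, so the
    occasion-level detection probability is 1 - (1-r)^N.
    """

    def __init__(self, K=300, tol=1e-8, maxiter=1000):
        self.K = K
        self.tol = tol
        self.maxiter = maxiter

    @property
    def _state_intercept_index(self) -> int:
        return 0

    def fit(self, counts: CountMatrix, covariates=None):
        engine = RNEngine(counts, K=self.K)
        res = optimize.minimize(
            engine.negloglik, np.zeros(2), method="BFGS",
            options={"gtol": self.tol, "maxiter": self.maxiter},
        )
        if not res.success:
            res2 = optimize.minimize(
                engine.negloglik, res.x, method="BFGS",
                options={"gtol": self.tol, "maxiter": self.maxiter},
            )
            if res2.fun <= res.fun:
                res = res2
        self.engine_ = engine
        self.coef_ = res.x
        self.coef_names_ = ["lam_(Intercept)", "logit_r"]
        self.loglik_ = -res.fun
        self.n_params_ = 2
        self.aic_ = 2 * res.fun + 4
        gtol_eff = 100 * np.sqrt(np.finfo(float).eps) * (1 + abs(res.fun))
        self.converged_ = bool(res.success or np.abs(res.jac).max() < gtol_eff)
        if not self.converged_:
            warnings.warn(f"optimizer did not report convergence: {res.message}")
        H = approx_hess(res.x, engine.negloglik)
        H = 0.5 * (H + H.T)
        try:
            vcov = np.linalg.inv(H)
            if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn("singular observed information; standard errors undefined")
            vcov = np.full((2, 2), np.nan)
        self.vcov_ = vcov
        self.se_ = np.sqrt(np.abs(np.diag(vcov)))
        self.zvalues_ = self.coef_ / self.se_
        self.pvalues_ = 2 * norm.sf(np.abs(self.zvalues_))
        self.r_ = float(expit(self.coef_[1]))
        self._counts = counts
        return self


def fit_model(spec: ModelSpec, counts: CountMatrix,
              covariates: SiteCovariates | None = None, **kwargs):
    """Fit one :class:`ModelSpec`; thin functional wrapper over the estimators."""
    if spec.mixture == "rn":
        return RoyleNichols(K=spec.K or 300, **kwargs).fit(counts)
    est = NMixture(
        mixture=spec.mixture,
        state_covariates=spec.state_covariates,
        det_covariates=spec.det_covariates,
        K=spec.K,
        **kwargs,
    )
    return est.fit(counts, covariates)


def fit_model_set(specs, counts, covariates=None, **kwargs):
    """Fit a list of specs, returning ``{label: fitted estimator}`` per mixture."""
    fits = {}
    for spec in specs:
        label = f"{spec.mixture}:{spec.label}"
        fits[label] = fit_model(spec, counts, covariates, **kwargs)
    return fits
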