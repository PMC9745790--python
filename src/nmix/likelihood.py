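"""Likelihood engine for binomial N-mixture and Royle-Nichols models.

The N-mixture model treats the latent abundance N_i of site i as a draw from a
count mixture (Poisson, negative binomial, or zero-inflated Poisson) and each
observed count y_it as an independent Binomial(N_i, p_it) thinning.  The
marginal likelihood of one site sums the binomial product over the latent
count, truncated at a bound K:

    L_i = sum_{N=max(y_i)}^{K}  [ prod_t Binom(y_it; N, p_it) ] * Pr(N_i = N)

All sums run in log space (log-sum-exp); with detection probabilities around
0.01-0.08 direct products underflow.  The lower limit max(y_i) is exact: the
binomial pmf vanishes for N below any observed count.

The negative binomial uses the mean-dispersion parameterisation (mean lambda,
variance lambda + lambda^2/alpha), the convention of the software family
ecologists use for these models, and the zero-inflated Poisson places extra
mass psi at N = 0.  The Royle-Nichols model links detection-nondetection data
to abundance through P(detect in one occasion | N) = 1 - (1-r)^N with a
Poisson abundance mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, logsumexp

from .containers import CountMatrix

__all__ = [
    "MIXTURES",
    "MixtureParams",
    "RNParams",
    "abundance_pmf",
    "abundance_logpmf",
    "truncation_mass",
    "site_marginal_loglik",
    "rn_site_loglik",
    "nmix_negloglik",
    "binarize",
    "NMixEngine",
    "RNEngine",
    "default_K",
]

MIXTURES = ("poisson", "nb", "zip")

#: extra latent-count headroom above the largest observed count
K_EXTRA = 100


def default_K(counts: CountMatrix) -> int:
    """Default truncation bound: max observed count + 100."""
    return int(counts.site_max().max()) + K_EXTRA


def _check_mixture(mixture: str) -> str:
    m = mixture.lower()
    if m not in MIXTURES:
        raise ValueError(f"unknown mixture {mixture!r}; choose from {MIXTURES}")
    return m


@dataclass
class MixtureParams:
    """Parameters of the latent-abundance mixture at one site.

    ``lam`` is the mean abundance, ``p`` the detection probability (scalar or
    per-occasion vector), ``alpha`` the NB dispersion (variance lambda +
    lambda^2/alpha), ``psi`` the zero-inflation probability, ``K`` the
    latent-count truncation bound.
    """

    mixture: str = "poisson"
    lam: float = 1.0
    p: float | np.ndarray = 0.5
    alpha: float | None = None
    psi: float | None = None
    K: int = 200

    def __post_init__(self):
        self.mixture = _check_mixture(self.mixture)
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p must lie in [0, 1]")
        if self.mixture == "nb":
            if self.alpha is None or self.alpha <= 0:
                raise ValueError("NB mixture needs dispersion alpha > 0")
        if self.mixture == "zip":
            if self.psi is None or not 0 <= self.psi <= 1:
                raise ValueError("ZIP mixture needs psi in [0, 1]")
        if self.K < 1:
            raise ValueError("K must be a positive integer")


@dataclass
class RNParams:
    """Royle-Nichols parameters: mean abundance and per-individual detection."""

    lam: float = 1.0
    r: float = 0.1
    K: int = 300

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not 0 <= self.r <= 1:
            raise ValueError("r must lie in [0, 1]")
        if self.K < 1:
            raise ValueError("K must be a positive integer")


# ---------------------------------------------------------------------------
# abundance mixtures
# ---------------------------------------------------------------------------

def abundance_logpmf(n, mixture: str, lam, alpha=None, psi=None) -> np.ndarray:
    """Log pmf of the latent-abundance mixture, vectorised over ``n``.

    ``lam`` (and the other parameters) may broadcast against ``n``.
    """
    mixture = _check_mixture(mixture)
    n = np.asarray(n)
    if (n < 0).any() or not np.issubdtype(n.dtype, np.integer) and (n != np.floor(n)).any():
        raise ValueError("n must be non-negative integers")
    lam = np.asarray(lam, dtype=float)
    if (lam <= 0).any():
        raise ValueError("lambda must be positive")
    pois = n * np.log(lam) - lam - gammaln(n + 1)
    if mixture == "poisson":
        return pois
    if mixture == "nb":
        alpha = float(alpha)
        if alpha <= 0:
            raise ValueError("NB dispersion alpha must be positive")
        return (
            gammaln(n + alpha) - gammaln(alpha) - gammaln(n + 1)
            + alpha * (np.log(alpha) - np.log(alpha + lam))
            + n * (np.log(lam) - np.log(alpha + lam))
        )
    # zip
    psi = float(psi)
    if not 0 <= psi <= 1:
        raise ValueError("psi must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        out = np.log1p(-psi) + pois
        if psi > 0:
            out = np.where(n == 0, np.logaddexp(np.log(psi), out), out)
    return out


def abundance_pmf(n, params: MixtureParams) -> np.ndarray:
    """Pmf of the latent-abundance mixture at ``n`` (vectorised)."""
    return np.exp(abundance_logpmf(n, params.mixture, params.lam,
                                   alpha=params.alpha, psi=params.psi))


def truncation_mass(params: MixtureParams) -> float:
    """Probability mass of the mixture beyond the truncation bound K."""
    grid = np.arange(params.K + 1)
    return float(1.0 - np.exp(abundance_logpmf(
        grid, params.mixture, params.lam, alpha=params.alpha, psi=params.psi
    )).sum())


# ---------------------------------------------------------------------------
# site-level marginal log-likelihoods
# ---------------------------------------------------------------------------

def site_marginal_loglik(y, lam: float, p, params: MixtureParams | None = None, *,
                         mixture: str | None = None, alpha=None, psi=None,
                         K: int | None = None) -> float:
    """Marginal log-likelihood of one site's counts, latent N summed out.

    ``y`` is the per-occasion count vector (NaN = missing cell, skipped);
    ``p`` a matching detection-probability vector or scalar.  Mixture
    parameters come either from ``params`` or from the keyword arguments.
    """
    if params is not None:
        mixture, alpha, psi = params.mixture, params.alpha, params.psi
        K = params.K if K is None else K
    mixture = _check_mixture(mixture or "poisson")
    y = np.asarray(y, dtype=float).ravel()
    present = ~np.isnan(y)
    if not present.any():
        raise ValueError("all cells missing: site contributes no likelihood")
    yv = y[present]
    if (yv < 0).any() or (yv != np.round(yv)).any():
        raise ValueError("counts must be non-negative integers")
    p = np.broadcast_to(np.asarray(p, dtype=float).ravel(), y.shape)[present]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p must lie in [0, 1]")
    ymax = int(yv.max())
    if K is None:
        K = ymax + K_EXTRA
    if ymax > K:
        raise ValueError(f"observed count {ymax} exceeds truncation bound K={K}")

    Ngrid = np.arange(K + 1)
    p = np.clip(p, 1e-300, 1 - 1e-16)
    # sum_t log Binom(y_t; N, p_t), as a function of N
    with np.errstate(divide="ignore", invalid="ignore"):
        logC = (gammaln(Ngrid[None, :] + 1)
                - gammaln(yv[:, None] + 1)
                - gammaln(Ngrid[None, :] - yv[:, None] + 1))
    logC[Ngrid[None, :] < yv[:, None]] = -np.inf
    obs = logC + yv[:, None] * np.log(p[:, None]) \
        + (Ngrid[None, :] - yv[:, None]) * np.log1p(-p[:, None])
    tot = obs.sum(axis=0) + abundance_logpmf(Ngrid, mixture, lam, alpha=alpha, psi=psi)
    return float(logsumexp(tot))


def rn_site_loglik(w, lam: float, r: float, K: int = 300) -> float:
    """Royle-Nichols marginal log-likelihood of one site's detection history.

    ``w`` is binary (NaN = missing); detection of at least one of the N
    individuals in an occasion has probability 1 - (1-r)^N.
    """
    w = np.asarray(w, dtype=float).ravel()
    present = ~np.isnan(w)
    if not present.any():
        raise ValueError("all cells missing")
    wv = w[present]
    if not np.isin(wv, (0.0, 1.0)).all():
        raise ValueError("Royle-Nichols data must be binary detection/non-detection")
    if not 0 <= r <= 1:
        raise ValueError("r must lie in [0, 1]")
    n_det = wv.sum()
    n_occ = wv.size
    Ngrid = np.arange(K + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_q = Ngrid * np.log1p(-min(r, 1 - 1e-16))          # log (1-r)^N
        log_1mq = np.where(
            Ngrid == 0, -np.inf,
            np.log(-np.expm1(np.minimum(log_q, -1e-300)))      # log(1 - (1-r)^N)
        )
    with np.errstate(invalid="ignore"):
        det_term = n_det * log_1mq
    if n_det == 0:
        det_term = np.zeros_like(log_1mq)  # 0 * log(0) at N=0 contributes nothing
    tot = det_term + (n_occ - n_det) * log_q \
        + abundance_logpmf(Ngrid, "poisson", lam)
    return float(logsumexp(tot))


def binarize(counts: CountMatrix) -> CountMatrix:
    """Collapse counts to detection/non-detection (missing cells preserved)."""
    return counts.binarize()


# ---------------------------------------------------------------------------
# full-data likelihood engines
# ---------------------------------------------------------------------------

class NMixEngine:
    """Precomputed full-data negative log-likelihood for one dataset.

    The coefficient vector packs, in order: state coefficients beta (log link
    on lambda), detection coefficients alpha (logit link on p), then log(NB
    dispersion) for the NB mixture or logit(psi) for ZIP.  Detection
    covariates are site-level, so p is constant across a site's cells; the
    binomial product over occasions then reduces to sufficient statistics
    (total count, number of surveyed cells, and a per-site table of summed
    log binomial coefficients over the latent grid), making one likelihood
    evaluation O(R * K).
    """

    def __init__(self, counts: CountMatrix, X_state: np.ndarray,
                 X_det: np.ndarray, mixture: str = "poisson",
                 K: int | None = None):
        self.mixture = _check_mixture(mixture)
        y = counts.counts
        R = y.shape[0]
        if X_state.shape[0] != R or X_det.shape[0] != R:
            raise ValueError("design matrices must have one row per site")
        self.X_state = np.asarray(X_state, dtype=float)
        self.X_det = np.asarray(X_det, dtype=float)
        self.K = default_K(counts) if K is None else int(K)
        site_max = counts.site_max().astype(int)
        if (site_max > self.K).any():
            raise ValueError("truncation bound K below an observed count")
        present = counts.present
        if not present.any(axis=1).all():
            bad = [counts.site_ids[i] for i in np.where(~present.any(axis=1))[0]]
            raise ValueError(f"site(s) with no surveyed cells: {bad}")
        self.Y = np.nansum(y, axis=1)                     # total count per site
        self.T = present.sum(axis=1).astype(float)        # surveyed cells per site
        self.Ngrid = np.arange(self.K + 1)
        self._gamN1 = gammaln(self.Ngrid + 1)

        # SC[i, N] = sum over surveyed cells of log C(N, y_it); -inf below max(y_i)
        yv = np.where(present, y, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logC = (self._gamN1[None, None, :]
                    - gammaln(yv[:, :, None] + 1)
                    - gammaln(self.Ngrid[None, None, :] - yv[:, :, None] + 1))
        logC = np.where(self.Ngrid[None, None, :] < yv[:, :, None], -np.inf, logC)
        logC = np.where(present[:, :, None], logC, 0.0)
        with np.errstate(invalid="ignore"):
            self.SC = logC.sum(axis=1)
        self.SC[self.Ngrid[None, :] < site_max[:, None]] = -np.inf

        self.n_state = self.X_state.shape[1]
        self.n_det = self.X_det.shape[1]
        self.n_extra = 1 if self.mixture in ("nb", "zip") else 0
        self.n_params = self.n_state + self.n_det + self.n_extra

    # -- parameter packing -------------------------------------------
    def unpack(self, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {theta.size}")
        beta = theta[: self.n_state]
        alpha = theta[self.n_state: self.n_state + self.n_det]
        extra = theta[self.n_state + self.n_det:] if self.n_extra else None
        return beta, alpha, extra

    def lam_p(self, theta: np.ndarray):
        beta, alpha, _ = self.unpack(theta)
        lam = np.exp(np.clip(self.X_state @ beta, -40, 40))
        p = expit(self.X_det @ alpha)
        return lam, np.clip(p, 1e-12, 1 - 1e-12)

    def _mixture_logpmf(self, lam: np.ndarray, extra) -> np.ndarray:
        """(R, K+1) table of log Pr(N_i = n)."""
        N = self.Ngrid[None, :]
        lam = lam[:, None]
        pois = N * np.log(lam) - lam - self._gamN1[None, :]
        if self.mixture == "poisson":
            return pois
        if self.mixture == "nb":
            a = np.exp(np.clip(extra[0], -30, 30))
            return (gammaln(N + a) - gammaln(a) - self._gamN1[None, :]
                    + a * (np.log(a) - np.log(a + lam))
                    + N * (np.log(lam) - np.log(a + lam)))
        lpsi = np.clip(extra[0], -500, 500)
        log_psi = -np.logaddexp(0.0, -lpsi)       # log psi
        log_1mpsi = -np.logaddexp(0.0, lpsi)      # log (1 - psi)
        out = log_1mpsi + pois
        out[:, 0] = np.logaddexp(log_psi, out[:, 0])
        return out

    def site_logliks(self, theta: np.ndarray) -> np.ndarray:
        lam, p = self.lam_p(theta)
        _, _, extra = self.unpack(theta)
        const = self.Y * np.log(p) - self.Y * np.log1p(-p)
        slope = self.T * np.log1p(-p)
        tot = (self.SC
               + const[:, None]
               + self.Ngrid[None, :] * slope[:, None]
               + self._mixture_logpmf(lam, extra))
        return logsumexp(tot, axis=1)

    def negloglik(self, theta: np.ndarray) -> float:
        ll = self.site_logliks(theta).sum()
        if not np.isfinite(ll):
            return 1e12
        return float(-ll)

    def eb_posterior(self, theta: np.ndarray) -> np.ndarray:
        """(R, K+1) empirical-Bayes posterior P(N_i = n | y_i) at ``theta``."""
        lam, p = self.lam_p(theta)
        _, _, extra = self.unpack(theta)
        const = self.Y * np.log(p) - self.Y * np.log1p(-p)
        slope = self.T * np.log1p(-p)
        tot = (self.SC
               + const[:, None]
               + self.Ngrid[None, :] * slope[:, None]
               + self._mixture_logpmf(lam, extra))
        tot -= logsumexp(tot, axis=1, keepdims=True)
        return np.exp(tot)


def nmix_negloglik(theta, counts: CountMatrix, X_state, X_det,
                   mixture: str = "poisson", K: int | None = None) -> float:
    """Negative full-data log-likelihood (functional form of :class:`NMixEngine`)."""
    return NMixEngine(counts, X_state, X_det, mixture, K).negloglik(theta)


class RNEngine:
    """Royle-Nichols full-data negative log-likelihood (intercept-only).

    Coefficient vector: [log lambda, logit r].  K should sit far in the tail
    of the Poisson abundance mixture; the default 300 leaves negligible mass
    beyond it for any plausible camera-trap lambda.
    """

    def __init__(self, counts: CountMatrix, K: int = 300):
        w = counts.binarize().counts
        present = ~np.isnan(w)
        if not present.any(axis=1).all():
            bad = [counts.site_ids[i] for i in np.where(~present.any(axis=1))[0]]
            raise ValueError(f"site(s) with no surveyed cells: {bad}")
        self.D = np.nansum(w, axis=1)               # detections per site
        self.T = present.sum(axis=1).astype(float)  # surveyed occasions per site
        self.K = int(K)
        self.Ngrid = np.arange(self.K + 1)
        self._logpois_gam = gammaln(self.Ngrid + 1)
        self.n_params = 2

    def site_logliks(self, theta: np.ndarray) -> np.ndarray:
        log_lam = np.clip(theta[0], -40, 40)
        lam = np.exp(log_lam)
        r = np.clip(expit(theta[1]), 1e-12, 1 - 1e-12)
        log_q = self.Ngrid * np.log1p(-r)
        with np.errstate(divide="ignore"):
            log_1mq = np.where(self.Ngrid == 0, -np.inf,
                               np.log(-np.expm1(np.minimum(log_q, -1e-300))))
        logpois = self.Ngrid * log_lam - lam - self._logpois_gam
        with np.errstate(invalid="ignore"):
            det_term = self.D[:, None] * log_1mq[None, :]
        det_term[self.D == 0, :] = 0.0  # 0 * log(0) at N=0 contributes nothing
        tot = (det_term
               + (self.T - self.D)[:, None] * log_q[None, :]
               + logpois[None, :])
        return logsumexp(tot, axis=1)

    def negloglik(self, theta: np.ndarray) -> float:
        ll = self.site_logliks(theta).sum()
        if not np.isfinite(ll):
            return 1e12
        return float(-ll)
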