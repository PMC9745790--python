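"""AIC multimodel ranking and parametric-bootstrap goodness of fit.

Candidate models are compared by AIC; inference is restricted to models
within 2 delta-AIC units, following standard information-theoretic practice.
Absolute fit is assessed by a parametric bootstrap: datasets are simulated
from the fitted model (same design and missingness), the model is refit to
each, and the observed fit statistic is referred to the bootstrap
distribution.  The overdispersion ratio c-hat = observed / mean(bootstrap)
inflates standard errors by sqrt(c-hat) when it exceeds 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "rank_models", "gof_bootstrap", "c_hat_inflate", "residual_map",
    "GoFResult", "FIT_STATISTICS", "observed_statistics",
]


def _label_of(fit, fallback):
    try:
        return f"{fit.mixture}:{fit.spec.label}"
    except AttributeError:
        return fallback


def rank_models(fits, labels=None) -> pd.DataFrame:
    """AIC table: model, nPars, AIC, dAIC, AICwt, cumltvWt, report flag.

    ``fits`` is a list (or dict label -> fit) of fitted estimators.  Rows are
    sorted ascending by AIC; the ``report`` column marks models within 2
    delta-AIC units of the best.
    """
    if isinstance(fits, dict):
        labels = list(fits.keys())
        fits = list(fits.values())
    fits = list(fits)
    if not fits:
        raise ValueError("no fitted models to rank")
    if labels is None:
        labels = [_label_of(f, f"model_{i}") for i, f in enumerate(fits)]
    if len(set(labels)) != len(labels):
        raise ValueError("model labels must be unique")
    not_conv = [l for l, f in zip(labels, fits) if not getattr(f, "converged_", True)]
    if not_conv:
        warnings.warn(f"ranking includes non-converged fit(s): {not_conv}")

    aic = np.array([f.aic_ for f in fits], dtype=float)
    npars = np.array([f.n_params_ for f in fits], dtype=int)
    order = np.argsort(aic, kind="stable")
    aic, npars = aic[order], npars[order]
    labels = [labels[i] for i in order]
    delta = aic - aic[0]
    w = np.exp(-delta / 2)
    w /= w.sum()
    return pd.DataFrame({
        "model": labels,
        "nPars": npars,
        "AIC": aic,
        "dAIC": delta,
        "AICwt": w,
        "cumltvWt": np.cumsum(w),
        "report": delta <= 2.0,
    })


# ---------------------------------------------------------------------------
# fit statistics (pluggable)
# ---------------------------------------------------------------------------

def _pearson_chi2(y, mu, var=None):
    return float(np.nansum((y - mu) ** 2 / mu))


def _sse(y, mu, var=None):
    return float(np.nansum((y - mu) ** 2))


def _freeman_tukey(y, mu, var=None):
    return float(np.nansum((np.sqrt(y) - np.sqrt(mu)) ** 2))


FIT_STATISTICS = {
    "pearson": _pearson_chi2,
    "sse": _sse,
    "freeman_tukey": _freeman_tukey,
}


def _statistic(fit, counts: CountMatrix, name: str) -> float:
    mu = fit.expected_counts()
    y = np.where(counts.present, counts.counts, np.nan)
    if mu.shape != y.shape:
        raise ValueError("count matrix does not match the fitted design")
    return FIT_STATISTICS[name](y, mu)


def observed_statistics(fit, counts: CountMatrix) -> dict:
    """All three fit statistics on the observed data (sensitivity table)."""
    return {name: _statistic(fit, counts, name) for name in FIT_STATISTICS}


@dataclass
class GoFResult:
    """Parametric-bootstrap goodness-of-fit summary.

    ``p_value`` is the proportion of bootstrap statistics at or above the
    observed one; ``c_hat`` the observed statistic over the bootstrap mean.
    """

    statistic_name: str
    observed: float
    bootstrap_stats: np.ndarray = field(repr=False)
    p_value: float
    c_hat: float
    seed: int | None
    n_failures: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "statistic": [self.statistic_name],
            "observed": [self.observed],
            "p_value": [self.p_value],
            "c_hat": [self.c_hat],
            "n_boot": [len(self.bootstrap_stats)],
            "n_failures": [self.n_failures],
            "seed": [self.seed],
        })


def gof_bootstrap(fit, counts: CountMatrix, covariates=None, n_boot: int = 1000,
                  seed: int | None = None, statistic: str = "pearson") -> GoFResult:
    """Parametric-bootstrap goodness of fit for a fitted N-mixture model.

    Each iteration simulates a dataset from the fitted model on the same
    design/missingness, refits the same specification (started from the
    original MLE for speed and basin consistency), and recomputes the fit
    statistic.  Refit failures are counted; more than 10% triggers a warning.
    """
    if statistic not in FIT_STATISTICS:
        raise KeyError(f"unknown statistic {statistic!r}; choose from {list(FIT_STATISTICS)}")
    if not getattr(fit, "converged_", False):
        warnings.warn("bootstrapping a fit that did not report convergence")
    observed = _statistic(fit, counts, statistic)
    rng = np.random.default_rng(seed)
    covariates = covariates if covariates is not None else fit._covariates

    boot = np.empty(n_boot)
    failures = 0
    for b in range(n_boot):
        sim = fit.simulate(rng)
        refit = type(fit)(**fit.get_params())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                refit.fit(sim, covariates, start=fit.coef_.copy(), compute_se=False)
            boot[b] = _statistic(refit, sim, statistic)
            if not np.isfinite(boot[b]):
                raise FloatingPointError
        except Exception:
            failures += 1
            boot[b] = np.nan
    ok = np.isfinite(boot)
    if failures > 0.1 * n_boot:
        warnings.warn(f"{failures}/{n_boot} bootstrap refits failed")
    stats = boot[ok]
    p_value = float(np.mean(stats >= observed)) if stats.size else np.nan
    c_hat = float(observed / stats.mean()) if stats.size else np.nan
    return GoFResult(statistic, observed, boot, p_value, c_hat, seed, failures)


def c_hat_inflate(se: float, c_hat: float) -> float:
    """Inflate a standard error by sqrt(c-hat), floored at 1 (no deflation)."""
    if se <= 0:
        raise ValueError("se must be positive")
    return se * float(np.sqrt(max(c_hat, 1.0)))


def residual_map(fit, counts: CountMatrix | None = None) -> pd.Series:
    """Per-site mean Pearson residual (y - E[y]) / sd(y), keyed by site id.

    Intended for joining to site geometry externally and judging spatial
    patterns of lack of fit by eye; no formal spatial test is computed.
    """
    counts = counts if counts is not None else fit._counts
    mu = fit.expected_counts()
    var = fit.cell_variance()
    y = np.where(counts.present, counts.counts, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (y - mu) / np.sqrt(var)
    return pd.Series(np.nanmean(r, axis=1), index=pd.Index(counts.site_ids, name="site_id"),
                     name="mean_pearson_residual")
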