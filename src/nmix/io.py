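"""CSV readers/writers and the model-label mini-language.

All artifacts are plain UTF-8 CSV with ``NA`` as the single missing-value
sentinel.  Count matrices are accepted in two layouts, auto-detected from the
header: replicate-major columns ``rep<k>_occ<t>`` or a flat site x occasion
table (one column per occasion).  Covariate files are checked for prior
Z-standardization so the transform is never applied twice.

Model labels follow the field's compact notation, e.g.
``p(fruit_density)lambda(sal.forest+vildist+human_CR+mixed)`` with ``(.)``
for a constant.
"""

from __future__ import annotations

import hashlib
import json
import re

import numpy as np
import pandas as pd

from .containers import CountMatrix, SiteCovariates
from .models import ModelSpec

__all__ = [
    "read_count_matrix", "write_count_matrix",
    "read_covariates", "write_covariates",
    "parse_model_label", "format_model_label",
    "write_aic_table", "write_coef_table", "write_gof_report",
    "config_hash",
]

_REP_OCC = re.compile(r"^rep(\d+)_occ(\d+)$")


def read_count_matrix(path, column_map: dict | None = None) -> CountMatrix:
    """Read a detection-count CSV; first column is the site id.

    The column layout is auto-detected: headers matching ``rep<k>_occ<t>``
    give the replicate-major layout; anything else is treated as a flat
    site x occasion matrix with a single spatial replicate.  The detected
    layout is recorded on the returned object (``.layout``).
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    if column_map:
        df = df.rename(columns=column_map)
    if df.shape[1] < 2:
        raise ValueError("count CSV needs a site-id column plus count columns")
    site_col = df.columns[0]
    site_ids = df[site_col].astype(str).tolist()
    body = df.drop(columns=[site_col])

    matches = [_REP_OCC.match(c) for c in body.columns]
    vals = body.to_numpy(dtype=float)
    bad = np.argwhere(
        ~np.isnan(vals) & ((vals < 0) | (vals != np.round(vals)))
    )
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"invalid count {vals[i, j]!r} at site {site_ids[i]!r}, "
            f"column {body.columns[j]!r} (must be a non-negative integer or NA)"
        )
    if all(matches):
        reps = sorted({int(m.group(1)) for m in matches})
        occs = sorted({int(m.group(2)) for m in matches})
        n_rep, n_occ = max(reps), max(occs)
        expected = [f"rep{k}_occ{t}" for k in range(1, n_rep + 1)
                    for t in range(1, n_occ + 1)]
        if list(body.columns) != expected:
            body = body.reindex(columns=expected)
            vals = body.to_numpy(dtype=float)
        return CountMatrix(vals, site_ids, n_occ, n_rep, layout="replicate-major")
    return CountMatrix(vals, site_ids, body.shape[1], 1, layout="flat")


def write_count_matrix(counts: CountMatrix, path) -> None:
    df = counts.to_frame()
    body = df.columns[1:]
    df[body] = df[body].astype(object)
    for c in body:
        df[c] = [("NA" if np.isnan(v) else int(v)) for v in df[c]]
    df.to_csv(path, index=False)


# standardized-column detection tolerances: values in a deposited CSV are
# rounded, so exact mean-0/sd-1 cannot be expected
_STD_ATOL = 0.02


def read_covariates(path, site_ids=None, column_map: dict | None = None) -> SiteCovariates:
    """Read a site-covariate CSV; first column is the site id.

    If every column already has mean ~ 0 and sd ~ 1 the table is flagged as
    pre-standardized and left untouched; otherwise it is returned raw (call
    ``standardize()`` before modelling).  When ``site_ids`` is given, the ids
    must match exactly; orphans on either side are reported.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    if column_map:
        df = df.rename(columns=column_map)
    site_col = df.columns[0]
    df[site_col] = df[site_col].astype(str)
    df = df.set_index(site_col)
    df.index.name = "site_id"
    if site_ids is not None:
        want = [str(s) for s in site_ids]
        orphans_file = sorted(set(df.index) - set(want))
        orphans_counts = sorted(set(want) - set(df.index))
        if orphans_file or orphans_counts:
            raise ValueError(
                "site ids do not match the count matrix; "
                f"only in covariates: {orphans_file}; only in counts: {orphans_counts}"
            )
        df = df.loc[want]
    mu = df.mean()
    sd = df.std(ddof=1)
    pre_std = bool((mu.abs() < _STD_ATOL).all() and ((sd - 1).abs() < _STD_ATOL).all())
    if pre_std:
        # nudge to exact Z-scores so downstream invariants hold
        df = (df - mu) / sd
        return SiteCovariates(df, standardized=True, center_=mu * 0, scale_=sd / sd)
    return SiteCovariates(df, standardized=False)


def write_covariates(covs: SiteCovariates, path) -> None:
    covs.data.to_csv(path, na_rep="NA")


# ---------------------------------------------------------------------------
# model labels
# ---------------------------------------------------------------------------

_LABEL = re.compile(
    r"^\s*p\(([^()]*)\)\s*\*?\s*(?:lambda|lam|λ)\s*\*?\s*\(([^()]*)\)\s*$",
    re.IGNORECASE,
)


def parse_model_label(label: str, mixture: str = "poisson",
                      K: int | None = None) -> ModelSpec:
    """Parse ``p(a+b)lambda(c+d)`` notation into a :class:`ModelSpec`."""
    m = _LABEL.match(label.replace("*λ*", "lambda"))
    if not m:
        raise ValueError(
            f"cannot parse model label {label!r}; expected p(...)lambda(...)"
        )

    def _covs(s: str):
        s = s.strip()
        if s in (".", ""):
            return ()
        return tuple(t.strip() for t in s.split("+") if t.strip())

    return ModelSpec(mixture, _covs(m.group(2)), _covs(m.group(1)), K)


def format_model_label(spec: ModelSpec) -> str:
    return spec.label


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def write_aic_table(table: pd.DataFrame, path) -> None:
    """AIC table CSV with columns model,nPars,AIC,dAIC,AICwt,cumltvWt."""
    cols = ["model", "nPars", "AIC", "dAIC", "AICwt", "cumltvWt"]
    table[cols].to_csv(path, index=False, float_format="%.6f")


def write_coef_table(fit, path) -> None:
    """Per-coefficient estimates, SEs and Wald P values (abundance-table layout)."""
    tab = fit.summary().reset_index(names="parameter")
    tab.to_csv(path, index=False, float_format="%.6g")


def write_gof_report(gof, path_csv, path_txt=None) -> None:
    gof.summary().to_csv(path_csv, index=False)
    if path_txt is not None:
        with open(path_txt, "w") as fh:
            fh.write(
                f"Goodness of fit ({gof.statistic_name})\n"
                f"observed statistic: {gof.observed:.4f}\n"
                f"bootstrap p-value:  {gof.p_value:.4f}\n"
                f"c-hat:              {gof.c_hat:.4f}\n"
                f"n_boot:             {len(gof.bootstrap_stats)}\n"
                f"refit failures:     {gof.n_failures}\n"
                f"seed:               {gof.seed}\n"
            )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable run configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
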