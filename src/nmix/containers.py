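"""Core data containers: the site x (replicate, occasion) count matrix and site covariates.

Counts are stored as a float ndarray where ``NaN`` marks a cell that was never
surveyed (camera absent or inactive); ``0`` always means surveyed with no
detections.  Covariates live in a site-indexed DataFrame with an explicit
standardized flag so that Z-scoring is applied exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "SiteCovariates"]


@dataclass
class CountMatrix:
    """Non-negative integer detection counts for R sites over J observation columns.

    Columns are replicate-major: all occasions of spatial replicate 1, then all
    occasions of replicate 2, and so on.  A flat site x occasion matrix is the
    special case ``n_replicates == 1``.

    Parameters
    ----------
    counts : ndarray of shape (R, J), float
        Counts with ``NaN`` for missing cells.
    site_ids : list of str
    n_occasions : int
        Occasions per replicate; ``J == n_replicates * n_occasions``.
    n_replicates : int
        Maximum number of spatial replicates (cameras) per site.
    partial : ndarray of shape (R, J), bool, optional
        Flags cells whose occasion window was only partially covered by the
        camera's active period (reduced effort, counts retained).
    layout : str
        ``"replicate-major"`` or ``"flat"``; records how the source file was
        organised when read from disk.
    """

    counts: np.ndarray
    site_ids: list
    n_occasions: int
    n_replicates: int = 1
    partial: np.ndarray | None = field(default=None, repr=False)
    layout: str = "replicate-major"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        R, J = self.counts.shape
        if R < 1 or J < 1:
            raise ValueError("count matrix must have at least one site and one column")
        if len(self.site_ids) != R:
            raise ValueError(f"{len(self.site_ids)} site ids for {R} rows")
        if J != self.n_replicates * self.n_occasions:
            raise ValueError(
                f"{J} columns incompatible with {self.n_replicates} replicates "
                f"x {self.n_occasions} occasions"
            )
        present = self.counts[~np.isnan(self.counts)]
        if present.size and ((present < 0).any() or (present != np.round(present)).any()):
            raise ValueError("counts must be non-negative integers (or NaN for missing)")
        if self.partial is not None:
            self.partial = np.asarray(self.partial, dtype=bool)
            if self.partial.shape != self.counts.shape:
                raise ValueError("partial-effort flags must match the count matrix shape")

    # -- basic queries -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_columns(self) -> int:
        return self.counts.shape[1]

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of surveyed cells."""
        return ~np.isnan(self.counts)

    def column_labels(self) -> list:
        if self.layout == "flat" and self.n_replicates == 1:
            return [f"occ{t + 1}" for t in range(self.n_occasions)]
        return [
            f"rep{k + 1}_occ{t + 1}"
            for k in range(self.n_replicates)
            for t in range(self.n_occasions)
        ]

    def total(self) -> float:
        return float(np.nansum(self.counts))

    def site_max(self) -> np.ndarray:
        """Per-site maximum observed count (0 where every cell is missing)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmax(self.counts, axis=1)
        return np.where(np.isnan(m), 0.0, m)

    def binarize(self) -> "CountMatrix":
        """Detection (1) / non-detection (0) version; missing cells preserved."""
        b = np.where(np.isnan(self.counts), np.nan, (self.counts > 0).astype(float))
        return CountMatrix(
            b, list(self.site_ids), self.n_occasions, self.n_replicates,
            partial=None if self.partial is None else self.partial.copy(),
            layout=self.layout,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.column_labels())
        df.insert(0, "site_id", self.site_ids)
        return df


@dataclass
class SiteCovariates:
    """Named numeric site covariates aligned with a :class:`CountMatrix`.

    ``center_`` / ``scale_`` hold the original means and sample (n-1) standard
    deviations once :meth:`standardize` has run, so response curves can be
    reported on the raw covariate scale.
    """

    data: pd.DataFrame
    standardized: bool = False
    center_: pd.Series | None = field(default=None, repr=False)
    scale_: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"covariates contain missing values: {bad}")
        non_numeric = [c for c in self.data.columns
                       if not np.issubdtype(self.data[c].dtype, np.number)]
        if non_numeric:
            raise ValueError(f"non-numeric covariate columns: {non_numeric}")
        if self.standardized:
            mu = self.data.mean()
            sd = self.data.std(ddof=1)
            if (mu.abs() > 1e-8).any() or ((sd - 1).abs() > 1e-8).any():
                raise ValueError(
                    "standardized flag set but columns are not Z-scored "
                    "(|mean| or |sd-1| exceeds 1e-8)"
                )

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def names(self) -> list:
        return list(self.data.columns)

    def standardize(self) -> "SiteCovariates":
        """Z-transform every column: (x - mean) / sd with sample (n-1) sd."""
        if self.standardized:
            return self
        mu = self.data.mean()
        sd = self.data.std(ddof=1)
        zero_var = sd[(sd == 0) | sd.isna()].index.tolist()
        if zero_var:
            raise ValueError(f"zero-variance covariate column(s): {zero_var}")
        z = (self.data - mu) / sd
        return SiteCovariates(z, standardized=True, center_=mu, scale_=sd)

    def unstandardize(self) -> "SiteCovariates":
        """Invert :meth:`standardize` using the stored means and sds."""
        if not self.standardized:
            return self
        if self.center_ is None or self.scale_ is None:
            raise ValueError("no stored center/scale to back-transform with")
        raw = self.data * self.scale_ + self.center_
        return SiteCovariates(raw, standardized=False)

    def matrix(self, names, intercept: bool = True) -> np.ndarray:
        """Design matrix with an intercept column followed by ``names``."""
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"unknown covariate(s): {missing}")
        cols = [np.ones(len(self.data))] if intercept else []
        cols.extend(self.data[n].to_numpy(float) for n in names)
        return np.column_stack(cols) if cols else np.empty((len(self.data), 0))
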