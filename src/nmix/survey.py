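"""Camera-trap survey preparation: independence filtering, occasion pooling,
site aggregation, capture rates and covariate QC.

Raw inputs are plain tables.  Photo events need columns ``camera_id``,
``timestamp`` (ISO-8601), ``species``; deployments need ``camera_id``,
``site_id``, ``active_start``, ``active_end``, ``trap_nights``.

The preparation rules implemented here are the standard camera-trap protocol
for unmarked species: consecutive photographs of the same species at the same
camera count as one "independent event" unless separated by at least 30
minutes; independent events are pooled into fixed-length occasions (3 days by
default, 15 occasions) anchored at each camera's own activation date; and the
1-4 cameras inside one grid-cell site become parallel spatial replicate
columns of the count matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CountMatrix, SiteCovariates

__all__ = [
    "filter_independent_events",
    "pool_occasions",
    "aggregate_to_sites",
    "build_count_matrix",
    "capture_rate",
    "standardize_covariates",
    "collinearity_screen",
    "validate_deployments",
]

EVENT_COLUMNS = ("camera_id", "timestamp", "species")
DEPLOYMENT_COLUMNS = ("camera_id", "site_id", "active_start", "active_end", "trap_nights")


def _parse_timestamps(events: pd.DataFrame) -> pd.DataFrame:
    events = events.copy()
    ts = pd.to_datetime(events["timestamp"], errors="coerce")
    if ts.isna().any():
        bad = events.loc[ts.isna()].iloc[0]
        raise ValueError(
            f"unparseable timestamp {bad['timestamp']!r} "
            f"(camera {bad['camera_id']!r}, species {bad['species']!r})"
        )
    events["timestamp"] = ts
    return events


def filter_independent_events(events: pd.DataFrame, min_gap_minutes: float = 30.0) -> pd.DataFrame:
    """Keep only independent photographs within each (camera, species) stream.

    A photo is retained iff it falls at least ``min_gap_minutes`` after the
    previously *retained* photo of the same species at the same camera (the
    first photo of a stream is always retained).  The boundary is inclusive: a
    gap of exactly 30 minutes counts as independent.  Measuring the gap from
    the last retained event guarantees all retained events in a stream are
    pairwise at least the gap apart, and makes the filter idempotent.
    """
    if min_gap_minutes <= 0:
        raise ValueError("min_gap_minutes must be positive")
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            raise ValueError(f"events table lacks required column {col!r}")
    if len(events) == 0:
        return events.copy()
    events = _parse_timestamps(events).reset_index(drop=True)  # indices may repeat after concat
    gap = pd.Timedelta(minutes=min_gap_minutes)
    keep_idx = []
    for _, grp in events.sort_values("timestamp").groupby(["camera_id", "species"], sort=False):
        last = None
        for idx, ts in zip(grp.index, grp["timestamp"]):
            if last is None or ts - last >= gap:
                keep_idx.append(idx)
                last = ts
    out = events.loc[keep_idx]
    return out.sort_values(["camera_id", "species", "timestamp"]).reset_index(drop=True)


def pool_occasions(
    events: pd.DataFrame,
    deployment,
    occasion_length_days: int = 3,
    n_occasions: int = 15,
    drop_partial: bool = False,
):
    """Bin one camera's independence-filtered events into fixed occasions.

    The occasion calendar is anchored at the camera's own ``active_start``:
    occasion t (1-based) covers days [(t-1)*L, t*L).  Occasions wholly outside
    the active period are missing (NaN); occasions only partially covered are
    counted but flagged (or dropped to NaN when ``drop_partial``).  Events
    outside the active period are excluded with a warning.

    Returns ``(counts, partial)``: two length-``n_occasions`` arrays.
    """
    if occasion_length_days <= 0 or n_occasions <= 0:
        raise ValueError("occasion_length_days and n_occasions must be positive")
    start = pd.Timestamp(deployment["active_start"])
    end = pd.Timestamp(deployment["active_end"])
    active_days = (end - start).days + 1
    if active_days <= 0:
        raise ValueError(f"camera {deployment['camera_id']!r}: active_end precedes active_start")

    counts = np.zeros(n_occasions)
    partial = np.zeros(n_occasions, dtype=bool)
    for t in range(n_occasions):
        lo, hi = t * occasion_length_days, (t + 1) * occasion_length_days
        if lo >= active_days:
            counts[t] = np.nan
        elif hi > active_days:
            partial[t] = True

    if len(events):
        events = _parse_timestamps(events)
        day = ((events["timestamp"] - start) / pd.Timedelta(days=1)).to_numpy()
        # active period spans whole calendar days [start, end]
        outside = (day < 0) | (day >= active_days)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} event(s) outside the active period of "
                f"camera {deployment['camera_id']!r} were excluded"
            )
        occ = np.floor(day[~outside] / occasion_length_days).astype(int)
        occ = occ[occ < n_occasions]
        for t in occ:
            counts[t] += 1

    if drop_partial:
        counts[partial] = np.nan
        partial = np.zeros(n_occasions, dtype=bool)
    return counts, partial


def validate_deployments(deployments: pd.DataFrame, max_replicates_warn: int = 4) -> pd.DataFrame:
    for col in DEPLOYMENT_COLUMNS:
        if col not in deployments.columns:
            raise ValueError(f"deployments table lacks required column {col!r}")
    dep = deployments.copy()
    dep["active_start"] = pd.to_datetime(dep["active_start"])
    dep["active_end"] = pd.to_datetime(dep["active_end"])
    days = (dep["active_end"] - dep["active_start"]).dt.days + 1
    bad = dep.loc[dep["trap_nights"] > days, "camera_id"].tolist()
    if bad:
        raise ValueError(f"trap_nights exceeds active span for camera(s): {bad}")
    per_site = dep.groupby("site_id")["camera_id"].nunique()
    crowded = per_site[per_site > max_replicates_warn]
    if len(crowded):
        warnings.warn(
            f"site(s) with more than {max_replicates_warn} cameras: "
            f"{crowded.index.tolist()}"
        )
    return dep


def aggregate_to_sites(camera_rows: dict, deployments: pd.DataFrame,
                       n_occasions: int = 15) -> CountMatrix:
    """Assemble per-camera occasion rows into the site x (replicate, occasion) matrix.

    Cameras inside one site become spatial replicates, ordered by camera id;
    every site gets ``max replicates x n_occasions`` columns (replicate-major),
    with all-missing cells in the surplus replicate columns of sites that had
    fewer cameras.  Missing cells carry no counts, so the matrix total equals
    the total of the per-camera rows.
    """
    dep = validate_deployments(deployments)
    cam_site = dict(zip(dep["camera_id"], dep["site_id"]))
    unknown = [c for c in camera_rows if c not in cam_site]
    if unknown:
        raise ValueError(f"camera(s) with no deployment record: {unknown}")

    site_ids = sorted(dep["site_id"].unique())
    site_cams = {
        s: sorted(dep.loc[dep["site_id"] == s, "camera_id"]) for s in site_ids
    }
    max_reps = max(len(c) for c in site_cams.values())

    R, J = len(site_ids), max_reps * n_occasions
    counts = np.full((R, J), np.nan)
    partial = np.zeros((R, J), dtype=bool)
    for i, s in enumerate(site_ids):
        for k, cam in enumerate(site_cams[s]):
            if cam not in camera_rows:
                continue
            row, flags = camera_rows[cam]
            sl = slice(k * n_occasions, (k + 1) * n_occasions)
            counts[i, sl] = row
            partial[i, sl] = flags
    return CountMatrix(counts, site_ids, n_occasions, max_reps, partial=partial)


def build_count_matrix(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    species: str = "sloth_bear",
    min_gap_minutes: float = 30.0,
    occasion_length_days: int = 3,
    n_occasions: int = 15,
    drop_partial: bool = False,
) -> CountMatrix:
    """Full preparation pipeline: filter -> pool per camera -> aggregate to sites."""
    dep = validate_deployments(deployments)
    focal = events.loc[events["species"] == species]
    indep = filter_independent_events(focal, min_gap_minutes)
    rows = {}
    for _, d in dep.iterrows():
        ev = indep.loc[indep["camera_id"] == d["camera_id"]]
        rows[d["camera_id"]] = pool_occasions(
            ev, d, occasion_length_days, n_occasions, drop_partial
        )
    return aggregate_to_sites(rows, dep, n_occasions)


def capture_rate(n_photos: int, trap_nights: int) -> float:
    """Photographic capture-rate index: independent photos per trap-night."""
    if n_photos < 0:
        raise ValueError("n_photos must be non-negative")
    if trap_nights <= 0:
        raise ValueError("undefined effort: trap_nights must be positive")
    return n_photos / trap_nights


def standardize_covariates(raw: SiteCovariates) -> SiteCovariates:
    """Z-transform all covariate columns (sample sd, denominator n-1)."""
    return raw.standardize()


def collinearity_screen(covs: SiteCovariates, threshold: float = 0.7):
    """Flag covariate pairs with |Pearson r| at or above ``threshold``.

    Model builders refuse formulas that place a flagged pair together.
    Returns a list of ``(name_a, name_b, r)`` tuples.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if len(covs.data) < 3:
        raise ValueError("collinearity screening needs at least 3 sites")
    corr = covs.data.corr(method="pearson")
    flagged = []
    names = covs.names
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= threshold:
                flagged.append((a, b, float(r)))
    return flagged
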