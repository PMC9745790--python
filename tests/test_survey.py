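"""Camera-trap data preparation: independence filter, pooling, aggregation, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nmix import (
    SiteCovariates, aggregate_to_sites, build_count_matrix, capture_rate,
    collinearity_screen, filter_independent_events, pool_occasions,
    standardize_covariates,
)

BASE = pd.Timestamp("2016-12-15 06:00")


def events_at(minutes, camera="C1", species="sloth_bear"):
    return pd.DataFrame({
        "camera_id": camera,
        "timestamp": [(BASE + pd.Timedelta(minutes=m)).isoformat() for m in minutes],
        "species": species,
    })


class TestIndependenceFilter:
    @pytest.mark.parametrize("minutes, n_kept", [
        ([0, 29], 1),            # below-threshold gap collapses
        ([0, 30], 2),            # boundary inclusive: >= 30 min is independent
        ([0, 20, 40, 70], 3),    # last-retained rule keeps {0, 40, 70}
    ])
    def test_gap_rule(self, minutes, n_kept):
        kept = filter_independent_events(events_at(minutes))
        assert len(kept) == n_kept

    def test_last_retained_rule_keeps_expected_times(self):
        kept = filter_independent_events(events_at([0, 20, 40, 70]))
        mins = sorted((pd.to_datetime(kept["timestamp"]) - BASE).dt.total_seconds() / 60)
        assert mins == [0, 40, 70]

    def test_streams_are_independent_per_camera_and_species(self):
        ev = pd.concat([
            events_at([0, 10], camera="C1"),
            events_at([0, 10], camera="C2"),
            events_at([0, 10], camera="C1", species="human"),
        ])
        kept = filter_independent_events(ev)
        assert len(kept) == 3

    def test_unparseable_timestamp_names_record(self):
        ev = events_at([0])
        ev.loc[0, "timestamp"] = "not-a-date"
        with pytest.raises(ValueError, match="not-a-date"):
            filter_independent_events(ev)

    @given(st.lists(st.integers(min_value=0, max_value=5000), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_pairwise_spaced(self, minutes):
        kept = filter_independent_events(events_at(sorted(minutes)))
        again = filter_independent_events(kept)
        assert kept["timestamp"].tolist() == again["timestamp"].tolist()
        t = pd.to_datetime(kept["timestamp"]).sort_values()
        gaps = t.diff().dropna().dt.total_seconds() / 60
        assert (gaps >= 30).all()


def _deployment(days=45, camera="C1", site="S1", start=BASE.normalize()):
    return pd.Series({
        "camera_id": camera, "site_id": site,
        "active_start": start, "active_end": start + pd.Timedelta(days=days - 1),
        "trap_nights": days,
    })


class TestPooling:
    def test_full_deployment_has_15_defined_occasions(self):
        counts, partial = pool_occasions(events_at([]), _deployment(45))
        assert counts.shape == (15,)
        assert not np.isnan(counts).any() and not partial.any()

    def test_short_deployment_partial_and_missing(self):
        counts, partial = pool_occasions(events_at([]), _deployment(13))
        assert (counts[:5] == 0).all()
        assert partial[4] and not partial[:4].any()
        assert np.isnan(counts[5:]).all()

    def test_drop_partial_turns_flagged_occasion_missing(self):
        counts, partial = pool_occasions(events_at([]), _deployment(13), drop_partial=True)
        assert np.isnan(counts[4]) and not partial.any()

    def test_binning_by_day(self):
        # events on active days 1, 2 and 8 (1-based) -> occasions 1, 1 and 3
        start = BASE.normalize()
        ev = events_at([0, 24 * 60, 7 * 24 * 60])
        ev["timestamp"] = [
            (start + pd.Timedelta(minutes=m)).isoformat() for m in (0, 24 * 60, 7 * 24 * 60)
        ]
        counts, _ = pool_occasions(ev, _deployment(45, start=start))
        assert counts[0] == 2 and counts[2] == 1 and np.nansum(counts) == 3

    def test_event_outside_active_period_warns_and_is_excluded(self):
        start = BASE.normalize()
        ev = events_at([0])
        ev["timestamp"] = [(start + pd.Timedelta(days=50)).isoformat()]
        with pytest.warns(UserWarning, match="outside the active period"):
            counts, _ = pool_occasions(ev, _deployment(45, start=start))
        assert np.nansum(counts) == 0


class TestAggregation:
    def test_single_camera_sites_identity(self):
        deps = pd.DataFrame([_deployment(45, "C1", "S1"), _deployment(45, "C2", "S2")])
        rows = {"C1": (np.arange(15.0), np.zeros(15, bool)),
                "C2": (np.ones(15), np.zeros(15, bool))}
        cm = aggregate_to_sites(rows, deps)
        assert cm.counts.shape == (2, 15)
        assert np.array_equal(cm.counts[0], np.arange(15.0))

    def test_surplus_replicate_columns_missing(self):
        deps = pd.DataFrame([
            _deployment(45, "C1", "S1"), _deployment(45, "C2", "S1"),
            _deployment(45, "C3", "S2"), _deployment(45, "C4", "S2"),
            _deployment(45, "C5", "S2"), _deployment(45, "C6", "S2"),
        ])
        rows = {c: (np.ones(15), np.zeros(15, bool)) for c in deps["camera_id"]}
        cm = aggregate_to_sites(rows, deps)
        assert cm.n_columns == 60            # 4 replicates x 15 occasions
        row = cm.counts[list(cm.site_ids).index("S1")]
        assert np.isnan(row).sum() == 30 and np.nansum(row) == 30

    def test_total_count_preserved(self):
        deps = pd.DataFrame([_deployment(45, "C1", "S1"), _deployment(45, "C2", "S1")])
        rows = {"C1": (np.full(15, 2.0), np.zeros(15, bool)),
                "C2": (np.full(15, 1.0), np.zeros(15, bool))}
        cm = aggregate_to_sites(rows, deps)
        assert cm.total() == 45

    def test_unknown_camera_is_an_error(self):
        deps = pd.DataFrame([_deployment(45, "C1", "S1")])
        with pytest.raises(ValueError, match="no deployment record"):
            aggregate_to_sites({"CX": (np.zeros(15), np.zeros(15, bool))}, deps)

    def test_matrix_total_equals_retained_events_in_windows(self):
        start = BASE.normalize()
        deps = pd.DataFrame([_deployment(45, "C1", "S1")])
        minutes = [0, 10, 40, 3 * 24 * 60, 46 * 24 * 60]  # last one outside
        ev = events_at(minutes)
        ev["timestamp"] = [(start + pd.Timedelta(minutes=m)).isoformat() for m in minutes]
        with pytest.warns(UserWarning):
            cm = build_count_matrix(ev, deps)
        # retained: 0, 40 (10 collapses), 3-day mark; the day-46 one is outside
        assert cm.total() == 3


class TestCaptureRate:
    @pytest.mark.parametrize("n, nights, rate", [(0, 40, 0.0), (12, 40, 0.3)])
    def test_rate(self, n, nights, rate):
        assert capture_rate(n, nights) == pytest.approx(rate)

    def test_zero_effort_is_an_error(self):
        with pytest.raises(ValueError, match="effort"):
            capture_rate(5, 0)


class TestCovariateQC:
    def test_z_score_example(self):
        covs = SiteCovariates(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        z = standardize_covariates(covs)
        assert np.allclose(z.data["x"], [-1, 0, 1])
        assert z.standardized

    def test_zero_variance_column_named_in_error(self):
        covs = SiteCovariates(pd.DataFrame({"flat": [5.0, 5.0, 5.0]}))
        with pytest.raises(ValueError, match="flat"):
            standardize_covariates(covs)

    def test_round_trip_recovers_raw(self, raw_covs):
        back = standardize_covariates(raw_covs).unstandardize()
        assert np.allclose(back.data.values, raw_covs.data.values, atol=1e-10)

    def test_means_and_sds_after_transform(self, raw_covs):
        z = standardize_covariates(raw_covs)
        assert np.allclose(z.data.mean(), 0, atol=1e-8)
        assert np.allclose(z.data.std(ddof=1), 1, atol=1e-8)

    def test_collinearity_flags(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({
            "x": x, "dup": x, "noisy": 0.9 * x + rng.normal(scale=0.1, size=50),
            "ortho1": np.resize([1.0, -1.0], 50), "ortho2": np.resize([1.0, 1.0, -1.0, -1.0], 48 + 2),
        })
        covs = SiteCovariates(df)
        flagged = {frozenset(p[:2]) for p in collinearity_screen(covs)}
        assert frozenset(("x", "dup")) in flagged
        assert frozenset(("x", "noisy")) in flagged
        assert frozenset(("ortho1", "ortho2")) not in flagged
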