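"""Series preprocessing, cross-correlation, density and summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import larvadrift as ld
from larvadrift.biology import (FATE_DIED_AGE, FATE_DIED_PHYSIOLOGY,
                                FATE_LEFT_DOMAIN, FATE_RECRUITED)
from larvadrift.exceptions import ParameterError
from larvadrift.stats import (compare_density_profiles, cross_correlation,
                              dispersal_summary, preprocess, survival_summary,
                              trajectory_density)


class TestPreprocess:
    def test_constant_series_maps_to_zero(self):
        out = preprocess(np.full(30, 7.0))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_linear_ramp_differences_to_slope(self):
        out = preprocess(np.arange(30, dtype=float))
        np.testing.assert_allclose(out.values, 1.0, atol=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.poisson(5, 60).astype(float)
        out = preprocess(v).values
        # brute-force: centered MA-5 by direct summation, then difference
        ma = np.array([v[i - 2:i + 3].sum() / 5.0 for i in range(2, 58)])
        oracle = ma[1:] - ma[:-1]
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_trimmed_length(self):
        assert preprocess(np.arange(30.0)).values.size == 30 - 4 - 1

    def test_too_short_series_rejected(self):
        with pytest.raises(ParameterError):
            preprocess(np.arange(6.0))

    @given(st.integers(min_value=8, max_value=200))
    @settings(deadline=None)
    def test_length_invariant(self, n):
        v = np.sin(np.arange(n, dtype=float))
        assert preprocess(v).values.size == n - 5

    def test_accepts_supply_series(self):
        s = ld.SupplySeries(pd.date_range("2006-02-01", periods=20, freq="D"),
                            np.arange(20.0), "A")
        assert preprocess(s).values.size == 15


class TestCrossCorrelation:
    def test_self_correlation_peaks_at_zero(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=80)
        cc = cross_correlation(v, v, 10)
        assert cc.best_lag == 0 and np.isclose(cc.best_r, 1.0)

    def test_predicted_leading_gives_negative_lag(self):
        """Observed repeats the predicted pulses 3 days later -> lag -3."""
        rng = np.random.default_rng(6)
        pred = rng.poisson(4, 120).astype(float)
        obs = np.roll(pred, 3)  # predicted maxima precede the observations
        cc = cross_correlation(obs[5:-5], pred[5:-5], 6)
        assert cc.best_lag == -3
        # brute-force confirmation of the argmax
        best = max(range(-6, 7), key=lambda k: np.corrcoef(
            pred[5:-5][k:] if k >= 0 else pred[5:-5][:k],
            obs[5:-5][:len(obs[5:-5]) - k] if k >= 0 else obs[5:-5][-k:])[0, 1])
        assert best == cc.best_lag

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=60), rng.normal(size=60)
        ab = cross_correlation(a, b, 5)
        ba = cross_correlation(b, a, 5)
        np.testing.assert_allclose(ab.r, ba.r[::-1], atol=1e-12)

    def test_matches_statsmodels_at_positive_lags(self):
        """Independent oracle: statsmodels ccf with demeaned inputs."""
        from statsmodels.tsa.stattools import ccf as sm_ccf
        rng = np.random.default_rng(8)
        pred = rng.normal(size=200)
        obs = rng.normal(size=200) + 0.5 * pred
        cc = cross_correlation(obs, pred, 4)
        ref = sm_ccf(pred, obs, adjusted=False)[:5]  # corr(pred[t], obs[t-k])
        mine = cc.r[4:]  # lags 0..4
        np.testing.assert_allclose(mine, ref, atol=0.05)

    def test_white_noise_null_calibration(self):
        """|r| at lag 0 below 1.96/sqrt(N) in ~95% of independent pairs."""
        rng = np.random.default_rng(9)
        n, hits, reps = 100, 0, 300
        for _ in range(reps):
            a, b = rng.normal(size=n), rng.normal(size=n)
            cc = cross_correlation(a, b, 0)
            hits += abs(cc.r[0]) < 1.96 / np.sqrt(n)
        assert hits / reps > 0.90

    def test_zero_variance_segment_reported_missing(self):
        a = np.concatenate([np.zeros(20), np.random.default_rng(1).normal(size=20)])
        cc = cross_correlation(a, a, 25)
        assert np.isnan(cc.r).any()


class TestTrajectoryDensity:
    def test_stationary_particle_counts_once(self):
        x = np.full((10, 1), 5.0)
        y = np.full((10, 1), 100.0)
        grid = trajectory_density(x, y, (50.0, 150.0), np.arange(0, 61, 3.0))
        assert grid.counts.sum() == 1
        assert grid.counts[1] == 1  # x=5 falls in column [3, 6)

    def test_monotone_crossing_counts_each_column_once(self):
        x = np.array([[1.0], [4.0], [7.0]])
        y = np.full((3, 1), 100.0)
        grid = trajectory_density(x, y, (50.0, 150.0), np.arange(0, 61, 3.0))
        np.testing.assert_array_equal(grid.counts[:3], [1, 1, 1])
        assert grid.counts.sum() == 3

    def test_outside_band_ignored(self):
        x = np.array([[1.0], [4.0]])
        y = np.full((2, 1), 500.0)
        grid = trajectory_density(x, y, (50.0, 150.0), np.arange(0, 61, 3.0))
        assert grid.counts.sum() == 0

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(12)
        nt, npart = 40, 25
        x = np.cumsum(rng.normal(0, 2, (nt, npart)), axis=0) + 30.0
        y = np.cumsum(rng.normal(0, 5, (nt, npart)), axis=0) + 100.0
        edges = np.arange(0, 61, 3.0)
        band = (60.0, 140.0)
        grid = trajectory_density(x, y, band, edges)
        counts = np.zeros(edges.size - 1)
        for p in range(npart):
            prev = -1
            for k in range(nt):
                in_band = band[0] <= y[k, p] <= band[1] and \
                    edges[0] <= x[k, p] <= edges[-1]
                col = int(np.searchsorted(edges, x[k, p], side="right") - 1) \
                    if in_band else -1
                col = min(col, edges.size - 2)
                if col >= 0 and col != prev:
                    counts[col] += 1
                prev = col
        np.testing.assert_array_equal(grid.counts, counts)


class TestDensityComparison:
    def test_identical_profiles_correlate_perfectly(self):
        prof = np.array([40.0, 25.0, 10.0, 2.0, 0.0, 0.0])
        r, p = compare_density_profiles(prof, prof)
        assert np.isclose(r, 1.0)

    def test_matches_direct_pearson_on_log_values(self):
        rng = np.random.default_rng(13)
        a = rng.poisson(10, 12).astype(float)
        b = rng.permutation(a)
        r, _ = compare_density_profiles(a, b)
        la, lb = np.log(a + 1), np.log(b + 1)
        oracle = (np.sum((la - la.mean()) * (lb - lb.mean()))
                  / np.sqrt(np.sum((la - la.mean()) ** 2)
                            * np.sum((lb - lb.mean()) ** 2)))
        assert np.isclose(r, oracle, rtol=1e-10)

    def test_bonferroni_doubles_p_for_two_comparisons(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(size=10), rng.normal(size=10)
        _, p1 = compare_density_profiles(np.abs(a), np.abs(b), n_comparisons=1)
        _, p2 = compare_density_profiles(np.abs(a), np.abs(b), n_comparisons=2)
        assert np.isclose(p2, min(1.0, 2 * p1))


def _event_frame(rows):
    return pd.DataFrame(rows, columns=list(ld.recruitment.EVENT_COLUMNS))


class TestDispersalSummary:
    def test_self_recruitment_only(self, estuaries):
        rows = [(0, i, "Aveiro", "Aveiro", 100.0, 4.2, 317.0, 317.0)
                for i in range(5)]
        d = dispersal_summary(_event_frame(rows), estuaries, "Aveiro")
        assert d.self_recruitment_fraction == 1.0
        assert np.isnan(d.mean_south_km) and np.isnan(d.mean_north_km)

    def test_southern_source_57km_is_negative(self, estuaries):
        rows = [(0, 0, "Mondego", "Aveiro", 100.0, 4.2, 260.0, 317.0)]
        d = dispersal_summary(_event_frame(rows), estuaries, "Aveiro")
        assert d.mean_south_km == -57.0 and d.max_south_km == -57.0

    def test_aggregates_match_brute_force_recount(self, estuaries):
        rng = np.random.default_rng(15)
        y = {e.name: e.y_center_km for e in estuaries}
        names = list(y)
        rows = [(0, i, src, "Aveiro", rng.uniform(0, 2000), 4.5,
                 y[src], y["Aveiro"])
                for i, src in enumerate(rng.choice(names, 40))]
        d = dispersal_summary(_event_frame(rows), estuaries, "Aveiro")
        dist = np.array([r[6] - r[7] for r in rows])
        assert np.isclose(d.mean_north_km, dist[dist > 0].mean())
        assert np.isclose(d.mean_south_km, dist[dist < 0].mean())
        assert d.n_recruits == 40
        assert np.isclose(d.daily_contribution.sum(),
                          40 / max(1, int(np.ceil(max(r[4] for r in rows) / 24))))


class TestSurvivalSummary:
    def test_worked_identity_13_37_50(self):
        """13% recruited + 37% physiological mortality -> 50% wastage."""
        f = np.concatenate([np.full(13, FATE_RECRUITED),
                            np.full(37, FATE_DIED_PHYSIOLOGY),
                            np.full(30, FATE_LEFT_DOMAIN),
                            np.full(20, FATE_DIED_AGE)])
        s = survival_summary(f)
        assert (s.pct_recruited, s.pct_died_physiology, s.pct_wastage) == \
            (13.0, 37.0, 50.0)

    def test_all_recruited_no_mortality(self):
        s = survival_summary(np.full(50, FATE_RECRUITED))
        assert (s.pct_recruited, s.pct_died_physiology, s.pct_wastage) == \
            (100.0, 0.0, 0.0)

    @given(st.lists(st.integers(min_value=0, max_value=4), min_size=1,
                    max_size=300))
    @settings(deadline=None)
    def test_percentages_recompute_from_raw_fates(self, fates):
        f = np.array(fates)
        s = survival_summary(f)
        assert np.isclose(s.pct_recruited,
                          100 * np.mean(f == FATE_RECRUITED))
        assert np.isclose(s.pct_recruited + s.pct_died_physiology
                          + s.pct_wastage, 100.0)
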