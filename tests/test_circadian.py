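"""Tests for phase labelling, autocorrelation and SOM/Ward clustering."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from respirhythm import (
    PhotoperiodSchedule,
    acf,
    bmu_assign,
    cluster_phase_association,
    dominant_period,
    hourly_features,
    label_phases,
    phase_summary,
    rhythm_summary,
    som_phase_analysis,
    som_train,
    ward_clusters,
)
from respirhythm.circadian import ward_linkage


class TestPhaseLabels:
    def test_clock_examples(self):
        # start 08:00; t=4 h -> 12:00 (photophase), t=14 h -> 22:00 (scotophase)
        flags = label_phases([4.0, 14.0])
        assert flags.tolist() == [True, False]

    def test_week_of_hourly_stamps_splits_16_to_8(self):
        flags = label_phases(np.arange(168.0))
        assert int(flags.sum()) == 112
        assert int((~flags).sum()) == 56

    def test_overnight_photophase_schedule(self):
        sched = PhotoperiodSchedule(lights_on=22.0, lights_off=6.0)
        assert label_phases([0.0], sched, start_clock=23.0).tolist() == [True]
        assert label_phases([0.0], sched, start_clock=12.0).tolist() == [False]


class TestPhaseSummary:
    def test_constant_series(self):
        flags = label_phases(np.arange(48.0))
        out = phase_summary(np.full(48, 5.0), flags)
        assert out["overall"][0] == out["light"][0] == out["dark"][0] == 5.0

    def test_alternating_toy_series(self):
        flags = np.array([True, False] * 10)
        values = np.where(flags, 1.0, 0.0)
        out = phase_summary(values, flags)
        assert out["light"] == (1.0, 0.0)
        assert out["dark"] == (0.0, 0.0)

    def test_empty_phase_rejected(self):
        with pytest.raises(ValueError, match="dark"):
            phase_summary(np.ones(5), np.ones(5, dtype=bool))


class TestAcf:
    def test_pure_cosine_period_structure(self):
        t = np.arange(168.0)
        x = np.cos(2 * np.pi * t / 24.0)
        r = acf(x, max_lag=30, detrend=False)
        assert r[0] == pytest.approx(1.0)
        assert r[24] > 0.95
        assert r[12] < -0.9

    @given(st.lists(st.floats(-10, 10), min_size=10, max_size=40))
    def test_unit_lag_zero_and_bounded(self, values):
        x = np.asarray(values)
        if np.ptp(x) == 0:
            return
        r = acf(x, max_lag=5, detrend=False)
        assert r[0] == pytest.approx(1.0)
        finite = r[np.isfinite(r)]
        assert np.all(np.abs(finite) <= 1 + 1e-12)

    def test_bounded_with_missing_values(self, rng):
        x = rng.normal(size=200)
        x[rng.integers(0, 200, 30)] = np.nan
        r = acf(x, max_lag=40)
        assert r[0] == pytest.approx(1.0)
        assert np.all(np.abs(r[np.isfinite(r)]) <= 1 + 1e-12)

    def test_white_noise_mostly_inside_confidence_band(self):
        x = np.random.default_rng(0).normal(size=500)
        r = acf(x, max_lag=72, detrend=False)
        inside = np.abs(r[1:]) < 2 / np.sqrt(500)
        assert inside.mean() >= 0.90  # nominal coverage ~95%

    def test_matches_statsmodels_on_complete_series(self):
        sm = pytest.importorskip("statsmodels.tsa.stattools")
        rng = np.random.default_rng(4)
        t = np.arange(2000.0)
        x = np.cos(2 * np.pi * t / 24) + 0.5 * rng.normal(size=t.size)
        mine = acf(x, max_lag=30, detrend=False)
        ref = sm.acf(x - x.mean(), nlags=30, adjusted=False, fft=True)
        np.testing.assert_allclose(mine, ref, atol=0.02)

    def test_constant_series_flagged_arrhythmic(self):
        with pytest.raises(ValueError):
            acf(np.full(100, 3.0), max_lag=10)
        summary = rhythm_summary(np.full(100, 3.0), max_lag=10, search_band=(3, 8))
        assert summary.arrhythmic and summary.dominant_period is None


class TestDominantPeriod:
    def test_pure_24h_cosine(self):
        t = np.arange(168.0)
        r = acf(np.cos(2 * np.pi * t / 24.0), max_lag=72, detrend=False)
        assert dominant_period(r) == 24

    def test_no_positive_local_maximum_is_arrhythmic(self):
        r = 1.0 / (1.0 + np.arange(73.0)) - 0.5  # negative throughout the band
        assert dominant_period(r) is None

    def test_band_beyond_computed_lags_rejected(self):
        with pytest.raises(ValueError, match="band"):
            dominant_period(np.ones(20), search_band=(18, 30))


class TestSom:
    def test_identical_samples_collapse_codebook(self):
        X = np.tile([1.5, -2.0, 0.25], (12, 1))
        code, _ = som_train(X, grid=(4, 3), epochs=50, seed=0)
        assert np.max(np.abs(code - X[0])) <= 1e-6

    def test_separates_two_point_clouds(self, rng):
        a = rng.normal([0, 0, 0], 0.1, (40, 3))
        b = rng.normal([10, 10, 10], 0.1, (40, 3))
        X = np.vstack([a, b])
        code, _ = som_train(X, grid=(4, 4), epochs=100, seed=1)
        assign = bmu_assign(X, code)
        # oracle: nearest-centroid classification of the codebook units
        centroids = np.vstack([a.mean(0), b.mean(0)])
        unit_side = np.argmin(
            ((code[:, None, :] - centroids[None]) ** 2).sum(-1), axis=1
        )
        labels = unit_side[assign]
        assert np.all(labels[:40] == labels[0])
        assert np.all(labels[40:] == 1 - labels[0])

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(30, 4))
        c1, _ = som_train(X, epochs=20, seed=5)
        c2, _ = som_train(X, epochs=20, seed=5)
        c3, _ = som_train(X, epochs=20, seed=6)
        np.testing.assert_array_equal(c1, c2)
        assert not np.array_equal(c1, c3)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            som_train(np.ones((1, 3)))
        with pytest.raises(ValueError, match="finite"):
            som_train(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestWard:
    def test_k_equal_units_gives_singletons(self, rng):
        code = rng.normal(size=(6, 3))
        labels = ward_clusters(code, k=6)
        assert sorted(labels) == [1, 2, 3, 4, 5, 6]

    def test_two_separated_blobs_recovered_exactly(self, rng):
        code = np.vstack([rng.normal(0, 0.2, (8, 2)), rng.normal(12, 0.2, (8, 2))])
        labels = ward_clusters(code, k=2)
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[-1]

    def test_linkage_matches_hand_computed_ward_distances(self):
        # collinear points 0, 1, 5, 6: merge (0,1) and (5,6) at height 1,
        # then the pairs at sqrt(2*2/(2+2)) * |0.5-5.5| * 2 = sqrt(50)
        pts = np.array([[0.0], [1.0], [5.0], [6.0]])
        Z = ward_linkage(pts)
        heights = sorted(Z[:, 2])
        assert heights[0] == pytest.approx(1.0)
        assert heights[1] == pytest.approx(1.0)
        assert heights[2] == pytest.approx(np.sqrt(50.0))

    def test_too_many_clusters_rejected(self, rng):
        with pytest.raises(ValueError):
            ward_clusters(rng.normal(size=(4, 2)), k=5)


class TestClusterPhaseAssociation:
    def test_perfectly_separated_clusters_have_unit_purity(self):
        clusters = np.array([1] * 10 + [2] * 14)
        flags = np.array([False] * 10 + [True] * 14)
        table = cluster_phase_association(clusters, flags)
        assert table.loc[1, "majority"] == "scotophase"
        assert table.loc[2, "majority"] == "photophase"
        assert np.allclose(table["purity"], 1.0)

    def test_random_flags_sit_near_light_fraction_baseline(self, rng):
        clusters = np.repeat(np.arange(1, 7), 50)
        flags = rng.random(300) < 16 / 24
        table = cluster_phase_association(clusters, rng.permutation(flags))
        assert 0.58 <= table["purity"].mean() <= 0.80  # baseline 16/24 = 0.667

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            cluster_phase_association([1, 1, 2], [True, False])


class TestFeatureAssembly:
    def test_zscoring_and_bihourly_interpolation(self):
        hours = np.arange(24.0) + 0.5
        fine = (hours, np.sin(hours))
        coarse_t = np.arange(1.0, 24.0, 2.0)
        coarse = (coarse_t, 2.0 * coarse_t)  # linear -> interpolation is exact
        X = hourly_features(hours, {"A": fine, "B": coarse})
        assert X.shape == (24, 2)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(X.std(axis=0), 1.0, atol=1e-12)
        # column B must stay perfectly linear inside the coarse grid's span
        # (np.interp holds the edges constant outside it)
        interior = (hours >= coarse_t[0]) & (hours <= coarse_t[-1])
        h, y = hours[interior], X[interior, 1]
        resid = np.polyval(np.polyfit(h, y, 1), h) - y
        assert np.max(np.abs(resid)) < 1e-9

    def test_constant_parameter_rejected(self):
        hours = np.arange(10.0)
        with pytest.raises(ValueError, match="constant"):
            hourly_features(hours, {"A": (hours, np.ones(10))})


class TestNoiselessPresetPeriodicity:
    @pytest.mark.parametrize("group", ["control", "phe", "pyr"])
    def test_noiseless_presets_show_exact_24h_period_everywhere(self, group):
        """Without sensor noise, every parameter of every preset carries an
        exactly 24-h dominant period through the full pipeline."""
        from dataclasses import replace

        from respirhythm import (
            analyze_traceset,
            generate_dataset,
            group_mean_series,
            preset_profile,
        )
        from respirhythm.rates import PARAMETERS

        profile = replace(preset_profile(group),
                          noise_sd={c: 0.0 for c in ("O2", "CO2", "NH3N")},
                          tank_effect_sd=0.0)
        ds = generate_dataset(profile, days=7, tanks=1, seed=0)
        series = group_mean_series(analyze_traceset(ds))
        hours = series["OR"][0]
        for name in PARAMETERS:
            t, v = series[name]
            if v.shape != hours.shape:
                ok = np.isfinite(v)
                v = np.interp(hours, t[ok], v[ok])
            summary = rhythm_summary(v)
            assert summary.dominant_period == 24, name


class TestSomPhaseAnalysis:
    def test_separable_features_yield_pure_relabelled_clusters(self, rng):
        flags = label_phases(np.arange(96.0))
        base = np.where(flags, 1.0, -1.0)
        X = np.column_stack([base + 0.05 * rng.normal(size=96) for _ in range(3)])
        result = som_phase_analysis(X, flags, grid=(4, 4), k=2, epochs=100, seed=2)
        assert result.phase_table["purity"].min() > 0.95
        # relabelling: cluster 1 is the scotophase-dominated one
        assert result.phase_table.loc[1, "majority"] == "scotophase"
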