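"""Capture–recapture estimators, MMDM geometry, and density arithmetic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import shapely

from onca import cmr
from onca import landscape as L
from onca.errors import (DegenerateGeometryError, InconsistentInputError,
                         InvalidArgumentError, UndefinedMMDMError)


def make_detections(rows):
    return pd.DataFrame(rows, columns=["individual", "station", "night",
                                       "x_km", "y_km"])


class TestEncounterHistory:
    def test_ninety_nights_in_nine_night_occasions(self):
        det = make_detections([("a", "S1", n, 0.0, 0.0) for n in (1, 90)])
        hist = cmr.build_encounter_history(det, 9)
        assert hist.occasions == 10
        assert hist.occasion_nights[0] == (1, 9)
        assert hist.occasion_nights[-1] == (82, 90)

    def test_always_detected_gives_all_ones_row(self):
        det = make_detections([("a", "S1", n, 0.0, 0.0) for n in range(1, 31)])
        hist = cmr.build_encounter_history(det, 3)
        assert hist.matrix.shape == (1, 10)
        assert hist.matrix.sum() == 10

    def test_manual_toy_matrix(self):
        # 7 detections, 3 individuals, occasion length 2 over nights 1..8
        det = make_detections([
            ("a", "S1", 1, 0, 0), ("a", "S2", 2, 1, 0), ("a", "S1", 5, 0, 0),
            ("b", "S1", 3, 0, 0), ("b", "S2", 8, 1, 0),
            ("c", "S2", 4, 1, 0), ("c", "S1", 7, 0, 0)])
        hist = cmr.build_encounter_history(det, 2)
        expected = np.array([[1, 0, 1, 0],     # a: nights 1,2 / 5
                             [0, 1, 0, 1],     # b: nights 3 / 8
                             [0, 1, 0, 1]])    # c: nights 4 / 7
        np.testing.assert_array_equal(hist.matrix, expected)

    def test_unknown_station_rejected(self):
        det = make_detections([("a", "S1", 1, 0, 0)])
        stations = pd.DataFrame({"station": ["S9"], "x_km": [0.0], "y_km": [0.0]})
        with pytest.raises(InconsistentInputError):
            cmr.build_encounter_history(det, 2, stations)


def m0_grid_oracle(X, n_max=500):
    """Brute-force integer maximization of the M0 profile likelihood."""
    mt1, t = X.shape
    total = int(X.sum())
    grid = np.arange(mt1, n_max + 1, dtype=float)
    lls = [cmr._m0_loglik(n, mt1, total, t) for n in grid]
    return float(grid[int(np.argmax(lls))]), float(np.max(lls))


class TestM0:
    def test_saturated_history_hits_boundary(self):
        X = np.ones((5, 4), dtype=int)
        est = cmr.estimate_m0(X)
        assert est.n_hat == 5 and est.p_hat == 1.0 and est.boundary

    def test_two_occasion_grid_search_and_lincoln_petersen(self):
        # n1=10, n2=8, overlap 4 -> Lincoln-Petersen N = 20
        X = np.array([[1, 1]] * 4 + [[1, 0]] * 6 + [[0, 1]] * 4)
        est = cmr.estimate_m0(X)
        n_grid, ll_grid = m0_grid_oracle(X)
        assert abs(est.n_hat - n_grid) <= 1.0
        assert cmr._m0_loglik(est.n_hat, 14, 18, 2) >= ll_grid - 1e-9
        assert abs(est.n_hat - 20.0) < 2.0

    def test_matches_grid_search_on_random_histories(self, rng):
        """Continuous MLE agrees with brute-force integer grid search on
        every generated history with M_{t+1} <= 30."""
        for trial in range(40):
            t = int(rng.integers(3, 11))
            n = int(rng.integers(5, 31))
            p = rng.uniform(0.1, 0.6)
            X = (rng.random((n, t)) < p).astype(int)
            X = X[X.sum(axis=1) > 0]
            if (X.shape[0] < 2 or X.shape[0] > 30
                    or X.sum() == X.shape[0]):   # no recaptures: no finite MLE
                continue
            est = cmr.estimate_m0(X)
            n_grid, ll_grid = m0_grid_oracle(X)
            assert abs(est.n_hat - n_grid) <= 1.0
            assert cmr._m0_loglik(est.n_hat, X.shape[0], int(X.sum()),
                                  X.shape[1]) >= ll_grid - 1e-9

    def test_simulation_recovery(self, rng):
        """M0 data (N=60, p=0.25, t=10): mean N-hat within 5% of truth."""
        n_hats = []
        for _ in range(500):
            X = (rng.random((60, 10)) < 0.25).astype(int)
            X = X[X.sum(axis=1) > 0]
            n_hats.append(cmr.estimate_m0(X).n_hat)
        assert abs(np.mean(n_hats) - 60.0) < 0.05 * 60.0


def leave_d_out_jackknife(X, k):
    """Independent oracle: generalized jackknife from leave-d-occasions-out
    means of the distinct-individual count."""
    t = X.shape[1]
    total = 0.0
    for d in range(k + 1):
        vals = [(X[:, list(c)].sum(axis=1) > 0).sum()
                for c in itertools.combinations(range(t), t - d)]
        total += ((-1) ** d * math.comb(k, d) * (t - d) ** k
                  / math.factorial(k) * np.mean(vals))
    return total


class TestMhJackknife:
    def test_first_order_collapses_without_singletons(self):
        # every individual captured twice: f1 = 0 so N_J1 = M_{t+1}
        X = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        coef = cmr.jackknife_coefficients(3, 1)
        f = np.array([0, 3, 0])
        assert coef @ f == 3.0

    def test_closed_form_first_order(self):
        # t=5, f=(4,3,2,0,0): N_J1 = 9 + (4/5)*4 = 12.2
        rows = ([[1, 0, 0, 0, 0]] * 4 + [[1, 1, 0, 0, 0]] * 3
                + [[1, 1, 1, 0, 0]] * 2)
        X = np.array(rows)
        f = cmr._freqs(X)
        np.testing.assert_array_equal(f, [4, 3, 2, 0, 0])
        coef = cmr.jackknife_coefficients(5, 1)
        assert coef @ f == pytest.approx(12.2)

    def test_coefficients_match_generalized_jackknife_oracle(self, rng):
        for trial in range(10):
            t = int(rng.integers(6, 9))
            X = (rng.random((20, t)) < rng.uniform(0.15, 0.5)).astype(int)
            X = X[X.sum(axis=1) > 0]
            if X.shape[0] < 5:
                continue
            f = cmr._freqs(X)
            for k in range(1, 6):
                mine = cmr.jackknife_coefficients(t, k) @ f
                oracle = leave_d_out_jackknife(X, k)
                assert mine == pytest.approx(oracle, rel=1e-10, abs=1e-8)

    def test_estimate_exceeds_observed_count(self, rng):
        for trial in range(20):
            X = (rng.random((30, 8)) < 0.2).astype(int)
            X = X[X.sum(axis=1) > 0]
            if X.shape[0] < 3:
                continue
            est = cmr.estimate_mh_jackknife(X)
            assert est.n_hat >= est.m_t1 - 1e-9
            m0 = cmr.estimate_m0(X)
            assert m0.n_hat >= m0.m_t1 - 1e-9

    def test_heterogeneity_favours_mh_over_m0(self, rng):
        """Under logit-normal detection heterogeneity M0 is negatively
        biased; the jackknife Mh mean lands closer to truth."""
        from scipy.special import expit, logit
        n_true, t = 60, 10
        m0_means, mh_means = [], []
        for _ in range(500):
            p_i = expit(logit(0.25) + rng.normal(0, 0.75, n_true))
            X = (rng.random((n_true, t)) < p_i[:, None]).astype(int)
            X = X[X.sum(axis=1) > 0]
            m0_means.append(cmr.estimate_m0(X).n_hat)
            mh_means.append(cmr.estimate_mh_jackknife(X).n_hat)
        m0_err = abs(np.mean(m0_means) - n_true)
        mh_err = abs(np.mean(mh_means) - n_true)
        assert mh_err < m0_err


class TestMMDM:
    def test_single_station_individuals_are_excluded(self):
        det = make_detections([("a", "S1", 1, 0, 0), ("a", "S1", 2, 0, 0),
                               ("b", "S2", 1, 5, 0)])
        with pytest.raises(UndefinedMMDMError):
            cmr.compute_mmdm(det)

    def test_two_individual_mean(self):
        det = make_detections([
            ("a", "S1", 1, 0, 0), ("a", "S2", 2, 6, 0),     # max 6 km
            ("b", "S1", 1, 0, 0), ("b", "S3", 2, 8, 0),     # max 8 km
            ("c", "S1", 1, 0, 0)])                          # excluded
        assert cmr.compute_mmdm(det) == pytest.approx(7.0)

    def test_all_pairs_oracle(self, rng):
        stations = [(f"S{i}", rng.uniform(0, 10), rng.uniform(0, 10))
                    for i in range(8)]
        rows, truth_maxima = [], []
        for i in range(5):
            k = int(rng.integers(2, 5))
            chosen = rng.choice(8, size=k, replace=False)
            pts = [stations[c] for c in chosen]
            rows += [(f"ind{i}", s, 1, x, y) for s, x, y in pts]
            dmax = max(np.hypot(a[1] - b[1], a[2] - b[2])
                       for a, b in itertools.combinations(pts, 2))
            truth_maxima.append(dmax)
        det = make_detections(rows)
        assert cmr.compute_mmdm(det) == pytest.approx(np.mean(truth_maxima))


class TestEffectiveArea:
    def square(self, side=10.0):
        return pd.DataFrame({
            "station": ["A", "B", "C", "D"],
            "x_km": [0.0, side, side, 0.0],
            "y_km": [0.0, 0.0, side, side]})

    def test_zero_buffer_is_polygon_area(self):
        assert cmr.effective_area(self.square(), 0.0) == pytest.approx(100.0)

    @pytest.mark.parametrize("b", [0.5, 1.7, 3.3, 6.0])
    def test_square_dilation_closed_form(self, b):
        expected = 100.0 + 40.0 * b + np.pi * b * b
        assert cmr.effective_area(self.square(), b) == pytest.approx(
            expected, abs=1e-6)

    def test_matches_rasterized_area(self, rng):
        pts = pd.DataFrame({
            "station": [f"S{i}" for i in range(12)],
            "x_km": rng.uniform(0, 10, 12), "y_km": rng.uniform(0, 10, 12)})
        b = 3.3
        area = cmr.effective_area(pts, b)
        hull = cmr.station_hull(pts)
        h = 0.02
        xs = np.arange(-b - 1, 11 + b + 1, h)
        ys = np.arange(-b - 1, 11 + b + 1, h)
        gx, gy = np.meshgrid(xs, ys)
        d = shapely.distance(hull, shapely.points(
            np.column_stack([gx.ravel(), gy.ravel()])))
        raster_area = float((d <= b).sum()) * h * h
        assert abs(area - raster_area) / raster_area < 0.005

    def test_collinear_stations_rejected(self):
        pts = pd.DataFrame({"station": list("ABC"),
                            "x_km": [0.0, 1.0, 2.0], "y_km": [0.0, 1.0, 2.0]})
        with pytest.raises(DegenerateGeometryError):
            cmr.effective_area(pts, 1.0)


class TestDensity:
    def fixed(self, n_hat, se=0.0):
        return cmr.PopulationEstimate("M0", n_hat, se, int(n_hat), 10,
                                      np.zeros(10))

    @pytest.mark.parametrize("n_hat,area,expected", [
        (8, 246.0, 3.3), (10, 229.0, 4.4), (8, 275.0, 2.9),
        (10, 405.0, 2.5), (8, 530.0, 1.5), (8, 562.0, 1.4)])
    def test_reported_density_rounding(self, n_hat, area, expected):
        d = cmr.density(self.fixed(n_hat), area)
        assert d.density_1dp == pytest.approx(expected)

    def test_zero_population_zero_density(self):
        assert cmr.density(self.fixed(0), 100.0).density == 0.0

    def test_interval_from_se(self):
        d = cmr.density(self.fixed(10, se=3.0), 200.0)
        assert d.interval == (pytest.approx(3.5), pytest.approx(6.5))

    def test_density_decreases_with_buffer(self):
        sq = TestEffectiveArea().square()
        est = self.fixed(10)
        dens = [cmr.density(est, cmr.effective_area(sq, b)).density
                for b in (0.0, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(dens) < 0)

    def test_half_away_from_zero_rounding(self):
        assert cmr.round_half_away(5.15, 1) == 5.2
        assert cmr.round_half_away(2.25, 1) == 2.3
        assert cmr.round_half_away(-5.15, 1) == -5.2


class TestAccumulationCurve:
    def test_all_first_night_is_flat(self):
        det = make_detections([("a", "S1", 1, 0, 0), ("b", "S1", 1, 0, 0),
                               ("a", "S1", 4, 0, 0)])
        curve = cmr.accumulation_curve(det)
        assert list(curve["individuals"]) == [2, 2, 2, 2]
        assert curve.attrs["stabilized_night"] == 1

    def test_manual_first_sightings(self):
        rows = [("a", "S1", 1, 0, 0), ("b", "S1", 1, 0, 0),
                ("c", "S1", 5, 0, 0), ("d", "S1", 12, 0, 0)]
        curve = cmr.accumulation_curve(make_detections(rows))
        by_night = curve.set_index("night")["individuals"]
        assert [by_night[n] for n in (1, 5, 12)] == [2, 3, 4]
        assert curve.attrs["stabilized_night"] == 12

    def test_monotone_non_decreasing(self, rng):
        rows = [(f"i{rng.integers(6)}", "S1", int(rng.integers(1, 40)), 0, 0)
                for _ in range(50)]
        curve = cmr.accumulation_curve(make_detections(rows))
        assert np.all(np.diff(curve["individuals"]) >= 0)

    def test_empty_input(self):
        curve = cmr.accumulation_curve(make_detections([]))
        assert len(curve) == 0 and curve.attrs["stabilized_night"] is None


class TestEndToEndCalibration:
    def test_mmdm_density_calibrated_and_half_mmdm_overestimates(self):
        """Simulated 16-station surveys estimated with Mh: the full-MMDM
        buffer gives a median density within 25% of the true density over
        the activity-centre region, while the ½MMDM buffer overestimates
        (the known bias of the narrower buffer)."""
        stations = L.station_grid(4, 2.5)
        truth = L.TruthModel(weights={}, suitability=np.zeros((4, 4)),
                             species=L.DEFAULT_SPECIES, n_population=60,
                             sigma_km=2.0, g0=0.3, het_sd=0.75)
        region = shapely.convex_hull(shapely.multipoints(
            np.column_stack([stations["x_km"], stations["y_km"]]))).buffer(4.0)
        true_density = 100.0 * 60 / region.area
        dens_full, dens_half = [], []
        for r in range(200):
            det = L.simulate_cmr(truth, stations, occasions=10, seed=r)
            hist = cmr.build_encounter_history(det, 1, stations)
            est = cmr.estimate_mh_jackknife(hist)
            half, full = cmr.density_from_detections(
                det, est, stations, buffers=("half-mmdm", "mmdm"))
            dens_half.append(half.density)
            dens_full.append(full.density)
        med_full = float(np.median(dens_full))
        assert abs(med_full - true_density) / true_density < 0.25
        assert float(np.median(dens_half)) > true_density
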