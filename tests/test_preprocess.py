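"""Anomaly construction, area averaging, EOF truncation, seasonal pooling."""

import numpy as np
import pytest

import gefa
from gefa import GEFAError
from gefa.preprocess import GriddedField, RegionBox


class TestSeasonalCycle:
    def test_pure_sinusoid_removed_exactly(self):
        t = np.arange(120)
        x = np.sin(2 * np.pi * (t % 12) / 12.0 + 0.3)
        assert np.allclose(gefa.remove_seasonal_cycle(x), 0.0, atol=1e-12)

    def test_constant_series_removed(self):
        assert np.allclose(gefa.remove_seasonal_cycle(np.full(48, 3.7)), 0.0)

    def test_noise_plus_cycle_leaves_noise(self, rng):
        # oracle: per-month demeaning done independently with pandas
        import pandas as pd

        t = np.arange(1200)
        noise = rng.standard_normal(1200)
        x = 5 * np.sin(2 * np.pi * (t % 12) / 12.0) + noise
        out = gefa.remove_seasonal_cycle(x)
        months = t % 12
        for m in range(12):
            assert abs(out[months == m].mean()) < 1e-12
        expected = pd.Series(x).groupby(months).transform(lambda s: s - s.mean()).to_numpy()
        assert np.allclose(out, expected, atol=1e-10)
        assert abs(out.var() / noise.var() - 1) < 0.05

    def test_short_record_rejected(self):
        with pytest.raises(GEFAError, match="24"):
            gefa.remove_seasonal_cycle(np.zeros(20))


class TestDetrend:
    def test_exact_line_removed(self):
        t = np.arange(100.0)
        assert np.allclose(gefa.detrend_linear(2.0 + 0.5 * t), 0.0, atol=1e-9)

    def test_residual_uncorrelated_with_time(self, rng):
        x = rng.standard_normal(500)
        out = gefa.detrend_linear(x)
        t = np.arange(500.0)
        assert abs(np.corrcoef(out, t)[0, 1]) < 1e-10

    def test_white_noise_variance_deflation_is_small(self, rng):
        # residual-variance identity: regression on {1, t} removes ~2/L of variance
        n = 1000
        x = rng.standard_normal(n)
        out = gefa.detrend_linear(x)
        assert out.var() <= x.var()
        assert (x.var() - out.var()) / x.var() < 10 / n

    def test_cycle_then_trend_removes_both_exactly(self):
        t = np.arange(240)
        x = 1.5 + 0.02 * t + 3 * np.sin(2 * np.pi * (t % 12) / 12.0)
        assert np.allclose(gefa.to_anomalies(x), 0.0, atol=1e-9)

    def test_all_missing_series_rejected(self):
        with pytest.raises(GEFAError, match="finite"):
            gefa.detrend_linear(np.full(10, np.nan))


def _field(values, lat, lon, **kw):
    return GriddedField(values=values, lat=np.asarray(lat, float),
                        lon=np.asarray(lon, float), **kw)


class TestAreaAverage:
    def test_constant_field_gives_constant_series(self):
        f = _field(np.full((5, 3, 4), 2.5), [0, 10, 20], [0, 5, 10, 15])
        box = RegionBox("all", -1, 21, -1, 16)
        assert np.allclose(gefa.area_average(f, box), 2.5)

    def test_two_equator_cells_average_evenly(self):
        vals = np.zeros((1, 1, 2))
        vals[0, 0] = [1.0, 3.0]
        f = _field(vals, [0.0], [0.0, 1.0])
        assert np.allclose(gefa.area_average(f, RegionBox("b", -1, 1, -1, 2)), 2.0)

    def test_matches_explicit_weighted_loop(self, rng):
        vals = rng.standard_normal((4, 6, 7))
        lat = np.linspace(-30, 30, 6)
        lon = np.linspace(0, 60, 7)
        f = _field(vals, lat, lon)
        box = RegionBox("b", -20, 25, 5, 55)
        out = gefa.area_average(f, box)
        # oracle: brute-force loop over cells
        w = np.cos(np.deg2rad(lat))
        for t in range(4):
            num = den = 0.0
            for i in range(6):
                for j in range(7):
                    if box.lat_min <= lat[i] <= box.lat_max and box.lon_min <= lon[j] <= box.lon_max:
                        num += w[i] * vals[t, i, j]
                        den += w[i]
            assert abs(out[t] - num / den) < 1e-12

    def test_invariant_under_lat_reordering(self, rng):
        vals = rng.standard_normal((3, 5, 4))
        lat = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        lon = np.array([0.0, 2.0, 4.0, 6.0])
        box = RegionBox("b", -1, 21, -1, 7)
        a = gefa.area_average(_field(vals, lat, lon), box)
        b = gefa.area_average(_field(vals[:, ::-1], lat[::-1], lon), box)
        assert np.allclose(a, b, atol=1e-12)

    def test_fully_masked_step_propagates_missing(self):
        vals = np.ones((2, 2, 2))
        mask = np.zeros((2, 2, 2), bool)
        mask[1] = True
        f = _field(vals, [0, 1], [0, 1], mask=mask)
        out = gefa.area_average(f, RegionBox("b", -1, 2, -1, 2))
        assert out[0] == 1.0 and np.isnan(out[1])

    def test_empty_overlap_rejected(self):
        f = _field(np.ones((1, 2, 2)), [0, 1], [0, 1])
        with pytest.raises(GEFAError, match="overlap"):
            gefa.area_average(f, RegionBox("far", 50, 60, 50, 60))


class TestEOF:
    def test_rank_one_field_explains_everything(self, rng):
        u = rng.standard_normal(50)
        v = rng.standard_normal(12)
        vals = np.outer(u, v).reshape(50, 3, 4)
        f = _field(vals, [0, 5, 10], [0, 2, 4, 6])
        basis = gefa.compute_eof(f, RegionBox("b", -1, 11, -1, 7), 1)
        assert abs(basis.explained_fraction[0] - 1.0) < 1e-10

    def test_white_noise_fractions_match_sample_eigenvalues(self, rng):
        vals = rng.standard_normal((5000, 2, 2))
        f = _field(vals, [0.0, 0.5], [0.0, 0.5])
        basis = gefa.compute_eof(f, RegionBox("b", -1, 1, -1, 1), 4)
        assert np.all(np.abs(basis.explained_fraction - 0.25) < 0.03)
        # oracle: eigenvalues of the weighted sample covariance
        w = np.sqrt(np.cos(np.deg2rad([0.0, 0.0, 0.5, 0.5])))
        X = vals.reshape(5000, 4) * w
        X = X - X.mean(axis=0)
        lam = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
        assert np.allclose(basis.explained_fraction, lam / lam.sum(), atol=1e-8)

    def test_full_reconstruction_and_weighted_orthogonality(self, rng):
        vals = rng.standard_normal((30, 3, 3))
        lat = [0.0, 20.0, 40.0]
        f = _field(vals, lat, [0, 1, 2])
        basis = gefa.compute_eof(f, RegionBox("b", -1, 41, -1, 3), 9)
        recon = basis.pcs @ basis.modes
        X = vals.reshape(30, 9)
        Xc = X - X.mean(axis=0)
        assert np.allclose(recon, Xc, atol=1e-8 * np.abs(Xc).max())
        G = (basis.modes * basis.cell_weights) @ basis.modes.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8
        # pcs are uncorrelated in sample and ordered by explained fraction
        r = np.corrcoef(basis.pcs.T)
        assert np.max(np.abs(r - np.eye(9))) < 1e-8
        assert np.all(np.diff(basis.explained_fraction) <= 1e-12)

    def test_sign_convention_max_element_positive(self, rng):
        vals = rng.standard_normal((40, 2, 2))
        f = _field(vals, [0.0, 1.0], [0.0, 1.0])
        basis = gefa.compute_eof(f, RegionBox("b", -1, 2, -1, 2), 2)
        for mode in basis.modes:
            assert mode[np.argmax(np.abs(mode))] > 0


class TestPoolSeason:
    def test_thirty_year_son_pool_has_90_months(self):
        pool = gefa.pool_season(360, "SON", tau=1)
        assert pool.n_pairs == 90 and pool.n_dropped == 0
        months = pool.targets % 12
        assert set(months) == {8, 9, 10}
        # lag partners are Aug/Sep/Oct of the same year
        assert set(pool.partners % 12) == {7, 8, 9}
        assert np.all(pool.targets // 12 == pool.partners // 12)

    def test_tau_zero_partners_equal_targets(self):
        pool = gefa.pool_season(120, "JAS", tau=0)
        assert np.array_equal(pool.targets, pool.partners)

    def test_two_year_toy_matches_hand_enumeration(self):
        # record: Jan yr0 .. Dec yr1; season JFM, tau=1 -> Jan yr0 pair dropped
        pool = gefa.pool_season(24, "JFM", tau=1)
        assert pool.targets.tolist() == [1, 2, 12, 13, 14]
        assert pool.partners.tolist() == [0, 1, 11, 12, 13]
        assert pool.n_dropped == 1

    @pytest.mark.parametrize("bad", ["XY", (0, 2, 4), (0, 1)])
    def test_invalid_season_rejected(self, bad):
        with pytest.raises(GEFAError):
            gefa.pool_season(120, bad, tau=1)
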