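"""Tests of FC/FCD observables, the fitting cost, and multi-stability statistics."""

import numpy as np
import pytest

from pmfm import (
    BoldTimeseries,
    FCDMatrix,
    FCMatrix,
    FcdPdf,
    average_fcd_pdf,
    classify_states,
    cost,
    fc_agreement,
    fcd_mean_timecourse,
    fcd_std_correlation_map,
    ks_distance,
    permutation_null_fcd_std,
    sliding_window_fcd,
    sliding_window_std,
    static_fc,
)
from pmfm.exceptions import DegenerateSignalError, InvalidInputError


def bold_from(array, tr=0.72):
    return BoldTimeseries(B=np.asarray(array, dtype=float), tr=tr)


def brute_force_ks(a, b):
    """Exhaustive two-sample ECDF sup-distance."""
    a, b = np.sort(a), np.sort(b)
    grid = np.concatenate([a, b])
    d = 0.0
    for g in grid:
        fa = np.sum(a <= g) / a.size
        fb = np.sum(b <= g) / b.size
        d = max(d, abs(fa - fb))
    return d


class TestStaticFC:
    def test_identical_series_correlate_to_one(self, rng):
        x = rng.standard_normal(50)
        fc = static_fc(bold_from([x, x.copy(), rng.standard_normal(50)]))
        assert fc.values[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_series(self, rng):
        x = rng.standard_normal(50)
        fc = static_fc(bold_from([x, -x]))
        assert fc.values[0, 1] == pytest.approx(-1.0)

    def test_matches_independent_pearson(self):
        B = np.array([
            [1.0, 2.0, 4.0, 3.0, 5.0],
            [2.0, 1.0, 3.0, 5.0, 4.0],
            [0.5, 0.4, 0.9, 0.1, 0.2],
        ])
        fc = static_fc(bold_from(B))
        for i in range(3):
            for j in range(3):
                xi, xj = B[i] - B[i].mean(), B[j] - B[j].mean()
                r = np.sum(xi * xj) / np.sqrt(np.sum(xi**2) * np.sum(xj**2))
                assert fc.values[i, j] == pytest.approx(r, abs=1e-12)

    def test_constant_region_raises(self, rng):
        B = np.vstack([rng.standard_normal(20), np.full(20, 3.0)])
        with pytest.raises(DegenerateSignalError, match="region_1"):
            static_fc(bold_from(B))


class TestSlidingWindowFCD:
    @pytest.mark.parametrize("T,window,expected", [(1200, 83, 1118), (100, 43, 58)])
    def test_window_count(self, rng, T, window, expected):
        fcd = sliding_window_fcd(bold_from(rng.standard_normal((5, T))), window=window)
        assert fcd.n_windows == expected
        assert fcd.values.shape == (expected, expected)

    def test_single_window(self, rng):
        fcd = sliding_window_fcd(bold_from(rng.standard_normal((4, 30))), window=30)
        assert np.array_equal(fcd.values, [[1.0]])

    def test_symmetric_unit_diagonal_bounded(self, rng):
        fcd = sliding_window_fcd(bold_from(rng.standard_normal((6, 60))), window=20)
        v = fcd.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert v.min() >= -1 and v.max() <= 1

    def test_too_small_window_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            sliding_window_fcd(bold_from(rng.standard_normal((4, 30))), window=2)


class TestFcAgreement:
    def _fc(self, upper, n=3):
        v = np.eye(n)
        iu = np.triu_indices(n, 1)
        v[iu] = upper
        v = v + v.T - np.eye(n)
        return FCMatrix(values=v)

    def test_identical_matrices(self):
        fc = self._fc([0.1, 0.4, -0.3])
        assert fc_agreement(fc, fc) == pytest.approx(1.0)

    def test_exact_anticorrelation_under_odd_transform(self):
        a = self._fc([0.0, 0.5, -0.5])
        b = self._fc([0.0, -0.5, 0.5])
        assert fc_agreement(a, b) == pytest.approx(-1.0)

    def test_matches_z_then_correlate_oracle(self, rng):
        ua = rng.uniform(-0.8, 0.8, 6)
        ub = rng.uniform(-0.8, 0.8, 6)
        a, b = self._fc(ua, n=4), self._fc(ub, n=4)
        za, zb = np.arctanh(ua), np.arctanh(ub)
        za_c, zb_c = za - za.mean(), zb - zb.mean()
        r = np.sum(za_c * zb_c) / np.sqrt(np.sum(za_c**2) * np.sum(zb_c**2))
        assert fc_agreement(a, b) == pytest.approx(r, abs=1e-12)

    def test_unit_entry_rejected(self):
        a = self._fc([1.0, 0.5, -0.5])
        with pytest.raises(InvalidInputError):
            fc_agreement(a, a)


class TestKsDistance:
    def test_identical_samples(self):
        x = [0.1, 0.5, 0.9]
        assert ks_distance(x, x) == 0.0

    def test_disjoint_supports(self):
        assert ks_distance([0.0, 0.0], [1.0, 1.0]) == 1.0

    def test_hand_enumerated(self):
        assert ks_distance([0.0, 1.0], [0.5, 0.5]) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_pairs(self):
        """Exact agreement with an exhaustive ECDF oracle on 100 seeded pairs."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            na, nb = rng.integers(1, 21, size=2)
            a = np.round(rng.uniform(-1, 1, na), 2)  # rounding forces ties
            b = np.round(rng.uniform(-1, 1, nb), 2)
            assert ks_distance(a, b) == pytest.approx(brute_force_ks(a, b), abs=1e-15)

    def test_binned_pdfs(self):
        edges = np.linspace(-1, 1, 201)
        m1 = np.zeros(200); m1[50] = 1.0
        m2 = np.zeros(200); m2[150] = 1.0
        assert ks_distance(FcdPdf(edges, m1), FcdPdf(edges, m2)) == pytest.approx(1.0)

    def test_mixed_sample_and_pdf(self, rng):
        x = rng.uniform(-1, 1, 500)
        edges = np.linspace(-1, 1, 201)
        counts, _ = np.histogram(x, bins=edges)
        p = FcdPdf(edges, counts / counts.sum())
        assert ks_distance(x, p) < 0.02  # binning resolution only


class TestAveragePdfAndCost:
    def _pdf(self, hot_bin):
        edges = np.linspace(-1, 1, 201)
        m = np.zeros(200)
        m[hot_bin] = 1.0
        return FcdPdf(edges, m)

    def test_single_pdf_identity(self):
        p = self._pdf(10)
        q = average_fcd_pdf([p])
        assert np.array_equal(p.masses, q.masses)

    def test_two_identical(self):
        p = self._pdf(10)
        q = average_fcd_pdf([p, p])
        assert np.allclose(q.masses, p.masses)

    def test_distinct_bins_average_half(self):
        q = average_fcd_pdf([self._pdf(10), self._pdf(20)])
        assert q.masses[10] == pytest.approx(0.5)
        assert q.masses[20] == pytest.approx(0.5)
        assert q.masses.sum() == pytest.approx(1.0)

    def test_mismatched_grids_rejected(self):
        p = self._pdf(10)
        q = FcdPdf(np.linspace(-1, 1, 101), np.full(100, 0.01))
        with pytest.raises(InvalidInputError):
            average_fcd_pdf([p, q])

    def test_cost_arithmetic(self):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 0.5
        v[0, 2] = v[2, 0] = -0.2
        v[1, 2] = v[2, 1] = 0.1
        fc = FCMatrix(values=v)
        p = self._pdf(10)
        assert cost(fc, fc, p, p) == pytest.approx(0.0)
        q = self._pdf(20)
        assert cost(fc, fc, p, q) == pytest.approx(1.0)  # r=1, KS=1
        assert cost(fc, fc, p, q, weight_fcd=0.0) == pytest.approx(0.0)
        with pytest.raises(InvalidInputError):
            cost(fc, fc, p, q, weight_fc=-1.0)

    def test_cost_reference_arithmetic(self):
        # (1 - 0.66) + 0.12 = 0.46
        assert (1 - 0.66) + 0.12 == pytest.approx(0.46)


class TestFcdMeanAndSwStd:
    def test_all_ones_fcd(self):
        fcd = FCDMatrix(values=np.ones((4, 4)), window_length=10)
        assert np.allclose(fcd_mean_timecourse(fcd), 1.0)

    def test_hand_computed_row_means(self):
        v = np.array([
            [1.0, 0.2, 0.4],
            [0.2, 1.0, 0.6],
            [0.4, 0.6, 1.0],
        ])
        fcd = FCDMatrix(values=v, window_length=10)
        assert np.allclose(fcd_mean_timecourse(fcd), [0.3, 0.4, 0.5])
        assert np.allclose(
            fcd_mean_timecourse(fcd, include_diagonal=True), v.mean(axis=1)
        )

    def test_sw_std_constant_region_is_zero(self, rng):
        B = np.vstack([np.full(30, 2.0), rng.standard_normal(30)])
        sw = sliding_window_std(bold_from(B), window=10)
        assert np.allclose(sw[0], 0.0)
        assert np.all(sw >= 0)

    def test_sw_std_matches_oracle(self):
        B = np.array([[1.0, 2.0, 3.0, 4.0]])
        sw = sliding_window_std(bold_from(B), window=3)
        expected = [np.std([1, 2, 3]), np.std([2, 3, 4])]  # population convention
        assert np.allclose(sw[0], expected)


class TestClassifyStates:
    def test_recovers_two_gaussian_modes(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([
            rng.normal(0.3, 0.05, 1000),
            rng.normal(0.8, 0.05, 1000),
        ])
        st = classify_states(x, seed=0)
        assert st.component_means[0] == pytest.approx(0.3, abs=0.02)
        assert st.component_means[1] == pytest.approx(0.8, abs=0.02)
        assert st.threshold == pytest.approx(0.55, abs=0.03)
        truth = np.concatenate([np.zeros(1000, bool), np.ones(1000, bool)])
        assert np.mean(st.labels != truth) < 0.02

    def test_all_coherent_above_threshold(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0.3, 0.03, 500), rng.normal(0.8, 0.03, 500)])
        st = classify_states(x, seed=0)
        assert np.all(st.labels[x > st.threshold])

    def test_dwell_time_enumeration(self):
        from pmfm.observables import _run_lengths
        labels = np.array([False, False, True, True, True, False])
        d = _run_lengths(labels)
        assert d["incoherent"] == [2, 1]
        assert d["coherent"] == [3]

    def test_too_few_windows_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_states(np.linspace(0, 1, 10))


class TestFcdStdCorrelation:
    def test_identical_series_correlate_to_one(self, rng):
        fm = rng.standard_normal(100).cumsum()
        sw = np.vstack([fm, -fm])
        r = fcd_std_correlation_map(fm, sw)
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(11)
        fm = rng.standard_normal(1001)
        sw = rng.standard_normal((3, 1001))
        r = fcd_std_correlation_map(fm, sw)
        assert np.all(np.abs(r) < 0.1)

    def test_constant_region_flagged_nan(self, rng):
        fm = rng.standard_normal(50)
        sw = np.vstack([np.full(50, 1.0), rng.standard_normal(50)])
        r = fcd_std_correlation_map(fm, sw)
        assert np.isnan(r[0]) and np.isfinite(r[1])


class TestPermutationNull:
    def _coupled_runs(self, n_runs=6, n_regions=8, W=300, seed=0):
        """Half the regions' SW-STD tracks the run's FCD mean, half is noise."""
        rng = np.random.default_rng(seed)
        runs = []
        for _ in range(n_runs):
            fm = np.cumsum(rng.standard_normal(W)) * 0.05
            sw = rng.standard_normal((n_regions, W)) * 0.3
            sw[: n_regions // 2] += fm[None, :]
            runs.append((fm, sw))
        return runs

    def test_identity_pairing_reproduces_observed(self):
        runs = self._coupled_runs()
        out = permutation_null_fcd_std(runs, n_perm=5, seed=0)
        from pmfm.observables import fcd_std_correlation_map as f
        manual = np.nanmean([f(fm, sw) for fm, sw in runs], axis=0)
        assert np.allclose(out["observed"], manual, equal_nan=True)

    def test_null_shape(self):
        runs = self._coupled_runs()
        out = permutation_null_fcd_std(runs, n_perm=50, seed=1)
        assert out["null"].shape == (50, 8)

    def test_coupled_regions_significant(self):
        runs = self._coupled_runs(n_runs=8, seed=5)
        out = permutation_null_fcd_std(runs, n_perm=1000, seed=2)
        assert np.all(out["significant"][:4])
        assert not np.any(out["significant"][4:])

    def test_requires_two_runs(self):
        runs = self._coupled_runs(n_runs=1)
        with pytest.raises(InvalidInputError):
            permutation_null_fcd_std(runs, n_perm=10)


class TestWindowLengthRobustness:
    def test_stationary_bold_pdfs_stable_across_windows(self):
        """FCD pdfs are stable under the window length on stationary
        structured BOLD: adjacent window choices (43 vs 83, 83 vs 125)
        stay within KS 0.2; the extreme pair drifts further because the
        FC-estimator noise scales with 1/window."""
        rng = np.random.default_rng(5)
        T, n = 1200, 10
        f = np.zeros((3, T))
        for t in range(1, T):
            f[:, t] = 0.95 * f[:, t - 1] + rng.standard_normal(3)
        B = rng.standard_normal((n, 3)) @ f + 0.5 * rng.standard_normal((n, T))
        bold = bold_from(B)
        pdfs = {w: sliding_window_fcd(bold, window=w).pdf() for w in (43, 83, 125)}
        assert ks_distance(pdfs[43], pdfs[83]) < 0.2
        assert ks_distance(pdfs[83], pdfs[125]) < 0.2
        assert ks_distance(pdfs[43], pdfs[125]) < 0.35
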