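"""Pearson matrices, circular-shift nulls, empirical p, KS, BH fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bimodal.containers import BandDef, BandPowerSet, TraceSet
from bimodal.correlate import (
    _null_rho_fft,
    _standardize,
    circular_shuffle,
    correlate_session,
    empirical_p,
    fdr_fractions,
    ks_original_vs_shuffled,
    pearson_matrix,
    top_correlated_rois,
)


def _bp_from_rows(rows, frame_times, n_bands=1):
    """Wrap (n_series, n_frames) rows as a one-band-per-row BandPowerSet."""
    rows = np.atleast_2d(rows)
    bands = tuple(
        BandDef(f"b{i}", 1 + 2 * i, 2 + 2 * i) for i in range(n_bands)
    )
    n_el = rows.shape[0] // n_bands
    power = rows.reshape(n_el, n_bands, -1)
    return BandPowerSet(
        power=power - power.min() + 0.0,
        frame_times_s=frame_times,
        band_defs=bands,
    )


class TestPearsonMatrix:
    frame_times = np.arange(100) / 15.0

    def test_identical_series_rho_one(self):
        rng = np.random.default_rng(0)
        y = rng.random(100) + 1.0
        traces = TraceSet(dff=y[None, :], frame_times_s=self.frame_times)
        rho = pearson_matrix(traces, _bp_from_rows(y, self.frame_times))
        assert rho[0, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_negated_series_rho_minus_one(self):
        rng = np.random.default_rng(1)
        y = rng.random(100) + 1.0
        traces = TraceSet(dff=-y[None, :], frame_times_s=self.frame_times)
        rho = pearson_matrix(traces, _bp_from_rows(y, self.frame_times))
        assert rho[0, 0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_three_point_hand_computation(self):
        # x=(1,2,3), y=(1,2,4): rho = 3/sqrt(2*4.6667) = 0.981980506...
        t = np.arange(3.0)
        traces = TraceSet(dff=np.array([[1.0, 2.0, 3.0]]), frame_times_s=t)
        bp = _bp_from_rows(np.array([1.0, 2.0, 4.0]), t)
        rho = pearson_matrix(traces, bp)
        assert rho[0, 0, 0] == pytest.approx(0.9819805060619659, abs=1e-12)

    def test_constant_trace_flagged_nan(self):
        rng = np.random.default_rng(2)
        y = rng.random(100)
        dff = np.vstack([np.full(100, 3.0), y])
        traces = TraceSet(dff=dff, frame_times_s=self.frame_times)
        rho = pearson_matrix(traces, _bp_from_rows(y, self.frame_times))
        assert np.isnan(rho[0, 0, 0])
        assert rho[1, 0, 0] == pytest.approx(1.0)

    def test_mismatched_frame_axes_rejected(self):
        y = np.arange(100.0)
        traces = TraceSet(dff=y[None, :], frame_times_s=self.frame_times)
        bp = _bp_from_rows(y, self.frame_times + 0.5)
        with pytest.raises(ValueError, match="frame axes"):
            pearson_matrix(traces, bp)


class TestCircularShuffle:
    def test_multiset_preserved(self):
        rng = np.random.default_rng(3)
        x = rng.random(57)
        for sh in circular_shuffle(x, n_shuffles=20, seed=0):
            assert np.array_equal(np.sort(sh), np.sort(x))

    def test_shift_bounds_L100(self):
        x = np.arange(100.0)
        shuffled = circular_shuffle(x, n_shuffles=300, seed=1)
        # recover the shift from where element 0 landed
        shifts = np.array([int(np.argwhere(s == 0.0)[0][0]) for s in shuffled])
        assert shifts.min() >= 10 and shifts.max() <= 90

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            circular_shuffle(np.arange(5.0))

    def test_decorrelates_autocorrelated_trace(self):
        t = np.arange(200.0)
        x = np.sin(2 * np.pi * t / 50) + 0.1 * np.cos(2 * np.pi * t / 7)
        shuffled = circular_shuffle(x, n_shuffles=50, seed=2)
        rhos = [abs(np.corrcoef(x, s)[0, 1]) for s in shuffled]
        assert np.mean(rhos) < 1.0
        assert np.median(rhos) < 0.9

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        L=st.integers(min_value=10, max_value=400),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_shift_contract_property(self, L, seed):
        x = np.arange(float(L))
        shuffled = circular_shuffle(x, n_shuffles=5, seed=seed)
        m = int(np.ceil(L / 10))
        for s in shuffled:
            shift = int(np.argwhere(s == 0.0)[0][0])
            assert m <= shift <= L - m
            assert np.array_equal(np.sort(s), x)


class TestEmpiricalP:
    def test_obs_beyond_all_nulls(self):
        p = empirical_p(np.array(5.0), np.random.default_rng(0).random(100))
        assert p == pytest.approx(1 / 101)

    def test_zero_obs_symmetric_nulls(self):
        nulls = np.concatenate([np.linspace(-1, 1, 200)])
        assert empirical_p(np.array(0.0), nulls) > 0.99

    def test_obs_at_median_null(self):
        nulls = np.linspace(0.01, 1.0, 99)
        p = empirical_p(np.array(np.median(nulls)), nulls)
        assert p == pytest.approx(0.5, abs=0.02)

    def test_shuffle_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        nulls = rng.standard_normal(100)
        obs = np.array(0.7)
        p1 = empirical_p(obs, nulls)
        p2 = empirical_p(obs, rng.permutation(nulls))
        assert p1 == p2


class TestKS:
    def test_identical_samples_zero_stat(self):
        x = np.linspace(-1, 1, 50)
        d, _ = ks_original_vs_shuffled(x, x)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_shifted_sample_highly_significant(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(1000)
        d, p = ks_original_vs_shuffled(a, a + 0.5)
        assert p < 0.001

    def test_matches_brute_force_cdf_gap(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.standard_normal(rng.integers(3, 11))
            b = rng.standard_normal(rng.integers(3, 11))
            d, _ = ks_original_vs_shuffled(a, b)
            # oracle: exhaustive max CDF gap over all pooled values
            gaps = [
                abs((a <= v).mean() - (b <= v).mean())
                for v in np.concatenate([a, b])
            ]
            assert d == pytest.approx(max(gaps), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_original_vs_shuffled(np.array([]), np.array([1.0]))


class TestFdrFractions:
    def test_all_p_one_nothing_significant(self):
        sig, frac = fdr_fractions(np.ones(50))
        assert not sig.any() and frac == 0.0

    def test_all_small_p_everything_significant(self):
        sig, frac = fdr_fractions(np.full(40, 0.001), fdr_q=0.05)
        assert sig.all() and frac == 1.0

    def test_bh_stepup_hand_example(self):
        # sorted p (0.01, 0.02, 0.04, 0.30) vs kq/m (0.0125, 0.025, 0.0375,
        # 0.05): p_(3)=0.04 > 0.0375, p_(2)=0.02 <= 0.025, so the step-up
        # stops at k=2 -> exactly the two smallest p are rejected
        p = np.array([0.01, 0.02, 0.30, 0.04])
        sig, frac = fdr_fractions(p, fdr_q=0.05)
        assert sig.tolist() == [True, True, False, False]
        assert frac == pytest.approx(0.5)

    def test_per_band_independence(self):
        p = np.full((10, 2, 2), 1.0)
        p[:, :, 0] = 0.001
        sig, frac = fdr_fractions(p, fdr_q=0.05)
        assert frac[0] == 1.0 and frac[1] == 0.0


class TestNullRhoFFT:
    def test_matches_direct_rolled_pearson(self):
        rng = np.random.default_rng(7)
        x = _standardize(rng.standard_normal((4, 113)))
        y = _standardize(rng.standard_normal((3, 113)))
        shifts = rng.integers(12, 100, size=(4, 6))
        out = _null_rho_fft(x, y, shifts)
        for i in range(4):
            for j in range(3):
                for k in range(6):
                    direct = np.corrcoef(
                        np.roll(x[i], shifts[i, k]), y[j]
                    )[0, 1]
                    assert out[i, j, k] == pytest.approx(direct, abs=1e-10)


@pytest.fixture(scope="module")
def coupled_result(coupled_session_small):
    from bimodal.lfp import band_power_traces

    _, (traces, rec, *_ ) = coupled_session_small
    bp = band_power_traces(rec, traces.frame_times_s)
    return correlate_session(traces, bp, seed=9), traces


class TestCorrelateSession:

    def test_coupled_roi_tops_theta_ranking(self, coupled_result):
        res, _ = coupled_result
        top = top_correlated_rois(res, "theta", k=4)
        assert top[0][0] in {0, 1, 2, 3}  # a coupled ROI ranks first
        assert top[0][1] > 0.1

    def test_skew_structure_original_vs_shuffled(self, coupled_result):
        res, _ = coupled_result
        b = res.band_index("theta")
        orig = res.rho[:, :, b]
        assert orig.mean() > 0
        assert abs(np.nanmean(res.null_rho[:, :, b, :])) < 0.05
        assert res.ks_p[b] < 0.001

    def test_determinism_same_seed(self, coupled_session_small):
        from bimodal.lfp import band_power_traces

        _, (traces, rec, *_ ) = coupled_session_small
        bp = band_power_traces(rec, traces.frame_times_s)
        a = correlate_session(traces, bp, n_shuffles=20, seed=5)
        b = correlate_session(traces, bp, n_shuffles=20, seed=5)
        np.testing.assert_array_equal(a.p_emp, b.p_emp)
        np.testing.assert_array_equal(a.null_rho, b.null_rho)

    def test_top_k_edge_cases(self, coupled_result):
        res, traces = coupled_result
        assert top_correlated_rois(res, "theta", k=0) == []
        with pytest.warns(UserWarning, match="only"):
            full = top_correlated_rois(res, "theta", k=999)
        assert len(full) == traces.n_rois
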