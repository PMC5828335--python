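"""Vibration metrics: elementary operations against brute-force oracles,
and recovery of injected phantom vibrations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import corvib as cv
from corvib.vibrations import (
    cutoff_points,
    cumulative_angle,
    max_deformation_position,
    measurement_error,
    peak_positions,
    peak_quarter_correlation,
    quarter_points,
    vibration_angle,
)


def brute_peak_positions(l_d):
    """Exhaustive-scan oracle for the half-wise minima."""
    N = len(l_d)
    half = (N + 1) // 2
    best_l, arg_l = np.inf, None
    for n in range(half):
        if l_d[n] < best_l:
            best_l, arg_l = l_d[n], n
    best_r, arg_r = np.inf, None
    for n in range(half, N):
        if l_d[n] < best_r:
            best_r, arg_r = l_d[n], n
    return best_l, arg_l, best_r, arg_r


class TestPeakPositions:
    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(1000):
            v = rng.normal(size=rng.integers(4, 40))
            assert peak_positions(v) == pytest.approx(brute_peak_positions(v))

    def test_direct_lookup(self):
        v = np.zeros(576)
        v[100] = -5.0
        v[400] = -2.0
        m_kl, n_kl, m_kr, n_kr = peak_positions(v)
        assert (m_kl, n_kl) == (-5.0, 100)
        assert (m_kr, n_kr) == (-2.0, 400)

    def test_leftmost_tie_break(self):
        v = np.zeros(200)
        v[50] = v[80] = -3.0
        _, n_kl, _, _ = peak_positions(v)
        assert n_kl == 50

    def test_flat_half_returns_center(self):
        v = np.zeros(100)
        v[70] = -1.0
        m_kl, n_kl, _, _ = peak_positions(v)
        assert n_kl == 25  # center of the flat left half
        assert m_kl == 0.0


class TestQuarterPoints:
    @pytest.mark.parametrize(
        "n_kl,n_kr,n_d,expected",
        [
            (100, 500, 300, (200, 400)),
            (101, 500, 300, (200, 400)),  # floor of 200.5
            (100, 501, 300, (200, 400)),
        ],
    )
    def test_floor_midpoints(self, n_kl, n_kr, n_d, expected):
        assert quarter_points(n_kl, n_kr, n_d) == expected

    def test_ordering_violation(self):
        with pytest.raises(ValueError, match="ordering violated"):
            quarter_points(300, 500, 200)

    @settings(derandomize=True, max_examples=50)
    @given(
        n_kl=st.integers(0, 200),
        gap1=st.integers(1, 100),
        gap2=st.integers(1, 100),
        shift=st.integers(0, 5),
    )
    def test_midpoint_invariant_under_common_shift(self, n_kl, gap1, gap2, shift):
        """0-based vs 1-based indexing yields consistent quarter columns."""
        n_d = n_kl + gap1
        n_kr = n_d + gap2
        a = quarter_points(n_kl, n_kr, n_d)
        b = quarter_points(n_kl + shift, n_kr + shift, n_d + shift)
        assert (b[0] - a[0], b[1] - a[1]) == (shift, shift)


class TestMaxDeformation:
    def test_unique_gaussian_maximum(self):
        n = np.arange(576, dtype=float)
        l_d = 30.0 * np.exp(-((n - 288.0) ** 2) / (2 * 40.0**2))
        l_d[150] = -8.0
        l_d[430] = -8.0
        assert max_deformation_position(l_d, l_d, 150, 430) == 288

    def test_restricted_equals_unrestricted_when_interior(self, rng):
        """If the global max already lies inside the quarter window the
        bootstrap and a plain argmax agree."""
        n = np.arange(576, dtype=float)
        for _ in range(50):
            c = rng.uniform(250, 330)
            l_d = rng.uniform(10, 40) * np.exp(-((n - c) ** 2) / (2 * 50.0**2))
            l_d[100] = -5.0
            l_d[470] = -5.0
            got = max_deformation_position(l_d, l_d, 100, 470)
            assert got == int(np.argmax(l_d))

    def test_drift_tracking(self, drift_result):
        """n_d follows the drifting dent center within 2 columns."""
        spec, truth, res = drift_result
        interior = np.array(list(res.ap.interior()))
        nd = res.traces.n_d[interior]
        ok = np.isfinite(nd)
        assert ok.mean() > 0.9
        err = np.abs(nd[ok] - truth.n_d_trace[interior][ok])
        assert err.max() <= 2.0


class TestCutoff:
    def test_confined_deformation(self, drift_result):
        spec, truth, res = drift_result
        peak = int(np.argmax(truth.depth_px))
        s0, s1 = truth.support
        assert abs(res.traces.n_bl[peak] - s0) <= 2
        assert abs(res.traces.n_br[peak] - s1) <= 2

    def test_zero_frame_flagged(self):
        with pytest.raises(ValueError):
            cutoff_points(np.zeros(576), 2.0)

    def test_monotone_widening(self):
        """While the dent only deepens, the cutoff width never shrinks."""
        spec = cv.default_spec(drift_mm=0.0, eye_reaction_px=0.0)
        truth = cv.synthesize_contour(spec)
        res = cv.analyze_contours(
            cv.contour_series_from_matrix(truth.contour), spec.calibration
        )
        peak = int(np.argmax(truth.depth_px))
        widths = res.traces.cutoff_vib[res.ap.idx1 + 1 : peak + 1]
        widths = widths[np.isfinite(widths)]
        assert (np.diff(widths) >= 0).all()


class TestMeasurementError:
    def test_zero_deformation_gives_one_pixel(self):
        assert measurement_error(np.zeros(576), 2.0) == 1.0

    def test_reciprocal_of_count(self):
        l_d = np.zeros(576)
        l_d[100:110] = 5.0  # exactly 10 columns above threshold
        assert measurement_error(l_d, 2.0) == pytest.approx(0.1)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 570))
    def test_monotone_in_area(self, k):
        """delta never grows when the deformed area grows."""
        l_d = np.zeros(576)
        l_d[:k] = 5.0
        wider = l_d.copy()
        wider[: k + 5] = 5.0
        assert measurement_error(wider) <= measurement_error(l_d)
        if k > 0:
            assert measurement_error(l_d) * k == pytest.approx(1.0)


class TestAngles:
    @pytest.mark.parametrize(
        "dm,dn,expected",
        [(0.0, 10.0, 0.0), (5.0, 5.0, math.pi / 4), (5.0, 0.0, math.pi / 2)],
    )
    def test_atan2_quadrants(self, dm, dn, expected):
        assert vibration_angle(dm, 0.0, dn, 0.0) == pytest.approx(expected)

    def test_degenerate_zero(self):
        assert vibration_angle(1.0, 1.0, 2.0, 2.0) == 0.0

    def test_constant_lambda_arithmetic_series(self):
        lam = np.full(10, 0.3)
        beta = cumulative_angle(lam)
        assert beta[-1] == pytest.approx(10 * 0.3)

    def test_prefix_sum_oracle(self, rng):
        lam = rng.normal(size=200)
        lam[rng.integers(0, 200, size=20)] = np.nan
        beta = cumulative_angle(lam)
        acc = 0.0
        for i in range(200):
            if np.isfinite(lam[i]):
                acc += lam[i]
                assert beta[i] == pytest.approx(acc)
            else:
                assert np.isnan(beta[i])

    def test_empty_interval(self):
        assert cumulative_angle(np.array([])).size == 0


class TestCorrelation:
    def test_self_and_negated(self, rng):
        x = rng.normal(size=50)
        assert peak_quarter_correlation(x, x) == pytest.approx(1.0)
        assert peak_quarter_correlation(x, -x) == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self, rng):
        a = rng.normal(size=1000)
        b = rng.normal(size=1000)
        assert abs(peak_quarter_correlation(a, b)) < 0.1

    def test_constant_trace_undefined(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            peak_quarter_correlation(np.ones(10), np.arange(10.0))


class TestTraceInvariances:
    def test_shift_invariance(self, quarter_result, rng):
        """A per-frame constant offset on L_d (residual eye motion) leaves
        all four vibration traces unchanged to machine precision."""
        import copy

        _, _, res = quarter_result
        d2 = copy.deepcopy(res.decomp)
        off = rng.normal(0, 3, d2.n_frames)
        off[0] = 0.0  # the baseline frame defines zero deformation
        d2.L_d, _ = cv.center_deformation(d2.L_d + off[None, :])
        d2.L_L, d2.L_H = cv.split_frequency(d2.L_d, d2.fs_hz, d2.cutoff_hz)
        tr2 = cv.compute_vibration_traces(d2, res.ap)
        for name in ("peak_vib", "quarter_vib", "cutoff_vib"):
            a = getattr(res.traces, name)
            b = getattr(tr2, name)
            assert (np.isfinite(a) == np.isfinite(b)).all()
            ok = np.isfinite(a)
            np.testing.assert_allclose(a[ok], b[ok], atol=1e-9)
        np.testing.assert_array_equal(
            res.traces.n_d, tr2.n_d, err_msg="n_d trace changed under offset"
        )

    def test_bitwise_reproducibility(self, quarter_result):
        _, _, res = quarter_result
        tr2 = cv.compute_vibration_traces(res.decomp, res.ap)
        for name in ("m_kl", "m_kr", "m_fl", "m_fr", "delta", "lam", "beta"):
            np.testing.assert_array_equal(
                getattr(res.traces, name), getattr(tr2, name)
            )

    def test_delta_times_count_is_one(self, quarter_result):
        _, _, res = quarter_result
        for i in res.ap.interior():
            count = int(np.sum(res.decomp.L_d[:, i] > 2.0))
            if count:
                assert res.traces.delta[i] * count == pytest.approx(1.0)
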