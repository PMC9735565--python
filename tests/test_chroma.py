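"""RGB averaging, Cg conversion and dropout interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from facepulse import (
    ChromaSeries,
    UnrecoverableGapError,
    generate_cg_fixture,
    inject_gap,
    interpolate_gaps,
    roi_mean_rgb,
    to_cg,
)
from facepulse.roi import RoiBox


def roi(x=0, y=0, w=4, h=4):
    return RoiBox("ROI1", x, y, w, h)


class TestRoiMeanRgb:
    def test_uniform_patch(self):
        frame = np.full((8, 8, 3), (150, 100, 90), dtype=np.uint8)
        assert roi_mean_rgb(frame, roi()) == (150.0, 100.0, 90.0)

    def test_two_pixel_hand_mean(self):
        frame = np.zeros((1, 2, 3), dtype=np.uint8)
        frame[0, 1] = 255
        assert roi_mean_rgb(frame, roi(w=2, h=1)) == (127.5, 127.5, 127.5)

    def test_checkerboard_hand_mean(self):
        frame = np.zeros((2, 2, 3), dtype=np.uint8)
        frame[0, 0] = frame[1, 1] = (100, 0, 0)
        frame[0, 1] = frame[1, 0] = (0, 100, 0)
        assert roi_mean_rgb(frame, roi(w=2, h=2)) == (50.0, 50.0, 0.0)

    def test_half_open_rectangle_excludes_far_edge(self):
        frame = np.zeros((3, 3, 3), dtype=np.uint8)
        frame[2, :, :] = 255  # outside [0,2) x [0,3)
        r, g, b = roi_mean_rgb(frame, roi(w=3, h=2))
        assert r == g == b == 0.0


class TestToCg:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((100, 100, 100), 0.0), ((0, 255, 0), 127.5), ((255, 0, 255), -127.5)],
    )
    def test_hand_values(self, rgb, expected):
        assert to_cg(*rgb) == expected

    @given(
        patch=hnp.arrays(
            np.uint8, st.tuples(st.integers(1, 6), st.integers(1, 6), st.just(3))
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_cg_linearity_mean_commutes(self, patch):
        # Cg is linear in the channels: averaging then converting equals
        # converting per pixel then averaging.
        r, g, b = roi_mean_rgb(patch, roi(w=patch.shape[1], h=patch.shape[0]))
        per_pixel = to_cg(
            patch[..., 0].astype(float), patch[..., 1].astype(float), patch[..., 2].astype(float)
        )
        assert to_cg(r, g, b) == pytest.approx(per_pixel.mean(), abs=1e-9)


def _natural_spline_oracle(t, y, t_query):
    """Brute-force natural cubic spline: solve the tridiagonal system for
    the knot second derivatives M_i (M_0 = M_n = 0), then evaluate."""
    n = len(t) - 1
    h = np.diff(t)
    A = np.zeros((n + 1, n + 1))
    rhs = np.zeros(n + 1)
    A[0, 0] = A[n, n] = 1.0
    for i in range(1, n):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2.0 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        rhs[i] = 6.0 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    M = np.linalg.solve(A, rhs)
    out = []
    for tq in np.atleast_1d(t_query):
        i = min(np.searchsorted(t, tq, side="right") - 1, n - 1)
        dt = tq - t[i]
        hi = h[i]
        val = (
            M[i] * (t[i + 1] - tq) ** 3 / (6 * hi)
            + M[i + 1] * dt**3 / (6 * hi)
            + (y[i] / hi - M[i] * hi / 6) * (t[i + 1] - tq)
            + (y[i + 1] / hi - M[i + 1] * hi / 6) * dt
        )
        out.append(val)
    return np.array(out)


def series_from_values(cg, fs=30.0, valid=None):
    n = len(cg)
    cg = np.asarray(cg, dtype=float)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    base = np.full(n, 100.0)
    return ChromaSeries("ROI1", fs, np.arange(n), base, base + 2 * cg, base, cg, valid)


class TestInterpolateGaps:
    def test_collinear_points_reproduce_line_exactly(self):
        # cg(t) = t sampled at t=0,1,3,4 s (fs=1), t=2 missing
        valid = np.array([True, True, False, True, True])
        s = series_from_values([0.0, 1.0, np.nan, 3.0, 4.0], fs=1.0, valid=valid)
        out = interpolate_gaps(s, max_gap_s=2.0)
        assert out.cg[2] == pytest.approx(2.0, abs=1e-12)

    def test_single_missing_sample_on_sinusoid_recovered(self):
        s = generate_cg_fixture(72.0, fps=30.0, duration_s=10.0)
        s.valid[150] = False
        s.cg[150] = np.nan
        out = interpolate_gaps(s)
        truth = np.sin(2 * np.pi * 1.2 * 150 / 30.0)
        assert abs(out.cg[150] - truth) < 1e-3  # amplitude is 1

    def test_long_gap_raises_with_time_span(self):
        s = generate_cg_fixture(72.0, duration_s=20.0)
        gapped = inject_gap(s, start_s=5.0, duration_s=3.0)
        with pytest.raises(UnrecoverableGapError) as exc:
            interpolate_gaps(gapped, max_gap_s=2.0)
        assert exc.value.start_s == pytest.approx(5.0, abs=0.1)
        assert exc.value.end_s == pytest.approx(8.0, abs=0.1)

    def test_interpolation_is_interpolatory(self):
        s = generate_cg_fixture(80.0, duration_s=10.0, noise_sd=0.2, seed=4)
        gapped = inject_gap(s, start_s=3.0, duration_s=0.5)
        out = interpolate_gaps(gapped)
        np.testing.assert_array_equal(out.cg[gapped.valid], s.cg[gapped.valid])

    def test_leading_and_trailing_invalid_runs_trimmed(self):
        cg = np.sin(np.arange(40) * 0.3)
        valid = np.ones(40, dtype=bool)
        valid[:3] = valid[-2:] = False
        s = series_from_values(np.where(valid, cg, np.nan), fs=10.0, valid=valid)
        out = interpolate_gaps(s)
        assert out.n == 35
        assert out.frame_index[0] == 3 and out.frame_index[-1] == 37
        assert out.valid.all()

    def test_matches_brute_force_natural_spline_oracle(self):
        rng = np.random.default_rng(11)
        cg = rng.normal(size=12)
        valid = np.ones(12, dtype=bool)
        valid[[4, 5, 9]] = False
        s = series_from_values(np.where(valid, cg, np.nan), fs=2.0, valid=valid)
        out = interpolate_gaps(s, max_gap_s=2.0)
        t = s.t_sec
        expected = _natural_spline_oracle(t[valid], cg[valid], t[~valid])
        np.testing.assert_allclose(out.cg[~valid], expected, atol=1e-9)

    def test_too_few_valid_samples_rejected(self):
        s = series_from_values([1.0, np.nan, 2.0, np.nan, 3.0], fs=1.0,
                               valid=np.array([1, 0, 1, 0, 1], dtype=bool))
        with pytest.raises(UnrecoverableGapError):
            interpolate_gaps(s)

    def test_rgb_channels_also_repaired(self):
        s = generate_cg_fixture(72.0, duration_s=10.0)
        gapped = inject_gap(s, start_s=4.0, duration_s=0.2)
        out = interpolate_gaps(gapped)
        assert np.isfinite(out.mean_g).all()
        np.testing.assert_allclose(
            out.cg, -0.25 * out.mean_r + 0.5 * out.mean_g - 0.25 * out.mean_b, atol=1e-6
        )


def test_csv_round_trip(tmp_path):
    s = generate_cg_fixture(72.0, duration_s=5.0, noise_sd=0.1, seed=3)
    s.valid[10] = False
    path = tmp_path / "cg.csv"
    s.to_csv(path)
    back = ChromaSeries.from_csv(path)
    assert back.roi_id == s.roi_id
    assert back.fs == pytest.approx(s.fs)
    np.testing.assert_allclose(back.cg, s.cg, atol=1e-9)
    np.testing.assert_array_equal(back.valid, s.valid)
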