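"""Temporal preprocessing chain: discard, detrend, confounds, band-pass,
map smoothing and framewise displacement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from restmetrics.preprocess import (bandpass, build_confounds, detrend_linear,
                                    discard_initial, extract_tissue_regressors,
                                    fd_jenkinson, friston24_expand,
                                    regress_nuisance, screen_motion,
                                    smooth_gaussian, _rigid_transform)

from conftest import make_bold, series_bold


class TestDiscard:
    def test_standard_discard(self, rng):
        bold = make_bold(rng.normal(size=(2, 2, 2, 186)))
        out = discard_initial(bold, 10)
        assert out.n_volumes == 176
        assert np.array_equal(out.data, bold.data[..., 10:])
        assert out.history[-1] == "discard(10)"

    def test_zero_is_identity(self, rng):
        bold = make_bold(rng.normal(size=(2, 2, 2, 20)))
        assert np.array_equal(discard_initial(bold, 0).data, bold.data)

    def test_discarding_everything_fails(self, rng):
        bold = make_bold(rng.normal(size=(1, 1, 1, 5)))
        with pytest.raises(ValueError):
            discard_initial(bold, 5)


class TestDetrend:
    def test_removes_line_keeps_mean(self):
        t = np.arange(50, dtype=float)
        bold = series_bold(3.0 + 0.25 * t)
        out = detrend_linear(bold).data.ravel()
        assert np.allclose(out, out.mean())
        assert out.mean() == pytest.approx((3.0 + 0.25 * t).mean(), rel=1e-12)

    def test_full_period_sinusoid_untouched(self):
        # 5 exact periods, even-symmetric about the series midpoint: such a
        # sinusoid is exactly orthogonal to both the constant and the ramp,
        # so detrending must leave it unchanged.
        t = np.arange(100, dtype=float)
        x = 100.0 + 4.0 * np.cos(2 * np.pi * 5 * (t - 49.5) / 100)
        out = detrend_linear(series_bold(x)).data.ravel()
        assert np.allclose(out, x, atol=1e-8)

    def test_idempotent(self, rng):
        bold = make_bold(rng.normal(1000, 5, size=(3, 3, 3, 40)))
        once = detrend_linear(bold)
        twice = detrend_linear(once)
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_mean_preserved(self, rng):
        bold = make_bold(rng.normal(1000, 5, size=(3, 3, 3, 40)))
        out = detrend_linear(bold)
        assert np.allclose(out.data.mean(axis=3), bold.data.mean(axis=3), rtol=1e-8)


class TestFriston24:
    def test_zero_trace_expands_to_zeros(self):
        out = friston24_expand(np.zeros((30, 6)))
        assert out.shape == (30, 24)
        assert not out.to_numpy().any()

    def test_single_entry_placement(self):
        m = np.zeros((10, 6))
        r, j = 4, 2
        m[r, j] = 0.5
        out = friston24_expand(m).to_numpy()
        expected = np.zeros((10, 24))
        expected[r, j] = 0.5
        expected[r + 1, j + 6] = 0.5
        expected[r, j + 12] = 0.25
        expected[r + 1, j + 18] = 0.25
        assert np.array_equal(out, expected)

    def test_shape_and_bad_input(self, rng):
        assert friston24_expand(rng.normal(size=(176, 6))).shape == (176, 24)
        with pytest.raises(ValueError):
            friston24_expand(rng.normal(size=(176, 5)))


class TestTissueRegressors:
    def test_single_voxel_mask_returns_that_series(self, rng):
        bold = make_bold(rng.normal(size=(3, 3, 3, 12)))
        one = np.zeros((3, 3, 3), dtype=bool)
        one[1, 2, 0] = True
        full = np.ones((3, 3, 3), dtype=bool)
        out = extract_tissue_regressors(bold, one, full, full)
        assert np.allclose(out["wm_mean"], bold.data[1, 2, 0])

    def test_checkerboard_averages_to_one(self):
        data = np.indices((4, 4, 4)).sum(axis=0) % 2 * 2.0
        bold = make_bold(np.repeat(data[..., None], 6, axis=3))
        full = np.ones((4, 4, 4), dtype=bool)
        out = extract_tissue_regressors(bold, full, full, full)
        assert np.allclose(out["global_mean"], 1.0)

    def test_empty_mask_rejected(self, rng):
        bold = make_bold(rng.normal(size=(2, 2, 2, 5)))
        full = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            extract_tissue_regressors(bold, np.zeros((2, 2, 2), bool), full, full)


class TestRegressNuisance:
    def test_no_confounds_is_identity(self, rng):
        bold = make_bold(rng.normal(size=(2, 2, 2, 20)))
        assert np.array_equal(regress_nuisance(bold, None).data, bold.data)

    def test_perfect_fit_leaves_constant(self, rng):
        c = rng.normal(size=30)
        conf = pd.DataFrame({"c": c})
        bold = series_bold(5.0 + 2.0 * c)
        out = regress_nuisance(bold, conf).data.ravel()
        assert np.allclose(out, 5.0 + 2.0 * c.mean(), atol=1e-10)

    def test_matches_qr_oracle_and_orthogonality(self, rng):
        T = 40
        conf = pd.DataFrame(rng.normal(size=(T, 3)), columns=list("abc"))
        bold = make_bold(rng.normal(100, 3, size=(2, 2, 1, T)))
        out = regress_nuisance(bold, conf)
        X = np.column_stack([np.ones(T), conf.to_numpy() - conf.to_numpy().mean(axis=0)])
        Q, _ = np.linalg.qr(X)
        for idx in np.ndindex(2, 2, 1):
            y = bold.data[idx]
            resid_oracle = y - Q @ (Q.T @ y)
            expected = resid_oracle + y.mean()
            got = out.data[idx]
            assert np.allclose(got, expected, atol=1e-8)
            for col in conf.columns:
                c = conf[col] - conf[col].mean()
                rel = abs(np.dot(got - got.mean(), c))
                rel /= max(np.linalg.norm(got - got.mean()) * np.linalg.norm(c), 1e-30)
                assert rel < 1e-6

    def test_mean_preserved(self, rng):
        conf = pd.DataFrame(rng.normal(size=(25, 4)))
        conf.columns = [f"c{i}" for i in range(4)]
        bold = make_bold(rng.normal(1000, 5, size=(2, 2, 2, 25)))
        out = regress_nuisance(bold, conf)
        assert np.allclose(out.data.mean(axis=3), bold.data.mean(axis=3), rtol=1e-8)

    def test_collinear_confounds_named(self, rng):
        c = rng.normal(size=20)
        conf = pd.DataFrame({"a": c, "b": 2 * c})
        bold = make_bold(rng.normal(size=(1, 1, 1, 20)))
        with pytest.raises(np.linalg.LinAlgError, match="b"):
            regress_nuisance(bold, conf)


class TestBandpass:
    def test_in_band_bin_passes(self):
        T, tr = 176, 2.17
        k = 15  # f = 15/(176*2.17) ~ 0.0393 Hz, inside [0.01, 0.08]
        t = np.arange(T)
        x = np.sin(2 * np.pi * k * t / T)
        out = bandpass(series_bold(x, tr_s=tr)).data.ravel()
        assert np.abs(out).max() > 0.99 * np.abs(x).max()
        assert np.allclose(out, x, atol=1e-9)

    def test_out_of_band_bin_removed(self):
        T, tr = 176, 2.17
        k = 76  # ~0.199 Hz, above 0.08 Hz
        x = np.sin(2 * np.pi * k * np.arange(T) / T)
        out = bandpass(series_bold(x, tr_s=tr)).data.ravel()
        assert np.abs(out).max() < 0.01

    def test_constant_series_unchanged(self):
        out = bandpass(series_bold(np.full(64, 7.5))).data.ravel()
        assert np.allclose(out, 7.5, atol=1e-10)

    def test_bad_band_rejected(self, rng):
        bold = series_bold(rng.normal(size=64))
        with pytest.raises(ValueError):
            bandpass(bold, 0.05, 0.4)  # above Nyquist ~= 0.23 Hz
        with pytest.raises(ValueError):
            bandpass(bold, 0.0, 0.08)


class TestSmoothing:
    def test_zero_fwhm_identity(self, rng):
        v = rng.normal(size=(8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        assert np.array_equal(smooth_gaussian(v, mask, 0.0, 3.0), v)

    def test_impulse_mass_preserved(self):
        v = np.zeros((24, 24, 24))
        v[12, 12, 12] = 1.0
        mask = np.ones_like(v, bool)
        out = smooth_gaussian(v, mask, 6.0, 3.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_constant_map_invariant_under_partial_mask(self, rng):
        mask = rng.random((10, 10, 10)) > 0.4
        v = np.where(mask, 3.25, 0.0)
        out = smooth_gaussian(v, mask, 6.0, 3.0)
        assert np.allclose(out[mask], 3.25, atol=1e-8)
        assert not out[~mask].any()


class TestFramewiseDisplacement:
    def test_no_motion_gives_zero(self):
        fd, mean_fd = fd_jenkinson(np.zeros((10, 6)))
        assert not fd.any() and mean_fd == 0.0

    def test_unit_translation_step(self):
        m = np.zeros((3, 6))
        m[1, 0] = 1.0  # 1 mm translation in x between volumes 0 and 1
        m[2, 0] = 1.0  # then no further movement
        fd, _ = fd_jenkinson(m)
        assert fd[0] == 0.0
        assert fd[1] == pytest.approx(1.0, abs=1e-12)
        assert fd[2] == pytest.approx(0.0, abs=1e-12)

    def test_small_rotation_matches_sphere_integral_oracle(self, rng):
        theta, radius = 0.01, 80.0
        m = np.zeros((2, 6))
        m[1, 4] = theta  # rotation about y
        fd, _ = fd_jenkinson(m, radius_mm=radius)
        # Monte-Carlo RMS displacement over the solid 80 mm sphere
        pts = rng.normal(size=(200_000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= radius * rng.random(200_000)[:, None] ** (1 / 3)
        M = _rigid_transform(m[1]) @ np.linalg.inv(_rigid_transform(m[0])) - np.eye(4)
        disp = pts @ M[:3, :3].T + M[:3, 3]
        oracle = np.sqrt((disp ** 2).sum(axis=1).mean())
        assert fd[1] == pytest.approx(oracle, rel=0.02)

    def test_nonfinite_rejected(self):
        m = np.zeros((5, 6))
        m[2, 1] = np.nan
        with pytest.raises(ValueError):
            fd_jenkinson(m)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(hnp.arrays(float, (6, 3), elements=st.floats(-2.0, 2.0)))
def test_fd_of_pure_translations_is_step_distance(translations):
    """Without rotation, framewise displacement reduces to the Euclidean
    distance between consecutive translation vectors."""
    motion = np.hstack([translations, np.zeros((6, 3))])
    fd, _ = fd_jenkinson(motion)
    steps = np.linalg.norm(np.diff(translations, axis=0), axis=1)
    assert np.allclose(fd[1:], steps, atol=1e-9)


class TestMotionScreen:
    def test_flags_exceeding_translation_without_deleting(self):
        m = np.zeros((20, 6))
        m[10, 1] = 4.0  # 4 mm translation
        report = screen_motion(m)
        assert report["flagged"] and report["max_translation_mm"] == 4.0

    def test_small_motion_not_flagged(self):
        m = np.full((20, 6), 0.01)
        assert not screen_motion(m)["flagged"]


def test_build_confounds_drops_zero_columns(rng):
    bold = make_bold(rng.normal(1000, 5, size=(4, 4, 4, 30)))
    motion = np.zeros((30, 6))
    motion[:, 0] = np.linspace(0, 0.1, 30)
    full = np.ones((4, 4, 4), bool)
    conf = build_confounds(motion, bold, full, full, full)
    # 4 nonzero motion-derived columns (tx, lag, sq, lag sq) + 3 tissue means
    assert conf.shape[1] == 7
    assert not (conf == 0).all(axis=0).any()
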