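"""ALFF / fALFF / PerAF / ReHo identities, scale relations and standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import rankdata

from restmetrics.metrics import (SpectrumSettings, alff, falff, kendall_w,
                                 peraf, reho, standardize_mean_divide,
                                 standardize_z)

from conftest import make_bold, series_bold

T, TR = 176, 2.17


def in_band_bins():
    freqs = np.fft.rfftfreq(T, d=TR)[1:]
    return ((freqs >= 0.01) & (freqs <= 0.08)).sum()


class TestAlff:
    def test_constant_series_zero(self):
        m = alff(series_bold(np.full(T, 42.0)))
        assert m.values[0, 0, 0] == 0.0

    def test_pure_bin_sinusoid_closed_form(self):
        """A sinusoid on an exact DFT bin has single-sided amplitude c, so
        ALFF = c / (number of in-band bins); cross-checked against a direct
        DFT oracle."""
        c, k = 3.0, 15  # bin 15 -> 0.0393 Hz, in band
        x = c * np.sin(2 * np.pi * k * np.arange(T) / T)
        m = alff(series_bold(x))
        assert m.values[0, 0, 0] == pytest.approx(c / in_band_bins(), rel=1e-10)
        # independent oracle: explicit DFT amplitude average
        freqs = np.fft.rfftfreq(T, d=TR)
        amp = 2 * np.abs(np.fft.rfft(x - x.mean())) / T
        band = (freqs >= 0.01) & (freqs <= 0.08)
        assert m.values[0, 0, 0] == pytest.approx(amp[band].mean(), rel=1e-12)

    def test_homogeneous_degree_one(self, rng):
        x = rng.normal(size=(2, 2, 1, T))
        m1 = alff(make_bold(x))
        m2 = alff(make_bold(7.5 * x))
        assert np.allclose(m2.values, 7.5 * m1.values, rtol=1e-10)

    def test_band_without_bins_rejected(self):
        with pytest.raises(ValueError, match="bin"):
            alff(series_bold(np.arange(20.0), tr_s=0.1),
                 SpectrumSettings(0.011, 0.012))


class TestFalff:
    def test_pure_in_band_is_one(self):
        x = np.sin(2 * np.pi * 15 * np.arange(T) / T)
        assert falff(series_bold(x)).values[0, 0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_pure_out_of_band_is_zero(self):
        x = np.sin(2 * np.pi * 76 * np.arange(T) / T)  # ~0.199 Hz
        assert falff(series_bold(x)).values[0, 0, 0] < 1e-10

    def test_scale_invariant(self, rng):
        x = rng.normal(size=(2, 2, 1, T))
        assert np.allclose(falff(make_bold(3.7 * x)).values,
                           falff(make_bold(x)).values, atol=1e-12)


class TestPeraf:
    def test_two_point_hand_example(self):
        m = peraf(series_bold([90.0, 110.0]))
        assert m.values[0, 0, 0] == pytest.approx(10.0, abs=1e-12)

    def test_constant_series_zero(self):
        assert peraf(series_bold(np.full(30, 55.0))).values[0, 0, 0] == 0.0

    def test_scale_invariant(self, rng):
        x = rng.normal(1000, 10, size=(2, 2, 2, 60))
        assert np.allclose(peraf(make_bold(0.001 * x)).values,
                           peraf(make_bold(x)).values, atol=1e-12)

    def test_zero_mean_voxel_logged_not_fatal(self, rng):
        x = rng.normal(0, 1, size=(1, 1, 1, 40))
        x -= x.mean()
        m = peraf(make_bold(x))
        assert m.values[0, 0, 0] == 0.0
        assert m.n_degenerate_voxels == 1


class TestReho:
    def test_identical_monotone_series_give_unity(self):
        x = np.linspace(0, 1, 20) ** 2
        data = np.broadcast_to(x, (3, 3, 3, 20)).copy()
        m = reho(make_bold(data))
        assert m.values[1, 1, 1] == pytest.approx(1.0, abs=1e-12)
        assert m.neighbor_counts[1, 1, 1] == 27

    def test_null_mean_approximates_one_over_k(self, rng):
        """For K independent continuous series E[W] ~ 1/K."""
        K, n, reps = 27, 176, 500
        ws = np.array([kendall_w(rng.normal(size=(K, n))) for _ in range(reps)])
        se = ws.std(ddof=1) / np.sqrt(reps)
        assert abs(ws.mean() - 1.0 / K) < 3 * se

    def test_two_series_match_brute_force(self, rng):
        """W for a 2-series toy equals an explicit rank-sum evaluation."""
        a = rng.normal(size=10)
        series = np.stack([a, -a])
        # brute force, written out directly from the definition
        ranks = np.stack([rankdata(a), rankdata(-a)])
        R = ranks.sum(axis=0)
        n, K = 10, 2
        w_brute = (np.sum(R ** 2) - n * (K * (n + 1) / 2) ** 2) / (K ** 2 * (n ** 3 - n) / 12)
        assert kendall_w(series) == pytest.approx(w_brute, abs=1e-12)
        data = np.zeros((2, 1, 1, 10))
        data[0, 0, 0], data[1, 0, 0] = a, -a
        m = reho(make_bold(data), neighborhood=27)
        assert m.values[0, 0, 0] == pytest.approx(w_brute, abs=1e-12)

    def test_out_of_mask_voxels_never_read(self, rng):
        data = rng.normal(size=(3, 3, 3, 15))
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        mask[0, 1, 1] = True
        data[~mask] = np.nan  # poisoned: any read would propagate NaN
        m = reho(make_bold(data, mask=mask))
        assert np.isfinite(m.values).all()
        assert m.neighbor_counts[1, 1, 1] == 2

    def test_rank_invariance_under_monotone_transform(self, rng):
        data = rng.normal(size=(4, 4, 4, 20))
        m1 = reho(make_bold(data))
        m2 = reho(make_bold(np.exp(data)))
        assert np.allclose(m1.values, m2.values, atol=1e-12)

    def test_neighborhood_sizes(self, rng):
        data = rng.normal(size=(5, 5, 5, 15))
        for nb in (7, 19, 27):
            m = reho(make_bold(data), neighborhood=nb)
            assert m.neighbor_counts[2, 2, 2] == nb
        with pytest.raises(ValueError):
            reho(make_bold(data), neighborhood=9)


class TestStandardization:
    def test_z_scores_have_unit_moments(self, rng):
        m = alff(make_bold(rng.normal(size=(4, 4, 4, T))))
        z = standardize_z(m)
        inside = z.values[z.mask]
        assert inside.mean() == pytest.approx(0.0, abs=1e-10)
        assert inside.std(ddof=0) == pytest.approx(1.0, abs=1e-10)
        assert z.standardization == "z"

    def test_z_idempotent(self, rng):
        m = alff(make_bold(rng.normal(size=(4, 4, 4, T))))
        z1 = standardize_z(m)
        z2 = standardize_z(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-10)

    def test_two_voxel_population_sd_convention(self):
        m = peraf(make_bold(np.stack([np.full(4, 100.0),
                                      np.full(4, 100.0)]).reshape(2, 1, 1, 4)))
        m = m.with_values(np.array([1.0, 3.0]).reshape(2, 1, 1))
        z = standardize_z(m)
        assert np.allclose(z.values.ravel(), [-1.0, 1.0])

    def test_mean_division(self, rng):
        m = peraf(make_bold(rng.normal(1000, 10, size=(3, 3, 3, 40))))
        d = standardize_mean_divide(m)
        assert d.values[d.mask].mean() == pytest.approx(1.0, abs=1e-10)
        m2 = m.with_values(np.where(m.mask, 5.0, 0.0))
        assert np.allclose(standardize_mean_divide(m2).values[m.mask], 1.0)
        hand = m.with_values(np.zeros_like(m.values))
        hand.values[0, 0, 0], hand.values[0, 0, 1] = 2.0, 6.0
        mask2 = np.zeros((3, 3, 3), bool)
        mask2[0, 0, 0] = mask2[0, 0, 1] = True
        hand.mask = mask2
        out = standardize_mean_divide(hand)
        assert np.allclose(out.values[0, 0, :2], [0.5, 1.5])

    def test_degenerate_maps_rejected(self):
        m = peraf(make_bold(np.full((2, 2, 2, 5), 100.0)))
        with pytest.raises(FloatingPointError):
            standardize_z(m)
        with pytest.raises(FloatingPointError):
            standardize_mean_divide(m)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(hnp.arrays(float, (1, 1, 1, 24), elements=st.floats(50.0, 150.0)),
       st.floats(0.1, 50.0))
def test_peraf_nonnegative_and_scale_invariant(x, c):
    """PerAF is nonnegative and invariant under positive rescaling for any
    positive-baseline series."""
    v1 = peraf(make_bold(x)).values[0, 0, 0]
    v2 = peraf(make_bold(c * x)).values[0, 0, 0]
    assert v1 >= 0.0
    assert v2 == pytest.approx(v1, rel=1e-9, abs=1e-9)


def test_alff_peraf_group_difference_signs_agree(rng):
    """A planted band-limited amplitude increase raises both ALFF and PerAF."""
    base = 1000.0
    t = np.arange(T)
    quiet = base + rng.normal(0, 5, size=(1, 1, 1, T))
    loud = quiet + 6.0 * np.sin(2 * np.pi * 15 * t / T)
    d_alff = alff(make_bold(loud)).values[0, 0, 0] - alff(make_bold(quiet)).values[0, 0, 0]
    d_peraf = peraf(make_bold(loud)).values[0, 0, 0] - peraf(make_bold(quiet)).values[0, 0, 0]
    assert d_alff > 0 and d_peraf > 0
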