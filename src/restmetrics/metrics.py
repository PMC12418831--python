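"""Voxelwise regional activity metrics: ALFF, fALFF, PerAF and ReHo.

ALFF is the mean single-sided spectral amplitude within the low-frequency
band (0.01-0.08 Hz by default); fALFF is the ratio of the in-band amplitude
sum to the amplitude sum over the whole non-DC spectrum; PerAF is the mean
absolute deviation of the series from its temporal mean, as a percentage of
that mean; ReHo is Kendall's coefficient of concordance (KCC) between a
voxel's time series and its neighbors (27-voxel cubic neighborhood by
default).

Amplitude convention: after removing the temporal mean, the single-sided
amplitude of DFT bin k is 2|X_k|/N, DC excluded. Any fixed convention
cancels under z-standardization; this one is stated for reproducibility.
A spectral bin is "in band" iff lo <= f_k <= hi (closed interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .containers import BoldSeries, MetricMap


@dataclass
class SpectrumSettings:
    band_lo_hz: float = 0.01
    band_hi_hz: float = 0.08
    exclude_dc: bool = True

    def validate(self, nyquist_hz: float) -> None:
        if not (0.0 < self.band_lo_hz < self.band_hi_hz <= nyquist_hz + 1e-12):
            raise ValueError(
                f"band [{self.band_lo_hz}, {self.band_hi_hz}] Hz must lie in "
                f"(0, Nyquist={nyquist_hz:.4f}]")


def _amplitudes(bold: BoldSeries):
    """Single-sided amplitude spectrum of every voxel.

    Returns (freqs, amps) with amps of shape (n_bins, x, y, z), the DC bin
    excluded; amplitude of bin k is 2|X_k|/N of the demeaned series.
    """
    T = bold.n_volumes
    data = bold.data - bold.data.mean(axis=3, keepdims=True)
    spec = np.fft.rfft(data, axis=3)
    freqs = np.fft.rfftfreq(T, d=bold.tr_s)
    amps = 2.0 * np.abs(spec) / T
    return freqs[1:], np.moveaxis(amps[..., 1:], 3, 0)


def _band_bins(freqs: np.ndarray, settings: SpectrumSettings) -> np.ndarray:
    band = (freqs >= settings.band_lo_hz) & (freqs <= settings.band_hi_hz)
    if not band.any():
        raise ValueError(
            f"no DFT bin falls in [{settings.band_lo_hz}, {settings.band_hi_hz}] Hz; "
            f"bin frequencies: {np.round(freqs, 5).tolist()}")
    return band


def alff(bold: BoldSeries, settings: SpectrumSettings | None = None) -> MetricMap:
    """Amplitude of low-frequency fluctuation: mean in-band amplitude."""
    settings = settings or SpectrumSettings()
    settings.validate(bold.nyquist_hz)
    if bold.n_volumes < 16:
        raise ValueError("ALFF needs at least 16 timepoints for usable in-band bins")
    freqs, amps = _amplitudes(bold)
    band = _band_bins(freqs, settings)
    values = amps[band].mean(axis=0)
    values[~bold.mask] = 0.0
    return MetricMap(values=values, metric="ALFF", mask=bold.mask,
                     band_hz=(settings.band_lo_hz, settings.band_hi_hz),
                     subject_id=bold.subject_id)


def falff(bold: BoldSeries, settings: SpectrumSettings | None = None) -> MetricMap:
    """Fractional ALFF: in-band amplitude sum over full-spectrum amplitude sum.

    Requires the unfiltered series — a prior band-pass empties the
    denominator's out-of-band mass and drives the ratio to 1.
    """
    settings = settings or SpectrumSettings()
    settings.validate(bold.nyquist_hz)
    if bold.n_volumes < 16:
        raise ValueError("fALFF needs at least 16 timepoints for usable in-band bins")
    freqs, amps = _amplitudes(bold)
    band = _band_bins(freqs, settings)
    num = amps[band].sum(axis=0)
    den = amps.sum(axis=0)
    values = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    values[~bold.mask] = 0.0
    return MetricMap(values=values, metric="fALFF", mask=bold.mask,
                     band_hz=(settings.band_lo_hz, settings.band_hi_hz),
                     subject_id=bold.subject_id)


def peraf(bold: BoldSeries) -> MetricMap:
    """Percent amplitude of fluctuation.

    PerAF = (1/N) * sum_i |(X_i - mu)/mu| * 100 with mu the temporal mean.
    Voxels whose mean is at machine-epsilon scale are set to 0 and counted
    in the map's QC attribute rather than raising.
    """
    mu = bold.data.mean(axis=3)
    scale = np.abs(bold.data).max()
    degenerate = np.abs(mu) <= np.finfo(float).eps * max(scale, 1.0)
    safe_mu = np.where(degenerate, 1.0, mu)
    mad = np.abs(bold.data - mu[..., None]).mean(axis=3)
    values = mad / np.abs(safe_mu) * 100.0
    values[degenerate] = 0.0
    values[~bold.mask] = 0.0
    out = MetricMap(values=values, metric="PerAF", mask=bold.mask,
                    subject_id=bold.subject_id)
    out.n_degenerate_voxels = int((degenerate & bold.mask).sum())
    return out


_NEIGHBORHOODS = {7: 1, 19: 2, 27: 3}


def _neighborhood_offsets(n_voxels: int) -> list[tuple[int, int, int]]:
    """Offsets of the cubic neighborhood: 7 = faces, 19 = faces+edges,
    27 = full 3x3x3 cube (the voxel itself included in all three)."""
    if n_voxels not in _NEIGHBORHOODS:
        raise ValueError(f"neighborhood must be one of {sorted(_NEIGHBORHOODS)}")
    max_l1 = _NEIGHBORHOODS[n_voxels]
    return [(dx, dy, dz)
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if abs(dx) + abs(dy) + abs(dz) <= max_l1]


def reho(bold: BoldSeries, neighborhood: int = 27) -> MetricMap:
    """Regional homogeneity: KCC of each voxel with its in-mask neighbors.

    Each series is ranked over time (midranks on ties); with K concordant
    series of length n and rank sums R_i over the K series at timepoint i,

        W = (sum_i R_i^2 - n * Rbar^2) / ((1/12) K^2 (n^3 - n)),

    Rbar = K (n+1)/2. Boundary voxels use their available in-mask neighbors
    (K < neighborhood), recorded in the map's ``neighbor_counts`` attribute;
    out-of-mask voxels never contribute.
    """
    offsets = _neighborhood_offsets(neighborhood)
    if bold.n_volumes < 10:
        raise ValueError("ReHo needs at least 10 timepoints")
    n = bold.n_volumes
    mask = bold.mask
    data = np.where(mask[..., None], bold.data, 0.0)
    ranks = rankdata(data, axis=3, method="average")
    ranks[~mask] = 0.0

    shape = bold.grid_shape
    rank_sum = np.zeros((*shape, n))
    counts = np.zeros(shape)
    for dx, dy, dz in offsets:
        shifted_r = _shift3d(ranks, dx, dy, dz)
        shifted_m = _shift3d(mask.astype(float), dx, dy, dz)
        rank_sum += shifted_r
        counts += shifted_m
    K = counts
    with np.errstate(invalid="ignore", divide="ignore"):
        rbar = K * (n + 1) / 2.0
        num = (rank_sum ** 2).sum(axis=3) - n * rbar ** 2
        den = (K ** 2) * (n ** 3 - n) / 12.0
        W = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    W = np.clip(W, 0.0, 1.0)
    W[~mask] = 0.0
    out = MetricMap(values=W, metric="ReHo", mask=mask, subject_id=bold.subject_id)
    out.neighbor_counts = np.where(mask, K, 0).astype(int)
    return out


def _shift3d(arr: np.ndarray, dx: int, dy: int, dz: int) -> np.ndarray:
    """Shift a (x,y,z,...) array by integer voxel offsets, zero-filling."""
    out = np.zeros_like(arr)
    src = [slice(max(0, -d), arr.shape[a] - max(0, d)) for a, d in enumerate((dx, dy, dz))]
    dst = [slice(max(0, d), arr.shape[a] - max(0, -d)) for a, d in enumerate((dx, dy, dz))]
    out[tuple(dst)] = arr[tuple(src)]
    return out


def kendall_w(series: np.ndarray) -> float:
    """KCC of K time series given as a (K, n) array (midranks on ties).

    Reference scalar form of the ReHo statistic, usable as a cross-check.
    """
    series = np.asarray(series, dtype=float)
    K, n = series.shape
    ranks = rankdata(series, axis=1, method="average")
    R = ranks.sum(axis=0)
    rbar = K * (n + 1) / 2.0
    num = np.sum(R ** 2) - n * rbar ** 2
    den = K ** 2 * (n ** 3 - n) / 12.0
    return float(num / den)


def standardize_z(metric_map: MetricMap) -> MetricMap:
    """Z-score within the mask (population SD): subtract the global in-mask
    mean, divide by the in-mask SD."""
    vals = metric_map.values
    inside = vals[metric_map.mask]
    sd = inside.std(ddof=0)
    if not sd > 0:
        raise FloatingPointError("in-mask SD is zero; cannot z-standardize")
    out = np.zeros_like(vals)
    out[metric_map.mask] = (inside - inside.mean()) / sd
    return metric_map.with_values(out, standardization="z")


def standardize_mean_divide(metric_map: MetricMap) -> MetricMap:
    """Divide by the global in-mask mean (mean-division standardization)."""
    vals = metric_map.values
    inside = vals[metric_map.mask]
    mean = inside.mean()
    if not mean > 0:
        raise FloatingPointError("in-mask mean is not positive; cannot mean-divide")
    out = np.zeros_like(vals)
    out[metric_map.mask] = inside / mean
    return metric_map.with_values(out, standardization="mean_divided")
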