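"""Temporal preprocessing of BOLD series.

The chain implemented here is: discard initial volumes -> linear detrend ->
nuisance regression (Friston-24 motion expansion, white-matter / CSF /
global-mean signals) -> band-pass (0.01-0.08 Hz, applied only on the branch
feeding regional homogeneity). Detrending and nuisance regression re-add
each voxel's temporal mean so that metrics dividing by the mean (PerAF)
remain well defined. Metric maps, not time series, are smoothed (6 mm FWHM,
mask-aware). Framewise displacement follows the rigid-transform RMS
formulation over an 80 mm sphere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .containers import BoldSeries

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

FRISTON24_ORDER = "6 params, their one-volume backward lags (first row zero), squares, lagged squares"


def discard_initial(bold: BoldSeries, k: int = 10) -> BoldSeries:
    """Drop the first ``k`` volumes (scanner steady-state settling)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= bold.n_volumes:
        raise ValueError(f"cannot discard {k} of {bold.n_volumes} volumes")
    if k == 0:
        return bold.with_data(bold.data, "discard(0)")
    return bold.with_data(bold.data[..., k:], f"discard({k})")


def detrend_linear(bold: BoldSeries) -> BoldSeries:
    """Remove each voxel's best-fit line, re-adding its temporal mean."""
    if bold.n_volumes < 3:
        raise ValueError("detrending needs at least 3 timepoints")
    T = bold.n_volumes
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t - t.mean()])
    Y = bold.data.reshape(-1, T).T  # (T, nvox)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = (resid + Y.mean(axis=0, keepdims=True)).T.reshape(bold.data.shape)
    return bold.with_data(out, "detrend_linear")


def friston24_expand(motion6: np.ndarray) -> pd.DataFrame:
    """Expand 6 rigid-motion parameters into the 24-regressor motion model.

    Column order: the 6 parameters, their one-volume backward lags (first
    row zero-padded), their squares, and the lagged squares.
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError(f"motion trace must be t x 6, got {motion6.shape}")
    lag = np.zeros_like(motion6)
    lag[1:] = motion6[:-1]
    block = np.hstack([motion6, lag, motion6 ** 2, lag ** 2])
    base = ["tx", "ty", "tz", "rx", "ry", "rz"]
    names = (base + [f"{b}_lag" for b in base] + [f"{b}_sq" for b in base]
             + [f"{b}_lag_sq" for b in base])
    return pd.DataFrame(block, columns=names)


def extract_tissue_regressors(bold: BoldSeries, wm_mask: np.ndarray,
                              csf_mask: np.ndarray,
                              global_mask: np.ndarray) -> pd.DataFrame:
    """Spatial-mean time courses over white matter, CSF and the whole brain."""
    cols = {}
    for name, mask in (("wm_mean", wm_mask), ("csf_mean", csf_mask),
                       ("global_mean", global_mask)):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != bold.grid_shape:
            raise ValueError(f"{name} mask shape {mask.shape} != grid {bold.grid_shape}")
        if not mask.any():
            raise ValueError(f"{name} mask is empty")
        cols[name] = bold.data[mask].mean(axis=0)
    return pd.DataFrame(cols)


def build_confounds(motion6: np.ndarray, bold: BoldSeries, wm_mask, csf_mask,
                    global_mask) -> pd.DataFrame:
    """Assemble the full nuisance matrix (Friston-24 + tissue means).

    Constant-zero columns (e.g. a motionless axis) are dropped rather than
    passed on, since they carry no signal and break rank checks.
    """
    f24 = friston24_expand(motion6)
    tissue = extract_tissue_regressors(bold, wm_mask, csf_mask, global_mask)
    if len(f24) != bold.n_volumes:
        raise ValueError(
            f"motion rows ({len(f24)}) != volumes ({bold.n_volumes}); "
            "discard the same leading volumes from the trace")
    conf = pd.concat([f24.reset_index(drop=True), tissue.reset_index(drop=True)], axis=1)
    nonzero = conf.columns[(conf != 0).any(axis=0)]
    return conf[nonzero]


def regress_nuisance(bold: BoldSeries, confounds: pd.DataFrame | None) -> BoldSeries:
    """OLS-residualize every voxel on [intercept | confounds], mean re-added."""
    T = bold.n_volumes
    if confounds is None or confounds.shape[1] == 0:
        return bold.with_data(bold.data, "regress_nuisance(none)")
    C = np.asarray(confounds, dtype=float)
    if C.shape[0] != T:
        raise ValueError(f"confound rows ({C.shape[0]}) != volumes ({T})")
    Cc = C - C.mean(axis=0, keepdims=True)
    X = np.column_stack([np.ones(T), Cc])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(Cc, list(confounds.columns))
        raise np.linalg.LinAlgError(
            f"nuisance design is rank deficient; collinear columns: {bad}")
    Y = bold.data.reshape(-1, T).T
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = (resid + Y.mean(axis=0, keepdims=True)).T.reshape(bold.data.shape)
    return bold.with_data(out, f"regress_nuisance({C.shape[1]} cols)")


def _collinear_columns(C: np.ndarray, names: list[str]) -> list[str]:
    """Greedy QR scan naming columns that add no rank."""
    bad, kept = [], np.ones((C.shape[0], 1))
    for j, name in enumerate(names):
        candidate = np.column_stack([kept, C[:, j]])
        if np.linalg.matrix_rank(candidate) == kept.shape[1]:
            bad.append(name)
        else:
            kept = candidate
    return bad


def bandpass(bold: BoldSeries, lo_hz: float = 0.01, hi_hz: float = 0.08) -> BoldSeries:
    """Ideal (frequency-domain) band-pass; the temporal mean (DC) is kept.

    A DFT bin is retained iff lo <= f_k <= hi (closed band); everything else
    except DC is zeroed, so a constant series passes unchanged.
    """
    nyq = bold.nyquist_hz
    if not (0.0 < lo_hz < hi_hz <= nyq + 1e-12):
        raise ValueError(f"band [{lo_hz}, {hi_hz}] Hz outside (0, Nyquist={nyq:.4f}]")
    T = bold.n_volumes
    freqs = np.fft.rfftfreq(T, d=bold.tr_s)
    keep = (freqs >= lo_hz) & (freqs <= hi_hz)
    keep[0] = True  # DC == temporal mean, re-added by construction
    spec = np.fft.rfft(bold.data, axis=3)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=3)
    return bold.with_data(out, f"bandpass({lo_hz},{hi_hz})")


def smooth_gaussian(values: np.ndarray, mask: np.ndarray, fwhm_mm: float,
                    voxel_size_mm: float) -> np.ndarray:
    """Mask-aware Gaussian smoothing of a 3D map.

    Out-of-mask voxels are excluded from the kernel normalization (the
    smoothed map is smooth(v*m)/smooth(m) inside the mask), so a constant
    map stays constant near the mask edge. ``fwhm_mm == 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if fwhm_mm == 0:
        return values.copy()
    sigma = fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm
    num = gaussian_filter(np.where(mask, values, 0.0), sigma=sigma)
    den = gaussian_filter(mask.astype(float), sigma=sigma)
    out = np.zeros_like(values)
    inside = mask & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    return out


def _rigid_transform(params: np.ndarray) -> np.ndarray:
    """4x4 rigid transform from (tx, ty, tz, rx, ry, rz); rotations in rad,
    composed as R = Rx @ Ry @ Rz."""
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = Rx @ Ry @ Rz
    T[:3, 3] = (tx, ty, tz)
    return T


def fd_jenkinson(motion6: np.ndarray, radius_mm: float = 80.0):
    """Framewise displacement as RMS deviation between consecutive rigid
    transforms over a sphere of ``radius_mm``.

    FD[i] = sqrt(radius^2/5 * trace(A.T A) + b.T b) where (A, b) are the
    linear and translation parts of T_i T_{i-1}^{-1} - I. FD[0] = 0.

    Returns
    -------
    (fd, mean_fd): per-volume FD vector and its mean over volumes 2..T,
    the scalar used as a group-level covariate.
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("motion trace must be t x 6")
    if motion6.shape[0] < 2:
        raise ValueError("need at least 2 volumes for FD")
    if not np.all(np.isfinite(motion6)):
        raise ValueError("motion parameters contain non-finite values")
    transforms = [_rigid_transform(row) for row in motion6]
    fd = np.zeros(len(transforms))
    for i in range(1, len(transforms)):
        M = transforms[i] @ np.linalg.inv(transforms[i - 1]) - np.eye(4)
        A = M[:3, :3]
        b = M[:3, 3]
        fd[i] = np.sqrt(radius_mm ** 2 / 5.0 * np.trace(A.T @ A) + b @ b)
    return fd, float(fd[1:].mean())


def screen_motion(motion6: np.ndarray, max_trans_mm: float = 3.0,
                  max_rot_deg: float = 3.0) -> dict:
    """Flag (never delete) subjects whose head motion exceeds the customary
    3 mm translation / 3 degree rotation exclusion rule."""
    motion6 = np.asarray(motion6, dtype=float)
    max_trans = float(np.abs(motion6[:, :3]).max())
    max_rot = float(np.degrees(np.abs(motion6[:, 3:]).max()))
    return {
        "max_translation_mm": max_trans,
        "max_rotation_deg": max_rot,
        "flagged": bool(max_trans > max_trans_mm or max_rot > max_rot_deg),
    }
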