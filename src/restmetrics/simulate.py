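"""Synthetic two-group resting-state BOLD cohorts with planted amplitude effects.

The generator emulates the acquisition this pipeline is designed for: two
groups (patients vs. healthy controls, default 45 vs. 40 subjects), 186
volumes at TR = 2.17 s on a 3 mm isotropic grid. Every in-brain voxel
carries a positive baseline, AR(1) thermal noise (optionally spatially
smoothed so the statistical maps have a meaningful smoothness for random
field theory), a slow linear scanner drift and a shared global fluctuation.
Inside each effect ROI a band-limited low-frequency oscillation
(0.01-0.08 Hz by default) is added whose amplitude differs between the two
groups — the quantity that ALFF/PerAF-type metrics measure.

Synthetic motion traces are cumulative Gaussian random walks over the six
rigid-body parameters; they exist to exercise the Friston-24 expansion and
framewise-displacement computation and do not corrupt the images (the
simulated data are already aligned on a common grid).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from .containers import BoldSeries
from . import io

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ConfigurationError(ValueError):
    """Raised for degenerate simulation configurations."""


@dataclass
class EffectROI:
    """A spherical region carrying a group-dependent oscillation.

    ``amplitude_control`` / ``amplitude_patient`` are peak amplitudes in
    signal units: with ``n_components == 1`` the planted signal is exactly
    ``a * sin(2*pi*f*t + phase)``; with several components the sum of
    sinusoids is rescaled to the same root-mean-square power (``a/sqrt(2)``).
    """

    center_vox: tuple[int, int, int]
    radius_vox: float
    band_hz: tuple[float, float] = (0.02, 0.06)
    amplitude_control: float = 5.0
    amplitude_patient: float = 3.0
    n_components: int = 5


def _default_rois() -> list[EffectROI]:
    # Three spheres standing in for the handful of group-difference regions
    # a study of this kind reports; patients have reduced amplitude.
    return [
        EffectROI(center_vox=(8, 8, 12), radius_vox=3.0),
        EffectROI(center_vox=(16, 14, 10), radius_vox=2.5),
        EffectROI(center_vox=(12, 16, 14), radius_vox=2.0),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, seeded and fully reproducible."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    n_patients: int = 45
    n_controls: int = 40
    n_volumes: int = 186
    tr_s: float = 2.17
    baseline_mean: float = 1000.0
    roi_effects: list[EffectROI] = field(default_factory=_default_rois)
    noise_sd: float = 8.0
    ar1_phi: float = 0.3
    drift_slope: float = 0.05
    global_fluct_sd: float = 2.0
    motion_sd: float = 0.02
    noise_smooth_fwhm_vox: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if any(g < 2 for g in self.grid_shape):
            raise ConfigurationError("grid_shape axes must all be >= 2")
        if not self.tr_s > 0:
            raise ConfigurationError("tr_s must be positive")
        if not (0.0 <= self.ar1_phi < 1.0):
            raise ConfigurationError("ar1_phi must lie in [0, 1)")
        if not self.baseline_mean > 0:
            raise ConfigurationError("baseline_mean must be positive (PerAF divides by it)")
        if self.n_volumes < 2:
            raise ConfigurationError("n_volumes must be >= 2")
        nyq = 1.0 / (2.0 * self.tr_s)
        for roi in self.roi_effects:
            lo, hi = roi.band_hz
            if not (0.0 < lo <= hi < nyq + 1e-12):
                raise ConfigurationError(
                    f"ROI band {roi.band_hz} outside (0, Nyquist={nyq:.4f}) Hz")
            center = np.asarray(roi.center_vox, dtype=float)
            if np.any(center - roi.radius_vox < 0) or np.any(
                    center + roi.radius_vox > np.asarray(self.grid_shape) - 1):
                raise ConfigurationError(
                    f"ROI at {roi.center_vox} radius {roi.radius_vox} exceeds the grid")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["roi_effects"] = [
            EffectROI(**{**r, "center_vox": tuple(r["center_vox"]),
                         "band_hz": tuple(r["band_hz"])})
            for r in d.get("roi_effects", [])
        ]
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


def brain_masks(config: SimulationConfig):
    """Return (brain, wm, csf) boolean masks on the configured grid.

    The brain is an ellipsoid filling ~90% of each axis; 'white matter' is a
    deeper concentric shell and 'CSF' a small central core. These are
    caricatures sufficient to drive tissue-mean nuisance regression.
    """
    shape = np.asarray(config.grid_shape)
    center = (shape - 1) / 2.0
    semi = 0.45 * shape
    grid = np.indices(config.grid_shape).astype(float)
    r2 = sum(((grid[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    brain = r2 <= 1.0
    wm = r2 <= 0.20
    csf = r2 <= 0.04
    wm &= ~csf
    if not brain.any() or not wm.any() or not csf.any():
        raise ConfigurationError("grid too small to carve brain/WM/CSF masks")
    return brain, wm, csf


def ground_truth_mask(config: SimulationConfig, cortical_only: bool = False) -> np.ndarray:
    """Integer label volume: voxel value k inside the k-th effect ROI (1-based).

    With ``cortical_only`` the labels are restricted to the voxels that
    actually carry the planted effect (brain minus the WM/CSF cores, where
    amplitude effects are modeled as cortical so that tissue-mean nuisance
    regressors do not absorb them).
    """
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    grid = np.indices(config.grid_shape).astype(float)
    for k, roi in enumerate(config.roi_effects, start=1):
        c = np.asarray(roi.center_vox, dtype=float)
        dist2 = sum((grid[a] - c[a]) ** 2 for a in range(3))
        labels[dist2 <= roi.radius_vox ** 2] = k
    if cortical_only:
        brain, wm, csf = brain_masks(config)
        labels[~(brain & ~wm & ~csf)] = 0
    return labels


def _smoothing_sd_factor(fwhm_vox: float, shape) -> float:
    """SD attenuation of a Gaussian smoother, measured on an impulse."""
    if fwhm_vox <= 0:
        return 1.0
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = gaussian_filter(impulse, sigma=fwhm_vox * _FWHM_TO_SIGMA)
    return float(np.sqrt(np.sum(kernel ** 2)))


def generate_subject(config: SimulationConfig, group: str, subject_seed: int,
                     subject_id: str = ""):
    """Simulate one subject.

    Returns
    -------
    (BoldSeries, motion) where motion is an (n_volumes, 6) array of
    translations (mm) and rotations (rad).
    """
    if group not in ("patient", "control"):
        raise ValueError("group must be 'patient' or 'control'")
    rng = np.random.default_rng(subject_seed)
    brain, wm, csf = brain_masks(config)
    cortex = brain & ~wm & ~csf
    if not brain.any():
        raise ConfigurationError("empty brain mask")
    T = config.n_volumes
    t_idx = np.arange(T)
    t_s = t_idx * config.tr_s

    data = np.zeros((*config.grid_shape, T))

    # AR(1) thermal noise, stationary variance noise_sd^2, optionally
    # spatially smoothed and rescaled so per-voxel SD stays noise_sd.
    if config.noise_sd > 0:
        innov_sd = config.noise_sd * np.sqrt(1.0 - config.ar1_phi ** 2)
        white = rng.normal(0.0, innov_sd, size=(*config.grid_shape, T))
        noise = lfilter([1.0], [1.0, -config.ar1_phi], white, axis=3)
        if config.noise_smooth_fwhm_vox > 0:
            sigma = config.noise_smooth_fwhm_vox * _FWHM_TO_SIGMA
            noise = gaussian_filter(noise, sigma=(sigma, sigma, sigma, 0.0))
            noise /= _smoothing_sd_factor(config.noise_smooth_fwhm_vox, config.grid_shape)
        data += noise

    if config.global_fluct_sd > 0:
        data[brain] += rng.normal(0.0, config.global_fluct_sd, size=T)

    data[brain] += config.baseline_mean + config.drift_slope * t_idx

    for roi in config.roi_effects:
        amp = roi.amplitude_patient if group == "patient" else roi.amplitude_control
        if amp == 0:
            continue
        lo, hi = roi.band_hz
        freqs = rng.uniform(lo, hi, size=roi.n_components)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=roi.n_components)
        raw = np.sum(np.sin(2.0 * np.pi * freqs[:, None] * t_s[None, :]
                            + phases[:, None]), axis=0)
        if roi.n_components == 1:
            signal = amp * raw
        else:
            rms = np.sqrt(np.mean(raw ** 2))
            signal = amp / np.sqrt(2.0) * raw / max(rms, 1e-12)
        grid = np.indices(config.grid_shape).astype(float)
        c = np.asarray(roi.center_vox, dtype=float)
        inside = sum((grid[a] - c[a]) ** 2 for a in range(3)) <= roi.radius_vox ** 2
        # Amplitude effects are cortical: the WM/CSF cores are kept clean so
        # that tissue-mean nuisance regressors cannot absorb the effect.
        data[inside & cortex] += signal

    data[~brain] = rng.normal(0.0, max(config.noise_sd, 1e-3) * 0.1,
                              size=((~brain).sum(), T))

    # Rigid-motion random walk: translations in mm, rotations in rad
    # (rotation steps two orders of magnitude smaller than translations).
    steps = rng.normal(0.0, config.motion_sd, size=(T, 6))
    steps[:, 3:] *= 0.01
    motion = np.cumsum(steps, axis=0)
    motion[0] = 0.0

    bold = BoldSeries(data=data, tr_s=config.tr_s, mask=brain,
                      subject_id=subject_id,
                      history=[f"simulated(seed={subject_seed},group={group})"])
    return bold, motion


@dataclass
class CohortManifest:
    """Index of one generated cohort: file paths, labels and seeds."""

    subjects: list[dict]
    ground_truth_path: str
    brain_mask_path: str
    wm_mask_path: str
    csf_mask_path: str
    participants_path: str
    config: dict

    def to_json(self, path) -> Path:
        return io.dump_json(path, asdict(self))

    @classmethod
    def from_json(cls, path) -> "CohortManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def subject_seeds(config: SimulationConfig) -> list[int]:
    """Distinct deterministic per-subject seeds derived from the cohort seed."""
    n = config.n_patients + config.n_controls
    ss = np.random.SeedSequence(config.seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def generate_cohort(config: SimulationConfig, out_dir) -> CohortManifest:
    """Write a full cohort (NIfTI volumes, motion TSVs, participants table,
    ground-truth labels, tissue masks and a manifest) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = io.centered_affine(config.grid_shape, config.voxel_size_mm)
    brain, wm, csf = brain_masks(config)

    seeds = subject_seeds(config)
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    labels = {"patient": "MHE", "control": "HC"}
    subjects = []
    ids = []
    for i, (group, seed) in enumerate(zip(groups, seeds), start=1):
        sid = f"sub-{i:03d}"
        bold, motion = generate_subject(config, group, seed, subject_id=sid)
        bold_path = out_dir / f"{sid}_bold.nii.gz"
        io.save_nifti(bold_path, bold.data, affine, tr_s=config.tr_s,
                      description=f"synthetic BOLD {labels[group]}")
        motion_path = out_dir / f"{sid}_motion.tsv"
        io.save_motion_tsv(motion_path, motion)
        subjects.append({"subject_id": sid, "group": labels[group],
                         "seed": seed, "bold_path": str(bold_path),
                         "motion_path": str(motion_path)})
        ids.append(sid)

    gt_path = io.save_nifti(out_dir / "ground_truth_rois.nii.gz",
                            ground_truth_mask(config), affine)
    brain_path = io.save_nifti(out_dir / "brain_mask.nii.gz", brain.astype(np.uint8), affine)
    wm_path = io.save_nifti(out_dir / "wm_mask.nii.gz", wm.astype(np.uint8), affine)
    csf_path = io.save_nifti(out_dir / "csf_mask.nii.gz", csf.astype(np.uint8), affine)
    part_path = io.save_participants_tsv(out_dir / "participants.tsv", ids,
                                         [labels[g] for g in groups])
    manifest = CohortManifest(
        subjects=subjects,
        ground_truth_path=str(gt_path),
        brain_mask_path=str(brain_path),
        wm_mask_path=str(wm_path),
        csf_mask_path=str(csf_path),
        participants_path=str(part_path),
        config=config.to_dict(),
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
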