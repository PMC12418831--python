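"""End-to-end orchestration: simulate -> preprocess -> metrics -> group
inference -> classification, with on-disk stage outputs and a provenance
record so runs are resumable and reproducible.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .containers import BoldSeries, MetricMap
from .classify import (PerFoldScreeningSource, SvmSettings,
                       classification_report, outer_loocv, roc_points)
from .inference import (GroupDesign, estimate_smoothness, fit_group_glm,
                        threshold_and_cluster)
from .metrics import (SpectrumSettings, alff, falff, peraf, reho,
                      standardize_mean_divide, standardize_z)
from .preprocess import (bandpass, build_confounds, detrend_linear,
                         discard_initial, fd_jenkinson, regress_nuisance,
                         screen_motion, smooth_gaussian)
from .simulate import CohortManifest, SimulationConfig, generate_cohort, file_checksum

logger = logging.getLogger(__name__)

ALL_METRICS = ("ALFF", "fALFF", "PerAF", "ReHo")

# Which global standardization precedes group analysis for each metric:
# z for the spectral amplitudes, mean-division for PerAF and ReHo.
DEFAULT_STANDARDIZATION = {"ALFF": "z", "fALFF": "z",
                           "PerAF": "mean_divided", "ReHo": "mean_divided"}


@dataclass
class RunConfig:
    """Everything a full run needs; mirrors the CLI flags and YAML config."""

    out_dir: str = "restmetrics_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: str | None = None  # use an existing cohort instead of simulating
    discard_volumes: int = 10
    band_lo_hz: float = 0.01
    band_hi_hz: float = 0.08
    smooth_fwhm_mm: float = 6.0
    smooth_series_before_metrics: bool = False
    metrics: tuple[str, ...] = ALL_METRICS
    standardization: dict = field(default_factory=lambda: dict(DEFAULT_STANDARDIZATION))
    voxel_p: float = 0.01
    cluster_p: float = 0.01
    min_extent: int = 100
    connectivity: int = 26
    svm: SvmSettings = field(default_factory=SvmSettings)
    screening: str = "per_fold_rois"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.voxel_p < 1 and 0 < self.cluster_p < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        bad = [m for m in self.metrics if m not in ALL_METRICS]
        if bad or not self.metrics:
            raise ValueError(f"metrics must be a non-empty subset of {ALL_METRICS}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metrics"] = list(self.metrics)
        d["svm"]["c_grid"] = list(self.svm.c_grid)
        d["svm"]["g_grid"] = list(self.svm.g_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "svm" in d and isinstance(d["svm"], dict):
            svm = dict(d["svm"])
            for k in ("c_grid", "g_grid"):
                if k in svm:
                    svm[k] = tuple(svm[k])
            d["svm"] = SvmSettings(**svm)
        if "metrics" in d:
            d["metrics"] = tuple(d["metrics"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def run_simulate(config: RunConfig) -> CohortManifest:
    out = Path(config.out_dir) / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    return generate_cohort(config.simulation, out)


def _load_cohort(cohort_dir) -> tuple[CohortManifest, dict]:
    cohort_dir = Path(cohort_dir)
    manifest = CohortManifest.from_json(cohort_dir / "manifest.json")
    brain, _, _ = io.load_nifti(manifest.brain_mask_path)
    wm, _, _ = io.load_nifti(manifest.wm_mask_path)
    csf, _, _ = io.load_nifti(manifest.csf_mask_path)
    masks = {"brain": brain.astype(bool), "wm": wm.astype(bool), "csf": csf.astype(bool)}
    return manifest, masks


def preprocess_subject(bold: BoldSeries, motion: np.ndarray, masks: dict,
                       config: RunConfig) -> dict:
    """Run the temporal chain for one subject.

    Returns the cleaned unfiltered series (spectral metrics branch), the
    band-passed series (regional-homogeneity branch) and the mean framewise
    displacement used later as a group-level covariate.
    """
    k = config.discard_volumes
    bold = discard_initial(bold, k)
    motion_k = motion[k:]
    bold = detrend_linear(bold)
    confounds = build_confounds(motion_k, bold, masks["wm"], masks["csf"], masks["brain"])
    clean = regress_nuisance(bold, confounds)
    filtered = bandpass(clean, config.band_lo_hz, config.band_hi_hz)
    _, mean_fd = fd_jenkinson(motion_k)
    return {"clean": clean, "bandpassed": filtered, "mean_fd": mean_fd,
            "motion_screen": screen_motion(motion), "confounds": confounds}


def compute_metric_maps(pre: dict, config: RunConfig,
                        voxel_size_mm: float) -> dict[str, MetricMap]:
    """All requested metric maps for one preprocessed subject, standardized
    and then smoothed (map smoothing, the pipeline default)."""
    spectrum = SpectrumSettings(config.band_lo_hz, config.band_hi_hz)
    clean, bp = pre["clean"], pre["bandpassed"]
    if config.smooth_series_before_metrics:
        clean = _smooth_series(clean, config, voxel_size_mm)
        bp = _smooth_series(bp, config, voxel_size_mm)
    producers = {
        "ALFF": lambda: alff(clean, spectrum),
        "fALFF": lambda: falff(clean, spectrum),
        "PerAF": lambda: peraf(clean),
        "ReHo": lambda: reho(bp),
    }
    out = {}
    for metric in config.metrics:
        m = producers[metric]()
        std = config.standardization.get(metric, DEFAULT_STANDARDIZATION[metric])
        m = standardize_z(m) if std == "z" else standardize_mean_divide(m)
        if not config.smooth_series_before_metrics and config.smooth_fwhm_mm > 0:
            m = m.with_values(smooth_gaussian(m.values, m.mask, config.smooth_fwhm_mm,
                                              voxel_size_mm))
        out[metric] = m
    return out


def _smooth_series(bold: BoldSeries, config: RunConfig, voxel_size_mm: float) -> BoldSeries:
    data = np.stack([smooth_gaussian(bold.data[..., t], bold.mask,
                                     config.smooth_fwhm_mm, voxel_size_mm)
                     for t in range(bold.n_volumes)], axis=3)
    return bold.with_data(data, f"smooth_series({config.smooth_fwhm_mm}mm)")


def _cohort_maps(manifest: CohortManifest, masks: dict,
                 config: RunConfig) -> tuple[dict, GroupDesign, np.ndarray]:
    """Preprocess every subject and compute its metric maps."""
    voxel_size = manifest.config["voxel_size_mm"]
    maps_by_metric: dict[str, list[MetricMap]] = {m: [] for m in config.metrics}
    mean_fds, ids, groups = [], [], []
    affine = None
    for entry in manifest.subjects:
        t0 = time.time()
        data, affine, tr = io.load_nifti(entry["bold_path"])
        motion = io.load_motion_tsv(entry["motion_path"])
        bold = BoldSeries(data=data, tr_s=tr, mask=masks["brain"],
                          subject_id=entry["subject_id"])
        pre = preprocess_subject(bold, motion, masks, config)
        maps = compute_metric_maps(pre, config, voxel_size)
        for metric in config.metrics:
            maps_by_metric[metric].append(maps[metric])
        mean_fds.append(pre["mean_fd"])
        ids.append(entry["subject_id"])
        groups.append(entry["group"])
        logger.info("stage=metrics subject=%s wall=%.2fs", entry["subject_id"],
                    time.time() - t0)
    design = GroupDesign(subject_ids=ids, groups=groups,
                         covariates=pd.DataFrame({"mean_fd": mean_fds}))
    return maps_by_metric, design, affine


def _classify_metric(maps_by_metric: dict, metrics, design: GroupDesign,
                     config: RunConfig, seed: int) -> dict:
    source = PerFoldScreeningSource(
        {m: maps_by_metric[m] for m in metrics}, design,
        voxel_p=config.voxel_p, cluster_p=config.cluster_p,
        min_extent=config.min_extent, connectivity=config.connectivity)
    preds = outer_loocv(source, design, config.svm, screening=config.screening,
                        seed=seed)
    report = classification_report(preds["predicted"], preds["decision_value"],
                                   preds["true"], patient_label=design.patient_label)
    roc = roc_points(preds["decision_value"], preds["true"],
                     patient_label=design.patient_label)
    return {"predictions": preds, "report": report, "roc": roc}


def run_full(config: RunConfig) -> dict:
    """Execute every stage and write the results bundle under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.input_dir is not None:
        manifest, masks = _load_cohort(config.input_dir)
    else:
        manifest = run_simulate(config)
        _, masks = _load_cohort(Path(config.out_dir) / "cohort")

    maps_by_metric, design, affine = _cohort_maps(manifest, masks, config)

    cluster_files = {}
    for metric in config.metrics:
        result = fit_group_glm(maps_by_metric[metric], design)
        sm = estimate_smoothness(result)
        ct = threshold_and_cluster(result, voxel_p=config.voxel_p,
                                   cluster_p=config.cluster_p,
                                   min_extent=config.min_extent,
                                   connectivity=config.connectivity,
                                   smoothness=sm, affine=affine)
        csv_path = out / f"{metric}_clusters.csv"
        ct.table.to_csv(csv_path, index=False)
        io.save_nifti(out / f"{metric}_tmap.nii.gz", result.t_map, affine,
                      description=f"{metric} group t map")
        io.save_nifti(out / f"{metric}_clusters.nii.gz", ct.labels, affine,
                      description=f"{metric} cluster labels")
        cluster_files[metric] = str(csv_path)
        logger.info("stage=group metric=%s clusters=%d fwhm=%s", metric, len(ct),
                    np.round(sm.fwhm_vox, 2))

    reports = {}
    report_dir = out / "reports"
    report_dir.mkdir(exist_ok=True)
    for name, metric_set in [(m, (m,)) for m in config.metrics] + [("Total", config.metrics)]:
        res = _classify_metric(maps_by_metric, metric_set, design, config, config.seed)
        payload = res["report"].to_dict()
        payload["per_fold_hyperparameters"] = res["predictions"][
            ["subject_id", "inner_c", "inner_g"]].to_dict(orient="records")
        io.dump_json(report_dir / f"{name}_report.json", payload)
        res["roc"].to_csv(report_dir / f"{name}_roc.csv", index=False)
        reports[name] = res
        logger.info("stage=classify model=%s accuracy=%.2f auc=%.3f", name,
                    res["report"].accuracy, res["report"].auc)

    provenance = {
        "software": {"name": "restmetrics", "version": __version__},
        "config": config.to_dict(),
        "stage_checksums": {
            f"reports/{name}_report.json": file_checksum(report_dir / f"{name}_report.json")
            for name in reports
        },
    }
    io.dump_json(out / "provenance.json", provenance)
    return {"manifest": manifest, "design": design, "maps": maps_by_metric,
            "cluster_files": cluster_files, "reports": reports,
            "provenance_path": str(out / "provenance.json")}


def stage_preprocess(cohort_dir, out_dir, config: RunConfig) -> Path:
    """Write each subject's cleaned (unfiltered) and band-passed series plus
    a confound/FD audit table; resumable input for ``stage_metrics``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest, masks = _load_cohort(cohort_dir)
    rows = []
    for entry in manifest.subjects:
        data, affine, tr = io.load_nifti(entry["bold_path"])
        motion = io.load_motion_tsv(entry["motion_path"])
        bold = BoldSeries(data=data, tr_s=tr, mask=masks["brain"],
                          subject_id=entry["subject_id"])
        pre = preprocess_subject(bold, motion, masks, config)
        sid = entry["subject_id"]
        io.save_nifti(out / f"{sid}_desc-clean_bold.nii.gz", pre["clean"].data,
                      affine, tr_s=tr, description="cleaned unfiltered")
        io.save_nifti(out / f"{sid}_desc-bandpassed_bold.nii.gz",
                      pre["bandpassed"].data, affine, tr_s=tr,
                      description="cleaned band-passed")
        pre["confounds"].to_csv(out / f"{sid}_confounds.tsv", sep="\t", index=False)
        rows.append({"subject_id": sid, "group": entry["group"],
                     "mean_fd": pre["mean_fd"],
                     "motion_flagged": pre["motion_screen"]["flagged"]})
    pd.DataFrame(rows).to_csv(out / "subjects.tsv", sep="\t", index=False)
    return out


def stage_metrics(cohort_dir, out_dir, config: RunConfig) -> Path:
    """Compute, standardize and smooth every subject's metric maps; write
    them as NIfTI with JSON sidecars plus a manifest for later stages."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest, masks = _load_cohort(cohort_dir)
    maps_by_metric, design, affine = _cohort_maps(manifest, masks, config)
    subjects = []
    for i, sid in enumerate(design.subject_ids):
        paths = {}
        for metric in config.metrics:
            m = maps_by_metric[metric][i]
            path = out / f"{sid}_{metric}.nii.gz"
            io.save_nifti(path, m.values, affine,
                          description=f"{metric} {m.standardization}")
            io.dump_json(path.with_suffix("").with_suffix(".json"), {
                "metric": m.metric, "standardization": m.standardization,
                "band_hz": m.band_hz, "subject_id": sid})
            paths[metric] = str(path)
        subjects.append({"subject_id": sid, "group": design.groups[i],
                         "mean_fd": float(design.covariates["mean_fd"][i]),
                         "maps": paths})
    io.dump_json(out / "metrics_manifest.json", {
        "subjects": subjects, "metrics": list(config.metrics),
        "brain_mask_path": manifest.brain_mask_path,
        "voxel_size_mm": manifest.config["voxel_size_mm"]})
    return out


def _load_metric_maps(metrics_dir):
    import json

    metrics_dir = Path(metrics_dir)
    with open(metrics_dir / "metrics_manifest.json") as fh:
        manifest = json.load(fh)
    mask, _, _ = io.load_nifti(manifest["brain_mask_path"])
    mask = mask.astype(bool)
    maps_by_metric: dict[str, list[MetricMap]] = {m: [] for m in manifest["metrics"]}
    affine = None
    for entry in manifest["subjects"]:
        for metric in manifest["metrics"]:
            values, affine, _ = io.load_nifti(entry["maps"][metric])
            maps_by_metric[metric].append(MetricMap(
                values=values, metric=metric, mask=mask,
                subject_id=entry["subject_id"]))
    design = GroupDesign(
        subject_ids=[e["subject_id"] for e in manifest["subjects"]],
        groups=[e["group"] for e in manifest["subjects"]],
        covariates=pd.DataFrame(
            {"mean_fd": [e["mean_fd"] for e in manifest["subjects"]]}))
    return maps_by_metric, design, affine


def stage_group(metrics_dir, out_dir, config: RunConfig) -> dict:
    """Group GLM + GRF cluster inference from on-disk metric maps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maps_by_metric, design, affine = _load_metric_maps(metrics_dir)
    cluster_files = {}
    for metric, maps in maps_by_metric.items():
        result = fit_group_glm(maps, design)
        ct = threshold_and_cluster(result, voxel_p=config.voxel_p,
                                   cluster_p=config.cluster_p,
                                   min_extent=config.min_extent,
                                   connectivity=config.connectivity,
                                   smoothness=estimate_smoothness(result),
                                   affine=affine)
        csv_path = out / f"{metric}_clusters.csv"
        ct.table.to_csv(csv_path, index=False)
        io.save_nifti(out / f"{metric}_clusters.nii.gz", ct.labels, affine)
        cluster_files[metric] = str(csv_path)
    return cluster_files


def stage_classify(metrics_dir, out_dir, config: RunConfig) -> dict:
    """Nested LOO SVM classification from on-disk metric maps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maps_by_metric, design, _ = _load_metric_maps(metrics_dir)
    metrics = tuple(maps_by_metric)
    reports = {}
    for name, metric_set in [(m, (m,)) for m in metrics] + [("Total", metrics)]:
        res = _classify_metric(maps_by_metric, metric_set, design, config, config.seed)
        io.dump_json(out / f"{name}_report.json", res["report"].to_dict())
        res["roc"].to_csv(out / f"{name}_roc.csv", index=False)
        reports[name] = res
    return reports


def run_from_provenance(provenance_path, out_dir) -> dict:
    """Re-run the full pipeline from a provenance record."""
    import json

    with open(provenance_path) as fh:
        prov = json.load(fh)
    config = RunConfig.from_dict(prov["config"])
    config.out_dir = str(out_dir)
    config.input_dir = None  # resimulate from the recorded seed
    return run_full(config)


def validate_inputs(cohort_dir) -> dict:
    """Header/shape/label sanity checks plus the 3 mm / 3 degree motion flag.

    Problems are listed, never fatal; flagged subjects are reported, not
    deleted.
    """
    cohort_dir = Path(cohort_dir)
    report = {"errors": [], "warnings": [], "flagged_subjects": [], "n_subjects": 0}
    manifest_path = cohort_dir / "manifest.json"
    if not manifest_path.exists():
        report["errors"].append(f"missing manifest.json in {cohort_dir}")
        return report
    manifest = CohortManifest.from_json(manifest_path)
    report["n_subjects"] = len(manifest.subjects)
    grids = set()
    participants = io.load_participants_tsv(manifest.participants_path)
    bad_labels = sorted(set(participants["group"]) - {"MHE", "HC"})
    if bad_labels:
        report["errors"].append(f"unexpected group labels: {bad_labels}")
    for entry in manifest.subjects:
        sid = entry["subject_id"]
        try:
            data, _, tr = io.load_nifti(entry["bold_path"])
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            report["errors"].append(f"{sid}: cannot read BOLD ({exc})")
            continue
        grids.add(data.shape[:3])
        if tr is None or not tr > 0:
            report["errors"].append(f"{sid}: repetition time missing from header")
        try:
            motion = io.load_motion_tsv(entry["motion_path"])
        except Exception as exc:  # noqa: BLE001
            report["errors"].append(f"{sid}: cannot read motion TSV ({exc})")
            continue
        if motion.shape[0] != data.shape[3]:
            report["errors"].append(
                f"{sid}: motion rows ({motion.shape[0]}) != volumes ({data.shape[3]})")
        screen = screen_motion(motion)
        if screen["flagged"]:
            report["flagged_subjects"].append({"subject_id": sid, **screen})
    if len(grids) > 1:
        report["errors"].append(f"inconsistent grids across subjects: {sorted(grids)}")
    return report
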