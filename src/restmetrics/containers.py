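"""In-memory containers shared across the pipeline.

A :class:`BoldSeries` holds one subject's 4D BOLD time series together with
its grid geometry, repetition time and analysis mask; a :class:`MetricMap`
holds one 3D scalar map derived from it (ALFF, fALFF, PerAF or ReHo) and
remembers which standardization, if any, has been applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

METRICS = ("ALFF", "fALFF", "PerAF", "ReHo")
STANDARDIZATIONS = ("raw", "z", "mean_divided")


@dataclass
class BoldSeries:
    """One subject's 4D BOLD series (x, y, z, t) on a fixed grid.

    Parameters
    ----------
    data:
        4D array, spatial axes first, time last. Signal units are arbitrary
        but must have a positive baseline for PerAF's mean-division to be
        well defined downstream.
    tr_s:
        Repetition time in seconds.
    mask:
        3D boolean analysis mask on the same grid.
    subject_id:
        Free-form identifier carried into outputs.
    history:
        Names of processing steps applied so far, in order.
    """

    data: np.ndarray
    tr_s: float
    mask: np.ndarray
    subject_id: str = ""
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x,y,z,t), got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 timepoints")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match grid {self.data.shape[:3]}"
            )
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    def in_mask(self) -> np.ndarray:
        """Return the in-mask series as a (t, n_voxels) array (a view-copy)."""
        return self.data[self.mask].T

    def with_data(self, data: np.ndarray, step: str) -> "BoldSeries":
        """Return a copy carrying ``data`` and ``step`` appended to history."""
        return replace(self, data=np.asarray(data, dtype=float),
                       history=[*self.history, step])


@dataclass
class MetricMap:
    """One 3D scalar metric map for one subject."""

    values: np.ndarray
    metric: str
    mask: np.ndarray
    standardization: str = "raw"
    band_hz: tuple[float, float] | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("metric map must be 3D")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match map shape")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if self.standardization not in STANDARDIZATIONS:
            raise ValueError(f"unknown standardization {self.standardization!r}")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("metric map contains non-finite values inside the mask")

    def with_values(self, values: np.ndarray, standardization: str | None = None) -> "MetricMap":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            standardization=self.standardization if standardization is None else standardization,
        )
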