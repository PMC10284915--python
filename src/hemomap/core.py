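"""Core in-memory containers for volumetric hemodynamic data.

The package works on a small set of containers shared by every stage of the
pipeline: a 4D BOLD series, 3D scalar maps (coefficient maps, CVR/BAT maps,
masks, atlases), a rigid-body motion trace, and a timestamped end-tidal CO2
trace.  They are thin dataclasses around NumPy arrays plus the grid metadata
needed to write valid NIfTI files and to convert physical units (mm, s) to
grid units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.interpolate import CubicSpline


class ConfigurationError(ValueError):
    """Raised when a request is inconsistent with the data or configuration."""


@dataclass
class VolumeMap:
    """A 3D scalar field on a regular voxel grid.

    ``units`` is a free-form tag; the pipeline uses ``raw``, ``zscore``,
    ``%/mmHg``, ``s`` and ``label``.  ``meta`` carries provenance (padding
    bookkeeping, seeds, clip reports) and is preserved through I/O sidecars.
    """

    values: np.ndarray
    units: str = "raw"
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ConfigurationError(
                f"VolumeMap requires a 3D array, got shape {self.values.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, units: str | None = None) -> "VolumeMap":
        return replace(self, values=np.asarray(values), units=units or self.units,
                       meta=dict(self.meta))


@dataclass
class BoldSeries:
    """A 4D BOLD series: spatial grid X*Y*Z sampled every ``tr`` seconds."""

    values: np.ndarray
    tr: float
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ConfigurationError(
                f"BoldSeries requires a 4D array, got shape {self.values.shape}"
            )
        if self.tr <= 0:
            raise ConfigurationError(f"tr must be positive, got {self.tr}")
        if self.n_timepoints < 2:
            raise ConfigurationError("BoldSeries needs at least 2 timepoints")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]  # type: ignore[return-value]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each frame, seconds from scan start."""
        return np.arange(self.n_timepoints) * self.tr

    def with_values(self, values: np.ndarray) -> "BoldSeries":
        return replace(self, values=np.asarray(values), meta=dict(self.meta))


@dataclass
class MotionTrace:
    """Six rigid-body parameters per frame (3 translations mm, 3 rotations rad)."""

    values: np.ndarray  # (T, 6)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != 6:
            raise ConfigurationError(
                f"MotionTrace requires 6 columns, got {self.values.shape[1]}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


@dataclass
class EtCo2Trace:
    """Timestamped end-tidal CO2 partial-pressure trace in mmHg.

    ``baseline`` is the room-air baseline bEtCO2.  ``baseline_mask`` marks
    samples belonging to designated room-air blocks (the simulator fills it
    for hypercapnic runs); when present, :meth:`estimate_baseline` averages
    over those samples.
    """

    timestamps: np.ndarray
    values: np.ndarray
    baseline: float = 40.0
    baseline_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ConfigurationError("timestamps and values must have equal length")
        if self.timestamps.size >= 2 and np.any(np.diff(self.timestamps) <= 0):
            raise ConfigurationError("EtCO2 timestamps must be strictly increasing")

    def interpolator(self) -> CubicSpline:
        """Natural cubic spline through the samples (for sub-TR evaluation)."""
        return CubicSpline(self.timestamps, self.values, bc_type="natural")

    def resample(self, times: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(times, dtype=float),
                    self.timestamps[0], self.timestamps[-1])
        return self.interpolator()(t)

    def estimate_baseline(self) -> float:
        if self.baseline_mask is not None and np.any(self.baseline_mask):
            return float(np.mean(self.values[np.asarray(self.baseline_mask, bool)]))
        return float(self.baseline)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


def as_mask(arr: np.ndarray | VolumeMap) -> np.ndarray:
    """Coerce a mask-like input (VolumeMap or array) to a 3D boolean array."""
    values = arr.values if isinstance(arr, VolumeMap) else np.asarray(arr)
    return values.astype(bool)
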