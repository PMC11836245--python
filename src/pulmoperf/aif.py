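"""Arterial input function extraction, bolus tracking, and frame timing.

The input function is read from a cylindrical volume-of-interest placed in
the pulmonary artery trunk. Bolus tracking fires when enhancement first
exceeds a threshold (80 HU above the baseline blood pool by default), and
the time-to-peak delay Δt that places the second volume scan near peak
arterial enhancement is predicted from the injection protocol as half the
contrast injection time plus a dispersion delay. For a full dynamic series
the base and peak frames of the enhancement curve are selected directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import (
    BaseNotFoundError,
    DataError,
    GeometryError,
    NoTriggerError,
    ParameterError,
    SignalError,
)
from .perfusion import VolumeScan

__all__ = [
    "ArterialVOI",
    "AIFCurve",
    "InjectionProtocol",
    "extract_aif",
    "bolus_track",
    "predict_time_to_peak",
    "select_base_peak",
]


@dataclass(frozen=True)
class ArterialVOI:
    """Cylindrical volume-of-interest, in physical (mm) coordinates.

    Voxel centers are at ``index * spacing`` (0-based, voxel-centered grid).
    """

    center: Tuple[float, float, float]  # mm
    axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    radius: float = 5.0  # mm
    half_length: float = 10.0  # mm

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.half_length <= 0:
            raise ParameterError("VOI radius and half_length must be positive")
        ax = np.asarray(self.axis, dtype=float)
        n = float(np.linalg.norm(ax))
        if n == 0:
            raise ParameterError("VOI axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(ax / n))

    def mask(self, shape: Sequence[int], spacing: Sequence[float]) -> np.ndarray:
        """Boolean voxel mask of the cylinder on the given grid."""
        grids = np.meshgrid(
            *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
        )
        rel = [g - c for g, c in zip(grids, self.center)]
        ax = np.asarray(self.axis)
        axial = sum(r * a for r, a in zip(rel, ax))
        rad2 = sum((r - axial * a) ** 2 for r, a in zip(rel, ax))
        return (np.abs(axial) <= self.half_length) & (rad2 <= self.radius**2)


@dataclass
class AIFCurve:
    """Arterial enhancement (HU above frame-0 baseline) versus time."""

    times: np.ndarray  # s
    enhancement: np.ndarray  # HU
    baseline_hu: float = 0.0
    trigger_index: Optional[int] = None
    base_index: Optional[int] = None
    peak_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.enhancement = np.asarray(self.enhancement, dtype=np.float64)
        if self.times.shape != self.enhancement.shape or self.times.ndim != 1:
            raise DataError("times and enhancement must be 1D of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        if (
            self.base_index is not None
            and self.peak_index is not None
            and not self.base_index < self.peak_index
        ):
            raise DataError("base_index must precede peak_index")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class InjectionProtocol:
    """Weight-adjusted contrast injection protocol.

    The injection time is T_inj = contrast_volume_per_kg × weight / rate.
    ``dispersion_delay`` is the extra transit/dispersion time from injection
    site to the pulmonary artery; the 2.0 s default is a configurable
    placeholder calibrated elsewhere, not a value measured here.
    """

    contrast_volume_per_kg: float = 0.5  # mL/kg
    rate: float = 5.0  # mL/s
    weight: float = 53.6  # kg
    dispersion_delay: float = 2.0  # s

    def __post_init__(self) -> None:
        if min(self.contrast_volume_per_kg, self.rate, self.weight) <= 0:
            raise ParameterError("injection protocol values must be positive")
        if self.dispersion_delay < 0:
            raise ParameterError("dispersion_delay must be non-negative")

    @property
    def injection_time(self) -> float:
        """T_inj in seconds."""
        return self.contrast_volume_per_kg * self.weight / self.rate


def extract_aif(series: Sequence[VolumeScan], voi: ArterialVOI) -> AIFCurve:
    """Mean-HU enhancement curve inside the arterial VOI, frame 0 as baseline."""
    if len(series) < 2:
        raise DataError("need at least 2 frames to extract an input function")
    mask = voi.mask(series[0].hu.shape, series[0].spacing)
    if not mask.any():
        raise GeometryError("arterial VOI covers zero voxels on this grid")
    means = np.array([float(v.hu[mask].mean()) for v in series])
    times = np.array([v.time for v in series], dtype=np.float64)
    return AIFCurve(
        times=times, enhancement=means - means[0], baseline_hu=float(means[0])
    )


def bolus_track(curve: AIFCurve, threshold: float = 80.0) -> float:
    """Earliest time at which enhancement reaches ``threshold`` HU above baseline.

    Emulates scanner bolus tracking on the sampled curve; records
    ``curve.trigger_index``. Raises :class:`NoTriggerError` if the threshold
    is never reached (a failed injection or mis-placed tracking ROI).
    """
    if len(curve) == 0:
        raise DataError("empty enhancement curve")
    hits = np.flatnonzero(curve.enhancement >= threshold)
    if hits.size == 0:
        raise NoTriggerError(
            f"enhancement never reached {threshold} HU above baseline"
        )
    curve.trigger_index = int(hits[0])
    return float(curve.times[curve.trigger_index])


def predict_time_to_peak(protocol: InjectionProtocol) -> float:
    """Predicted base-to-peak delay Δt = T_inj / 2 + dispersion_delay, seconds."""
    return protocol.injection_time / 2.0 + protocol.dispersion_delay


def select_base_peak(
    curve: AIFCurve, base_fraction: float = 0.05
) -> Tuple[int, int, float]:
    """Base and peak frames of the enhancement curve, and their separation Δt.

    The peak is the earliest argmax of enhancement; the base is the last
    pre-peak frame whose enhancement is at most ``base_fraction`` of the
    peak value ("approximately the base" made deterministic). Records the
    indices on the curve and returns (base_index, peak_index, Δt in s).
    """
    if len(curve) < 3:
        raise DataError("need at least 3 frames to select base and peak")
    enh = curve.enhancement
    peak = int(np.argmax(enh))  # argmax takes the earliest on ties
    if enh[peak] <= 0:
        raise SignalError("maximum enhancement is not positive")
    pre = np.flatnonzero(enh[:peak] <= base_fraction * enh[peak])
    if pre.size == 0:
        raise BaseNotFoundError(
            f"no pre-peak frame at or below {base_fraction:.0%} of peak enhancement"
        )
    base = int(pre[-1])
    curve.base_index, curve.peak_index = base, peak
    return base, peak, float(curve.times[peak] - curve.times[base])
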