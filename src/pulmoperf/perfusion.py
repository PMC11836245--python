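"""First-pass whole-lung compartment perfusion model.

The lung is treated as one lumped compartment. Before contrast begins to
leave it (the first circulatory pass), the average perfusion in mL/min/g is

    P = ΔM_c / (M_T · C_in · Δt)

where ΔM_c is the integrated contrast enhancement change over the compartment
(HU·mL), M_T the lung tissue mass (g), C_in the average arterial input
enhancement over the accumulation window (HU), and Δt the base-to-peak
accumulation time (minutes inside the equation; seconds at every interface).
Because CT enhancement is linear in iodine concentration at fixed tube
voltage, the HU scale cancels between ΔM_c and C_in and the result is an
absolute flow per tissue mass.

Voxel masses come from the tissue–air fraction: a voxel at ``hu`` holds
``(hu - hu_air)/(hu_reference - hu_air)`` of tissue-equivalent material, so
its mass is that fraction times the voxel volume times the reference density.
Dividing each voxel's enhancement change by its own mass yields a voxel-wise
flow map whose mass-weighted mean is, identically, the global value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .errors import DataError, DegenerateInputError, ParameterError, SignalError

__all__ = [
    "VolumeScan",
    "MassModel",
    "PerfusionInputs",
    "FlowMap",
    "PerfusionResult",
    "LOBE_NAMES",
    "tissue_fraction_map",
    "voxel_mass_map",
    "contrast_mass_change",
    "mean_input_concentration",
    "compute_perfusion",
    "regional_perfusion",
    "align_by_shift",
]

#: Canonical six-lobe labelling used throughout (swine lung: the right lung
#: carries upper, middle, lower and accessory lobes).
LOBE_NAMES: Dict[int, str] = {
    1: "right_upper_lobe",
    2: "right_middle_lobe",
    3: "right_lower_lobe",
    4: "accessory_lobe",
    5: "left_upper_lobe",
    6: "left_lower_lobe",
}


@dataclass
class VolumeScan:
    """One 3D HU volume with voxel spacing (mm) and acquisition metadata."""

    hu: np.ndarray
    spacing: Tuple[float, float, float]
    time: float = 0.0  # acquisition time, s
    tube_current: float = float("nan")  # mA, metadata only

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float64)
        if self.hu.ndim != 3:
            raise DataError(f"volume must be 3D, got shape {self.hu.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.hu)):
            raise DataError("volume contains non-finite HU values")

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in mL (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class MassModel:
    """HU→tissue-fraction→mass calibration.

    Air is anchored at -1000 HU and full tissue at the water value 0 HU with
    density 1.0 g/mL; both anchors are configurable (soft tissue ~55 HU is a
    defensible alternative full-tissue anchor). Voxels whose fraction falls
    below ``min_tissue_fraction`` are excluded from the flow map and from the
    compartment mass to avoid division blow-up in near-air voxels.
    """

    hu_air: float = -1000.0
    hu_reference: float = 0.0
    density_reference: float = 1.0  # g/mL
    min_tissue_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.hu_reference <= self.hu_air:
            raise ParameterError("hu_reference must exceed hu_air")
        if self.density_reference <= 0:
            raise ParameterError("density_reference must be positive")
        if not (0.0 < self.min_tissue_fraction < 1.0):
            raise ParameterError("min_tissue_fraction must lie in (0, 1)")


@dataclass
class PerfusionInputs:
    """Everything the compartment equation needs for one measurement.

    ``delta_t_s`` is the base-to-peak accumulation window in seconds; the
    conversion to minutes happens once, inside :func:`compute_perfusion`.
    """

    v1: VolumeScan
    v2: VolumeScan
    lung_mask: np.ndarray
    c_in: float  # HU
    delta_t_s: float  # s
    mass_model: MassModel = field(default_factory=MassModel)

    def __post_init__(self) -> None:
        self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
        if not (self.v1.hu.shape == self.v2.hu.shape == self.lung_mask.shape):
            raise DataError(
                "v1, v2 and lung_mask shapes differ: "
                f"{self.v1.hu.shape}, {self.v2.hu.shape}, {self.lung_mask.shape}"
            )
        if self.v1.spacing != self.v2.spacing:
            raise DataError("v1 and v2 voxel spacings differ")
        if not self.c_in > 0:
            raise SignalError(f"c_in must be positive, got {self.c_in}")
        if not self.delta_t_s > 0:
            raise ParameterError(f"delta_t_s must be positive, got {self.delta_t_s}")


@dataclass
class FlowMap:
    """Voxel-wise perfusion map plus the mass map it was computed under.

    ``perfusion`` is NaN outside the included voxels (lung mask minus the
    sub-threshold exclusions); negative values inside are retained, they are
    zero-mean noise and clipping them would bias the global sum.
    """

    perfusion: np.ndarray  # mL/min/g, NaN outside included voxels
    voxel_mass: np.ndarray  # g
    lung_mask: np.ndarray
    excluded_mask: np.ndarray
    global_perfusion: float  # mL/min/g
    total_mass: float  # g

    @property
    def included_mask(self) -> np.ndarray:
        return self.lung_mask & ~self.excluded_mask


@dataclass
class PerfusionResult:
    """Global and per-lobe perfusion with the Eq. inputs used to compute it."""

    global_perfusion: float  # mL/min/g
    per_lobe: Dict[int, Tuple[float, float]]  # label -> (mean mL/min/g, mass g)
    delta_t_s: float
    c_in: float  # HU
    delta_mass_c: float  # HU·mL
    total_mass: float  # g

    def to_records(self):
        """One record per lobe for tabular serialization."""
        return [
            {
                "label": lab,
                "name": LOBE_NAMES.get(lab, f"label_{lab}"),
                "mass_g": mass,
                "perfusion_ml_min_g": perf,
            }
            for lab, (perf, mass) in sorted(self.per_lobe.items())
        ]


def tissue_fraction_map(v: VolumeScan, mm: MassModel = MassModel()) -> np.ndarray:
    """Per-voxel tissue fraction from HU, linearly interpolated air→reference.

    f = (hu - hu_air) / (hu_reference - hu_air), clipped to [0, 1].
    """
    f = (v.hu - mm.hu_air) / (mm.hu_reference - mm.hu_air)
    return np.clip(f, 0.0, 1.0)


def voxel_mass_map(
    fraction: np.ndarray,
    spacing: Tuple[float, float, float],
    mm: MassModel = MassModel(),
) -> np.ndarray:
    """Voxel tissue mass in grams: fraction × voxel volume (mL) × density."""
    fraction = np.asarray(fraction, dtype=np.float64)
    if fraction.min() < 0 or fraction.max() > 1:
        raise ParameterError("tissue fraction must lie in [0, 1]")
    voxel_volume_ml = float(np.prod(spacing)) / 1000.0
    return fraction * voxel_volume_ml * mm.density_reference


def contrast_mass_change(
    v1: VolumeScan, v2: VolumeScan, lung_mask: np.ndarray
) -> float:
    """Integrated contrast enhancement change ΔM_c over the compartment, HU·mL.

    ΔM_c = Σ_mask (hu2 - hu1) × voxel_volume. Negative values (pathological
    or noisy input) are returned as-is.
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if not (v1.hu.shape == v2.hu.shape == lung_mask.shape):
        raise DataError("v1, v2 and mask shapes differ")
    if v1.spacing != v2.spacing:
        raise DataError("v1 and v2 voxel spacings differ")
    if not lung_mask.any():
        raise DataError("lung mask is empty")
    dhu = v2.hu[lung_mask] - v1.hu[lung_mask]
    return float(dhu.sum() * v1.voxel_volume_ml)


def mean_input_concentration(curve, mode: str = "multivolume") -> float:
    """Average arterial input enhancement C_in (HU) over the base→peak window.

    mode="two_volume": the two-point mean (E_base + E_peak)/2 — the estimate
    available when only a pre-contrast and a peak-enhancement volume exist.
    It is exact when the input rises linearly over the window.

    mode="multivolume": the trapezoidal area under the sampled curve between
    the base and peak frames divided by their time separation (AUC/Δt), the
    reference estimator when a full dynamic series exists. Requires
    ``curve.base_index`` and ``curve.peak_index`` to be set (see
    :func:`pulmoperf.aif.select_base_peak`).
    """
    enh = np.asarray(curve.enhancement, dtype=np.float64)
    if mode == "two_volume":
        base_i = curve.base_index if curve.base_index is not None else 0
        if curve.peak_index is not None:
            peak_e = float(enh[curve.peak_index])
        else:
            peak_e = float(enh.max())
        base_e = float(enh[base_i])
        if peak_e <= 0:
            raise SignalError("peak enhancement must be positive")
        return 0.5 * (base_e + peak_e)
    if mode == "multivolume":
        if curve.base_index is None or curve.peak_index is None:
            raise ParameterError("multivolume C_in requires base_index and peak_index")
        b, p = curve.base_index, curve.peak_index
        if float(enh[p]) <= 0:
            raise SignalError("peak enhancement must be positive")
        t = np.asarray(curve.times, dtype=np.float64)
        auc = float(np.trapezoid(enh[b : p + 1], t[b : p + 1]))
        return auc / float(t[p] - t[b])
    raise ParameterError(f"unknown C_in mode {mode!r}")


def compute_perfusion(inputs: PerfusionInputs) -> FlowMap:
    """Voxel-wise and global perfusion via the first-pass compartment equation.

    Per included voxel: p_v = ΔHU_v × voxel_volume / (C_in × Δt × m_v); the
    global value is the same equation with compartment totals, and equals the
    mass-weighted mean of the voxel map by construction. Voxels whose tissue
    fraction is below the mass model's threshold are excluded from both.
    """
    mm = inputs.mass_model
    fraction = tissue_fraction_map(inputs.v1, mm)
    mass = voxel_mass_map(fraction, inputs.v1.spacing, mm)
    excluded = inputs.lung_mask & (fraction < mm.min_tissue_fraction)
    included = inputs.lung_mask & ~excluded

    total_mass = float(mass[included].sum())
    if not total_mass > 0:
        raise DegenerateInputError("zero included tissue mass in the compartment")

    delta_t_min = inputs.delta_t_s / 60.0
    voxel_volume_ml = inputs.v1.voxel_volume_ml
    dhu = inputs.v2.hu - inputs.v1.hu

    perfusion = np.full(inputs.v1.hu.shape, np.nan)
    denom = inputs.c_in * delta_t_min
    perfusion[included] = dhu[included] * voxel_volume_ml / (denom * mass[included])

    delta_mass_c = float(dhu[included].sum() * voxel_volume_ml)
    global_perfusion = delta_mass_c / (denom * total_mass)

    return FlowMap(
        perfusion=perfusion,
        voxel_mass=mass,
        lung_mask=inputs.lung_mask,
        excluded_mask=excluded,
        global_perfusion=global_perfusion,
        total_mass=total_mass,
    )


def regional_perfusion(
    flow: FlowMap,
    lobe_labels: np.ndarray,
    *,
    delta_t_s: float = float("nan"),
    c_in: float = float("nan"),
) -> PerfusionResult:
    """Mass-weighted mean perfusion per lobe label (1–6), plus the global value.

    A lobe with zero included mass is reported as NaN with a warning rather
    than dropped, so the output always covers every label present in the map.
    """
    lobe_labels = np.asarray(lobe_labels)
    if lobe_labels.shape != flow.perfusion.shape:
        raise DataError("lobe label volume shape differs from the flow map")

    included = flow.included_mask
    per_lobe: Dict[int, Tuple[float, float]] = {}
    for lab in sorted(int(v) for v in np.unique(lobe_labels) if v != 0):
        sel = included & (lobe_labels == lab)
        lobe_mass = float(flow.voxel_mass[sel].sum())
        if lobe_mass > 0:
            mean_p = float(
                (flow.perfusion[sel] * flow.voxel_mass[sel]).sum() / lobe_mass
            )
        else:
            warnings.warn(
                f"lobe {lab} has zero included tissue mass; perfusion reported as NaN",
                stacklevel=2,
            )
            mean_p = float("nan")
        per_lobe[lab] = (mean_p, lobe_mass)

    dmc = flow.global_perfusion * flow.total_mass  # ΔM_c/(C_in·Δt), rescaled below
    delta_mass_c = float("nan")
    if np.isfinite(c_in) and np.isfinite(delta_t_s):
        delta_mass_c = dmc * c_in * (delta_t_s / 60.0)

    return PerfusionResult(
        global_perfusion=flow.global_perfusion,
        per_lobe=per_lobe,
        delta_t_s=delta_t_s,
        c_in=c_in,
        delta_mass_c=delta_mass_c,
        total_mass=flow.total_mass,
    )


def align_by_shift(
    v1: VolumeScan, v2: VolumeScan, max_shift: int = 3
) -> Tuple[VolumeScan, Tuple[int, int, int]]:
    """Integer-voxel alignment of v1 onto the fixed image v2.

    Exhaustively searches shifts within ±max_shift per axis, scoring each by
    the normalized cross-correlation over the overlapping region, and applies
    the best shift to v1 (out-of-field voxels filled with air, -1000 HU).
    This is a deliberately minimal stand-in for deformable registration and
    assumes the pair is already approximately aligned.
    """
    if v1.hu.shape != v2.hu.shape:
        raise DataError("volumes must share a shape")

    def _overlap(a: np.ndarray, b: np.ndarray, shift):
        sl_a, sl_b = [], []
        for s, n in zip(shift, a.shape):
            if s >= 0:
                sl_a.append(slice(0, n - s))
                sl_b.append(slice(s, n))
            else:
                sl_a.append(slice(-s, n))
                sl_b.append(slice(0, n + s))
        return a[tuple(sl_a)], b[tuple(sl_b)]

    best_shift, best_score = (0, 0, 0), -np.inf
    r = range(-max_shift, max_shift + 1)
    for dx in r:
        for dy in r:
            for dz in r:
                a, b = _overlap(v1.hu, v2.hu, (dx, dy, dz))
                if a.size == 0:
                    continue
                a0 = a - a.mean()
                b0 = b - b.mean()
                denom = np.sqrt((a0**2).sum() * (b0**2).sum())
                score = float((a0 * b0).sum() / denom) if denom > 0 else 0.0
                if score > best_score:
                    best_score, best_shift = score, (dx, dy, dz)

    shifted = np.full_like(v1.hu, -1000.0)
    src, dst = [], []
    for s, n in zip(best_shift, v1.hu.shape):
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    shifted[tuple(dst)] = v1.hu[tuple(src)]
    moved = VolumeScan(
        hu=shifted, spacing=v1.spacing, time=v1.time, tube_current=v1.tube_current
    )
    return moved, best_shift
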