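"""Synthetic dynamic contrast-enhanced CT phantom with known ground truth.

The phantom emulates exactly the physics the compartment model inverts:
each lung voxel accumulates contrast enhancement in proportion to its local
flow, its local tissue mass, and the cumulative arterial input,

    ΔHU_v(t) · V_voxel = p_v · m_v · ∫₀^min(t, t0+T_transit) C_a(τ) dτ,

with an optional plateau after the transit time (contrast leaving the
compartment no longer accumulates — the minimal model of a first-pass
violation). The arterial input C_a is a normalized gamma-variate (or a
linear ramp), and its cumulative integral is evaluated *analytically*, so
that any discrepancy in recovered perfusion is attributable to the
estimator's quadrature, not to the simulation.

Geometry is deliberately schematic: two axis-aligned ellipsoidal lung
fields, a cylindrical pulmonary artery between them along z, and planar
six-lobe partitions (right upper/middle/lower + accessory, left
upper/lower) — reproducible, and sufficient for every model invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import gammainc, gammaln

from .aif import AIFCurve, ArterialVOI
from .errors import ParameterError, SpecificationError
from .perfusion import MassModel, VolumeScan

__all__ = [
    "AIFParams",
    "LungGeometry",
    "PhantomSpec",
    "PhantomGroundTruth",
    "gamma_variate_aif",
    "aif_cumulative_integral",
    "build_geometry",
    "arterial_voi",
    "simulate_series",
    "phantom_spec_from_dict",
    "DEFAULT_LOBE_PERFUSION",
]

#: Default per-lobe flow (mL/min/g): healthy-swine lobar means, gravity-
#: dependent lower lobes higher than upper/middle lobes.
DEFAULT_LOBE_PERFUSION: Dict[int, float] = {
    1: 9.7,  # right upper
    2: 7.8,  # right middle
    3: 14.5,  # right lower
    4: 9.9,  # accessory
    5: 8.8,  # left upper
    6: 14.1,  # left lower
}

#: Reference tube current (mA) at which noise_sd applies unscaled.
REFERENCE_TUBE_CURRENT = 300.0


@dataclass(frozen=True)
class AIFParams:
    """Parametric arterial input function.

    The default form is the normalized gamma-variate
    ``E(t) = peak · u^α · exp(α(1-u))`` with ``u = (t-t0)/tp``, which peaks
    at exactly ``peak_enhancement`` when ``t = t0 + tp``. ``shape="linear"``
    substitutes a ramp from 0 at t0 to the peak at t0+tp (then flat), the
    case in which the two-point and area-under-curve input averages agree
    exactly.
    """

    peak_enhancement: float = 400.0  # HU above blood baseline
    t0: float = 4.0  # contrast arrival time, s
    tp: float = 6.0  # time from arrival to peak, s
    shape_alpha: float = 3.0
    baseline_hu: float = 40.0  # pre-contrast blood pool HU
    shape: str = "gamma_variate"

    def __post_init__(self) -> None:
        if self.peak_enhancement <= 0:
            raise ParameterError("peak_enhancement must be positive")
        if self.tp <= 0:
            raise ParameterError("tp must be positive")
        if self.shape_alpha <= 0:
            raise ParameterError("shape_alpha must be positive")
        if self.shape not in ("gamma_variate", "linear"):
            raise ParameterError(f"unknown AIF shape {self.shape!r}")


def gamma_variate_aif(params: AIFParams, t) -> np.ndarray:
    """Arterial enhancement (HU) at time(s) ``t``; zero for t ≤ t0.

    Normalized so the maximum equals ``peak_enhancement`` at ``t = t0 + tp``.
    """
    t = np.asarray(t, dtype=np.float64)
    u = (t - params.t0) / params.tp
    if params.shape == "linear":
        out = params.peak_enhancement * np.clip(u, 0.0, 1.0)
    else:
        a = params.shape_alpha
        with np.errstate(invalid="ignore"):
            out = np.where(
                u > 0,
                params.peak_enhancement
                * np.exp(a * np.log(np.maximum(u, 1e-300)) + a * (1.0 - u)),
                0.0,
            )
    return out if out.ndim else float(out)


def aif_cumulative_integral(params: AIFParams, t) -> np.ndarray:
    """Analytic ∫_{-inf}^{t} E(τ) dτ in HU·s (zero before onset).

    For the gamma-variate, substituting u = (τ-t0)/tp gives
    peak · tp · e^α · α^{-(α+1)} · γ(α+1, α·u), with γ the lower incomplete
    gamma function.
    """
    t = np.asarray(t, dtype=np.float64)
    u = np.maximum((t - params.t0) / params.tp, 0.0)
    if params.shape == "linear":
        rise = 0.5 * np.minimum(u, 1.0) ** 2
        flat = np.maximum(u - 1.0, 0.0)
        out = params.peak_enhancement * params.tp * (rise + flat)
    else:
        a = params.shape_alpha
        scale = params.peak_enhancement * params.tp * np.exp(
            a + gammaln(a + 1.0) - (a + 1.0) * np.log(a)
        )
        out = scale * gammainc(a + 1.0, a * u)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LungGeometry:
    """Ellipsoidal lung fields and an arterial cylinder, as grid fractions."""

    right_center: Tuple[float, float, float] = (0.27, 0.5, 0.5)
    left_center: Tuple[float, float, float] = (0.73, 0.5, 0.5)
    semi_axes: Tuple[float, float, float] = (0.16, 0.32, 0.40)
    artery_center_xy: Tuple[float, float] = (0.5, 0.5)
    artery_radius: float = 0.06
    artery_half_length: float = 0.30


@dataclass
class PhantomSpec:
    """Full description of one simulated dynamic acquisition.

    ``true_perfusion`` may be a scalar (uniform), a per-lobe mapping
    {label: mL/min/g}, or a full per-voxel array; ``tissue_fraction_field``
    a scalar or a per-voxel array (lung voxels only are consulted).
    ``transit_time`` is the delay after contrast arrival at which outflow
    begins and accumulation plateaus; ``inf`` means a strict first pass.
    """

    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: Tuple[float, float, float] = (4.0, 4.0, 4.0)  # mm
    lung_geometry: LungGeometry = field(default_factory=LungGeometry)
    lobe_layout: Optional[np.ndarray] = None  # explicit label volume, else planar
    true_perfusion: Union[float, Dict[int, float], np.ndarray] = field(
        default_factory=lambda: dict(DEFAULT_LOBE_PERFUSION)
    )
    tissue_fraction_field: Union[float, np.ndarray] = 0.3
    aif: AIFParams = field(default_factory=AIFParams)
    frame_times: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 21.0, 1.0)
    )  # s
    noise_sd: float = 0.0  # HU at the reference tube current
    transit_time: float = float("inf")  # s after AIF onset
    rng_seed: int = 0
    frame_tube_currents: Optional[Sequence[float]] = None  # mA per frame
    mass_model: MassModel = field(default_factory=MassModel)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if self.frame_times.ndim != 1 or self.frame_times.size < 2:
            raise SpecificationError("frame_times must be a 1D array of ≥ 2 instants")
        if np.any(np.diff(self.frame_times) <= 0):
            raise SpecificationError("frame_times must be strictly increasing")
        if self.noise_sd < 0:
            raise SpecificationError("noise_sd must be non-negative")
        if self.transit_time <= 0:
            raise SpecificationError("transit_time must be positive (inf allowed)")
        if any(n < 4 for n in self.grid_shape):
            raise SpecificationError("grid_shape axes must be ≥ 4 voxels")
        if self.frame_tube_currents is not None and len(
            self.frame_tube_currents
        ) != len(self.frame_times):
            raise SpecificationError("frame_tube_currents length must match frames")


@dataclass
class PhantomGroundTruth:
    """Everything the simulation knows that an estimator must recover."""

    perfusion_map: np.ndarray  # mL/min/g, 0 outside the lung
    lobe_labels: np.ndarray  # 0 background, 1–6 lobes
    lung_mask: np.ndarray
    artery_mask: np.ndarray
    tissue_fraction: np.ndarray
    aif_curve_true: AIFCurve
    per_lobe_mean_perfusion: Dict[int, float]  # mass-weighted


def build_geometry(
    spec: PhantomSpec,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(lung_mask, lobe_labels, artery_mask) on the spec's grid.

    Lobes are planar z-partitions: the right lung in four slabs (labels
    1–4, accessory caudal), the left lung in two (labels 5–6).
    """
    shape = spec.grid_shape
    g = spec.lung_geometry
    idx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    frac = [i / (n - 1) for i, n in zip(idx, shape)]

    def ellipsoid(center):
        d2 = sum(
            ((f - c) / ax) ** 2 for f, c, ax in zip(frac, center, g.semi_axes)
        )
        return d2 <= 1.0

    right = ellipsoid(g.right_center)
    left = ellipsoid(g.left_center)

    axy = g.artery_center_xy
    artery = (
        ((frac[0] - axy[0]) ** 2 + (frac[1] - axy[1]) ** 2 <= g.artery_radius**2)
        & (np.abs(frac[2] - 0.5) <= g.artery_half_length)
    )
    right &= ~artery
    left &= ~artery
    lung = right | left

    if spec.lobe_layout is not None:
        labels = np.asarray(spec.lobe_layout)
        if labels.shape != lung.shape:
            raise SpecificationError("lobe_layout shape differs from the grid")
        if not np.array_equal(labels > 0, lung):
            raise SpecificationError("lobe_layout must cover exactly the lung mask")
        return lung, labels.astype(np.int16), artery

    z = frac[2]
    labels = np.zeros(shape, dtype=np.int16)
    labels[right & (z >= 0.75)] = 1
    labels[right & (z >= 0.50) & (z < 0.75)] = 2
    labels[right & (z >= 0.25) & (z < 0.50)] = 3
    labels[right & (z < 0.25)] = 4
    labels[left & (z >= 0.50)] = 5
    labels[left & (z < 0.50)] = 6
    return lung, labels, artery


def arterial_voi(spec: PhantomSpec, margin: float = 0.85) -> ArterialVOI:
    """Cylindrical VOI safely inside the phantom's arterial cylinder.

    ``margin`` shrinks the VOI relative to the artery so that voxel-center
    sampling never picks up lung or background voxels at the boundary.
    """
    g = spec.lung_geometry
    extents = [
        (n - 1) * s for n, s in zip(spec.grid_shape, spec.voxel_spacing)
    ]  # mm, voxel-centered grid spans index*spacing
    center = (
        g.artery_center_xy[0] * extents[0],
        g.artery_center_xy[1] * extents[1],
        0.5 * extents[2],
    )
    radius = margin * g.artery_radius * min(extents[0], extents[1])
    half_length = margin * g.artery_half_length * extents[2]
    return ArterialVOI(
        center=center, axis=(0.0, 0.0, 1.0), radius=radius, half_length=half_length
    )


def _resolve_perfusion(spec: PhantomSpec, lung: np.ndarray, labels: np.ndarray):
    p = np.zeros(spec.grid_shape, dtype=np.float64)
    tp = spec.true_perfusion
    if isinstance(tp, dict):
        for lab, val in tp.items():
            p[labels == lab] = val
    elif np.isscalar(tp):
        p[lung] = float(tp)
    else:
        arr = np.asarray(tp, dtype=np.float64)
        if arr.shape != lung.shape:
            raise SpecificationError("true_perfusion array shape differs from grid")
        p[lung] = arr[lung]
    if np.any(p < 0):
        raise SpecificationError("true_perfusion must be non-negative")
    return p


def _resolve_fraction(spec: PhantomSpec, lung: np.ndarray):
    f = np.zeros(spec.grid_shape, dtype=np.float64)
    tf = spec.tissue_fraction_field
    if np.isscalar(tf):
        f[lung] = float(tf)
    else:
        arr = np.asarray(tf, dtype=np.float64)
        if arr.shape != lung.shape:
            raise SpecificationError("tissue_fraction_field shape differs from grid")
        f[lung] = arr[lung]
    inside = f[lung]
    if inside.size and (inside.min() <= 0 or inside.max() > 1):
        raise SpecificationError("tissue_fraction_field must lie in (0, 1] on the lung")
    return f


def simulate_series(
    spec: PhantomSpec,
) -> Tuple[List[VolumeScan], PhantomGroundTruth]:
    """Simulate one dynamic series and return it with its ground truth.

    Frame HU = structural baseline (air/tissue mixture via the HU mass
    model; arterial blood at the AIF baseline) + accumulated contrast
    enhancement + seeded Gaussian noise. Noise SD scales as
    sqrt(300 mA / tube current) when per-frame currents are given, mimicking
    a low-dose pre-contrast scan.
    """
    lung, labels, artery = build_geometry(spec)
    perfusion = _resolve_perfusion(spec, lung, labels)
    fraction = _resolve_fraction(spec, lung)
    mm = spec.mass_model

    baseline = np.full(spec.grid_shape, mm.hu_air, dtype=np.float64)
    baseline[lung] = mm.hu_air + fraction[lung] * (mm.hu_reference - mm.hu_air)
    baseline[artery] = spec.aif.baseline_hu

    # ΔHU_v(t) = p_v f_v ρ I(t); the voxel volume cancels between m_v and V_voxel
    coeff = perfusion * fraction * mm.density_reference
    cutoff = spec.aif.t0 + spec.transit_time
    eff_times = np.minimum(spec.frame_times, cutoff)
    cum_hu_min = aif_cumulative_integral(spec.aif, eff_times) / 60.0
    aif_enh = gamma_variate_aif(spec.aif, spec.frame_times)

    currents = (
        np.asarray(spec.frame_tube_currents, dtype=float)
        if spec.frame_tube_currents is not None
        else np.full(len(spec.frame_times), REFERENCE_TUBE_CURRENT)
    )
    rng = np.random.default_rng(spec.rng_seed)

    series: List[VolumeScan] = []
    for i, t in enumerate(spec.frame_times):
        hu = baseline + coeff * cum_hu_min[i]
        hu[artery] = spec.aif.baseline_hu + aif_enh[i]
        if spec.noise_sd > 0:
            sd = spec.noise_sd * np.sqrt(REFERENCE_TUBE_CURRENT / currents[i])
            hu = hu + rng.normal(0.0, sd, size=hu.shape)
        series.append(
            VolumeScan(
                hu=hu,
                spacing=spec.voxel_spacing,
                time=float(t),
                tube_current=float(currents[i]),
            )
        )

    mass = fraction  # mass-weighting ∝ fraction at uniform voxel volume/density
    per_lobe: Dict[int, float] = {}
    for lab in sorted(int(v) for v in np.unique(labels) if v != 0):
        sel = labels == lab
        w = mass[sel]
        per_lobe[lab] = float((perfusion[sel] * w).sum() / w.sum())

    truth = PhantomGroundTruth(
        perfusion_map=perfusion,
        lobe_labels=labels,
        lung_mask=lung,
        artery_mask=artery,
        tissue_fraction=fraction,
        aif_curve_true=AIFCurve(
            times=spec.frame_times.copy(),
            enhancement=np.asarray(aif_enh, dtype=np.float64),
            baseline_hu=spec.aif.baseline_hu,
        ),
        per_lobe_mean_perfusion=per_lobe,
    )
    return series, truth


def phantom_spec_from_dict(d: dict, seed: Optional[int] = None) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from a plain JSON-style dictionary.

    Recognised keys mirror the dataclass fields; ``aif`` and
    ``lung_geometry`` are nested dictionaries; ``true_perfusion`` may be a
    number or a {label: value} mapping (JSON string keys are coerced to
    int); ``frame_times`` may be a list or a {"start", "stop", "step"}
    range. ``seed`` overrides ``rng_seed`` when given.
    """
    kwargs: dict = {}
    if "grid_shape" in d:
        kwargs["grid_shape"] = tuple(int(v) for v in d["grid_shape"])
    if "voxel_spacing" in d:
        kwargs["voxel_spacing"] = tuple(float(v) for v in d["voxel_spacing"])
    if "lung_geometry" in d:
        g = d["lung_geometry"]
        kwargs["lung_geometry"] = LungGeometry(
            **{k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in g.items()}
        )
    if "aif" in d:
        kwargs["aif"] = AIFParams(**d["aif"])
    if "true_perfusion" in d:
        tp = d["true_perfusion"]
        kwargs["true_perfusion"] = (
            {int(k): float(v) for k, v in tp.items()} if isinstance(tp, dict) else float(tp)
        )
    if "tissue_fraction_field" in d:
        kwargs["tissue_fraction_field"] = float(d["tissue_fraction_field"])
    if "frame_times" in d:
        ft = d["frame_times"]
        if isinstance(ft, dict):
            kwargs["frame_times"] = np.arange(
                float(ft["start"]), float(ft["stop"]), float(ft["step"])
            )
        else:
            kwargs["frame_times"] = np.asarray(ft, dtype=float)
    for key in ("noise_sd", "transit_time"):
        if key in d:
            kwargs[key] = float(d[key])
    if "frame_tube_currents" in d:
        kwargs["frame_tube_currents"] = [float(v) for v in d["frame_tube_currents"]]
    if "rng_seed" in d:
        kwargs["rng_seed"] = int(d["rng_seed"])
    if seed is not None:
        kwargs["rng_seed"] = int(seed)
    return PhantomSpec(**kwargs)
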