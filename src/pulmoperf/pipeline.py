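"""End-to-end reproducible workflow: series in, perfusion report out.

``run_pipeline`` chains the stages of the two-volume technique —
input-function extraction, bolus tracking / base-peak selection, input
averaging, compartment perfusion, lobar aggregation — and writes the flow
map, a JSON result, a per-lobe CSV, and a provenance record (config hash,
seed, versions). Any stage failure is re-raised carrying the stage name;
outputs are written only after every stage has succeeded, so a failed run
leaves no partial results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .aif import bolus_track, extract_aif, select_base_peak
from .errors import ParameterError, PulmoperfError
from .io import (
    load_label_volume,
    load_volume,
    read_aif_curve,
    read_series,
    read_voi,
    save_label_volume,
    save_volume,
    write_aif_curve,
    write_perfusion_result,
    write_series,
    write_voi,
)
from .perfusion import (
    MassModel,
    PerfusionInputs,
    compute_perfusion,
    mean_input_concentration,
    regional_perfusion,
)
from .phantom import PhantomSpec, arterial_voi, simulate_series

logger = logging.getLogger("pulmoperf")

__all__ = ["RunConfig", "run_pipeline", "simulate_to_dir"]


@dataclass
class RunConfig:
    """Configuration for one perfusion computation.

    Either ``series_dir`` (a dynamic series written by ``simulate``/
    ``write_series``; V1/V2 are the selected base/peak frames) or the pair
    ``v1_path``/``v2_path`` together with ``aif_csv`` must be provided.
    """

    out_dir: str
    mode: str = "multivolume"  # or "two_volume"
    series_dir: Optional[str] = None
    v1_path: Optional[str] = None
    v2_path: Optional[str] = None
    mask_path: Optional[str] = None
    lobes_path: Optional[str] = None
    aif_csv: Optional[str] = None
    voi_path: Optional[str] = None
    bolus_threshold_hu: float = 80.0
    base_fraction: float = 0.05
    hu_air: float = -1000.0
    hu_reference: float = 0.0
    density_reference: float = 1.0
    min_tissue_fraction: float = 0.01
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("two_volume", "multivolume"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.series_dir is None:
            if self.v1_path is None or self.v2_path is None:
                raise ParameterError("provide series_dir or both v1_path and v2_path")
            if self.aif_csv is None:
                raise ParameterError("aif_csv is required when not using series_dir")
        if self.mask_path is None and self.series_dir is None:
            raise ParameterError("mask_path is required")

    def config_hash(self) -> str:
        """Hash of the computation-relevant configuration.

        Output location and log level do not influence results and are
        excluded, so reruns into different directories hash identically.
        """
        d = asdict(self)
        d.pop("out_dir", None)
        d.pop("log_level", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PulmoperfError as exc:
                raise type(exc)(f"stage '{name}': {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig):
    """Execute the full perfusion workflow and write its artifacts.

    Returns (PerfusionResult, FlowMap).
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    mm = MassModel(
        hu_air=config.hu_air,
        hu_reference=config.hu_reference,
        density_reference=config.density_reference,
        min_tissue_fraction=config.min_tissue_fraction,
    )

    if config.series_dir is not None:
        series = _stage("read_series")(read_series)(config.series_dir)
        d = Path(config.series_dir)
        mask_path = config.mask_path or str(d / "lung_mask.nii")
        lobes_path = config.lobes_path or (
            str(d / "lobe_labels.nii") if (d / "lobe_labels.nii").exists() else None
        )
        voi_path = config.voi_path or str(d / "voi.json")
        voi = read_voi(voi_path)
        curve = _stage("extract_aif")(extract_aif)(series, voi)
    else:
        series = None
        mask_path, lobes_path = config.mask_path, config.lobes_path
        curve = _stage("read_aif")(read_aif_curve)(config.aif_csv)

    if config.mode == "two_volume":
        trig = _stage("bolus_track")(bolus_track)(curve, config.bolus_threshold_hu)
        logger.info("bolus_track: trigger at t=%.2f s", trig)

    base_i, peak_i, delta_t_s = _stage("select_base_peak")(select_base_peak)(
        curve, config.base_fraction
    )
    logger.info(
        "select_base_peak: base=%d peak=%d delta_t=%.2f s", base_i, peak_i, delta_t_s
    )
    c_in = _stage("mean_input_concentration")(mean_input_concentration)(
        curve, config.mode
    )
    logger.info("mean_input_concentration (%s): C_in=%.2f HU", config.mode, c_in)

    if series is not None:
        v1, v2 = series[base_i], series[peak_i]
    else:
        v1 = _stage("load_volumes")(load_volume)(config.v1_path)
        v2 = _stage("load_volumes")(load_volume)(config.v2_path)
    lung_mask = load_label_volume(mask_path).astype(bool)

    inputs = PerfusionInputs(
        v1=v1, v2=v2, lung_mask=lung_mask, c_in=c_in, delta_t_s=delta_t_s,
        mass_model=mm,
    )
    flow = _stage("compute_perfusion")(compute_perfusion)(inputs)
    logger.info(
        "compute_perfusion: M_T=%.1f g dM_c=%.1f HU.mL P=%.3f mL/min/g",
        flow.total_mass,
        flow.global_perfusion * flow.total_mass * c_in * (delta_t_s / 60.0),
        flow.global_perfusion,
    )

    if lobes_path is not None:
        lobes = load_label_volume(lobes_path)
        result = _stage("regional_perfusion")(regional_perfusion)(
            flow, lobes, delta_t_s=delta_t_s, c_in=c_in
        )
    else:
        result = regional_perfusion(
            flow, np.zeros_like(lung_mask, dtype=np.int16),
            delta_t_s=delta_t_s, c_in=c_in,
        )

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
        "pulmoperf_version": __version__,
        "numpy_version": np.__version__,
        "base_index": base_i,
        "peak_index": peak_i,
    }
    out = Path(config.out_dir)
    write_perfusion_result(out, result, flow, v1.spacing, provenance)
    write_aif_curve(out / "aif.csv", curve, out / "aif.json")
    return result, flow


def simulate_to_dir(spec: PhantomSpec, out_dir) -> None:
    """Simulate a phantom series and write everything downstream stages need.

    Writes the dynamic frames with their timing sidecar, the lung mask and
    lobe labels, an arterial VOI definition, the true input curve, and a
    ground-truth JSON (per-lobe true perfusion and AIF parameters).
    """
    series, truth = simulate_series(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_series(out, series)
    save_label_volume(out / "lung_mask.nii", truth.lung_mask.astype(np.int16), spec.voxel_spacing)
    save_label_volume(out / "lobe_labels.nii", truth.lobe_labels, spec.voxel_spacing)
    save_volume(
        out / "true_perfusion.nii",
        type(series[0])(hu=truth.perfusion_map, spacing=spec.voxel_spacing),
    )
    write_voi(out / "voi.json", arterial_voi(spec))
    write_aif_curve(out / "aif_true.csv", truth.aif_curve_true)
    gt = {
        "per_lobe_mean_perfusion_ml_min_g": truth.per_lobe_mean_perfusion,
        "aif": asdict(spec.aif),
        "noise_sd_hu": spec.noise_sd,
        "transit_time_s": spec.transit_time,
        "rng_seed": spec.rng_seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=2, sort_keys=True))
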