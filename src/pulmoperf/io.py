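"""File I/O: NIfTI volumes, JSON sidecars, CSV tables.

Volumes are stored as single-file NIfTI (float32 HU, voxel spacing on the
affine diagonal). Acquisition timing and tube currents, which NIfTI headers
cannot carry, live in a ``frames.json`` sidecar next to the series.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .aif import AIFCurve, ArterialVOI
from .errors import DataError
from .perfusion import FlowMap, PerfusionResult, VolumeScan

__all__ = [
    "save_volume",
    "load_volume",
    "write_series",
    "read_series",
    "write_aif_curve",
    "read_aif_curve",
    "read_voi",
    "write_voi",
    "write_perfusion_result",
    "read_paired_csv",
]


def save_volume(path, v: VolumeScan) -> None:
    """Write a volume as float32 NIfTI with spacing on the affine diagonal."""
    affine = np.diag(list(v.spacing) + [1.0])
    img = nib.Nifti1Image(v.hu.astype(np.float32), affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def load_volume(path, time: float = 0.0, tube_current: float = float("nan")) -> VolumeScan:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeScan(hu=data, spacing=spacing, time=time, tube_current=tube_current)


def save_label_volume(path, labels: np.ndarray, spacing: Sequence[float]) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def load_label_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.int16)


def write_series(out_dir, series: Sequence[VolumeScan]) -> None:
    """Write a dynamic series: frame_###.nii plus a frames.json sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, v in enumerate(series):
        save_volume(out / f"frame_{i:03d}.nii", v)
    sidecar = {
        "frame_times_s": [v.time for v in series],
        "tube_currents_ma": [v.tube_current for v in series],
    }
    (out / "frames.json").write_text(json.dumps(sidecar, indent=2))


def read_series(series_dir) -> List[VolumeScan]:
    """Read a dynamic series written by :func:`write_series`."""
    d = Path(series_dir)
    sidecar_path = d / "frames.json"
    if not sidecar_path.exists():
        raise DataError(f"missing frames.json sidecar in {d}")
    sidecar = json.loads(sidecar_path.read_text())
    times = sidecar["frame_times_s"]
    currents = sidecar.get("tube_currents_ma", [float("nan")] * len(times))
    paths = sorted(d.glob("frame_*.nii"))
    if len(paths) != len(times):
        raise DataError(
            f"{len(paths)} frame files but {len(times)} frame times in sidecar"
        )
    return [
        load_volume(p, time=t, tube_current=c)
        for p, t, c in zip(paths, times, currents)
    ]


def write_aif_curve(csv_path, curve: AIFCurve, json_path=None) -> None:
    """CSV (time_s, enhancement_hu) plus optional JSON annotation sidecar."""
    pd.DataFrame(
        {"time_s": curve.times, "enhancement_hu": curve.enhancement}
    ).to_csv(csv_path, index=False)
    if json_path is not None:
        ann = {
            "baseline_hu": curve.baseline_hu,
            "trigger_index": curve.trigger_index,
            "base_index": curve.base_index,
            "peak_index": curve.peak_index,
        }
        Path(json_path).write_text(json.dumps(ann, indent=2))


def read_aif_curve(csv_path, json_path=None) -> AIFCurve:
    df = pd.read_csv(csv_path)
    kwargs = {}
    jp = Path(json_path) if json_path is not None else Path(csv_path).with_suffix(".json")
    if jp.exists():
        ann = json.loads(jp.read_text())
        kwargs = {
            "baseline_hu": ann.get("baseline_hu", 0.0),
            "trigger_index": ann.get("trigger_index"),
            "base_index": ann.get("base_index"),
            "peak_index": ann.get("peak_index"),
        }
    return AIFCurve(
        times=df["time_s"].to_numpy(),
        enhancement=df["enhancement_hu"].to_numpy(),
        **kwargs,
    )


def write_voi(path, voi: ArterialVOI) -> None:
    Path(path).write_text(json.dumps(asdict(voi), indent=2))


def read_voi(path) -> ArterialVOI:
    d = json.loads(Path(path).read_text())
    return ArterialVOI(
        center=tuple(d["center"]),
        axis=tuple(d.get("axis", (0.0, 0.0, 1.0))),
        radius=float(d["radius"]),
        half_length=float(d["half_length"]),
    )


def write_perfusion_result(
    out_dir,
    result: PerfusionResult,
    flow: Optional[FlowMap] = None,
    spacing: Optional[Tuple[float, float, float]] = None,
    provenance: Optional[dict] = None,
) -> None:
    """JSON result + per-lobe CSV (+ flow-map NIfTI when a map is given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "global_perfusion_ml_min_g": result.global_perfusion,
        "delta_t_s": result.delta_t_s,
        "c_in_hu": result.c_in,
        "delta_mass_c_hu_ml": result.delta_mass_c,
        "total_mass_g": result.total_mass,
        "per_lobe": result.to_records(),
    }
    if provenance is not None:
        payload["provenance"] = provenance
    (out / "perfusion.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    pd.DataFrame(result.to_records()).to_csv(out / "lobes.csv", index=False)
    if flow is not None:
        if spacing is None:
            raise DataError("spacing required to write the flow map volume")
        save_volume(
            out / "flow_map.nii",
            VolumeScan(hu=np.nan_to_num(flow.perfusion, nan=0.0), spacing=spacing),
        )


def read_paired_csv(path):
    """Paired-measurement CSV with columns (label optional), x, y."""
    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise DataError("paired CSV must have columns 'x' and 'y'")
    labels = df["label"].tolist() if "label" in df.columns else None
    return df["x"].to_numpy(), df["y"].to_numpy(), labels
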