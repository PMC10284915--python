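"""File formats: gzipped NIfTI volumes/series, TSV traces, JSON sidecars.

All volumes are written with a diagonal affine built from the voxel size
(the package assumes data already live on an MNI-like grid, so no
orientation handling beyond that is attempted).  Every writer can attach a
JSON sidecar carrying provenance (seeds, parameters, clip/pad reports).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BoldSeries, ConfigurationError, EtCo2Trace, MotionTrace, VolumeMap


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def write_sidecar(path: str | Path, payload: dict[str, Any]) -> Path:
    path = Path(path)
    side = path.parent / (path.name.split(".")[0] + ".json")
    side.write_text(json.dumps(payload, indent=2, default=str))
    return side


def save_volume(vol: VolumeMap, path: str | Path,
                sidecar: dict | None = None) -> Path:
    path = Path(path)
    data = vol.values
    if vol.units == "label":
        data = data.astype(np.int16)
    elif vol.units == "mask":
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), _affine(vol.voxel_size_mm))
    nib.save(img, str(path))
    payload = {"units": vol.units, **vol.meta}
    if sidecar:
        payload.update(sidecar)
    write_sidecar(path, payload)
    return path


def load_volume(path: str | Path, units: str | None = None) -> VolumeMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta: dict[str, Any] = {}
    side = Path(path).parent / (Path(path).name.split(".")[0] + ".json")
    if side.exists():
        meta = json.loads(side.read_text())
        units = units or meta.pop("units", None)
    return VolumeMap(data, units=units or "raw", voxel_size_mm=vs, meta=meta)


def save_mask(mask: np.ndarray, path: str | Path,
              voxel_size_mm=(2.0, 2.0, 2.0)) -> Path:
    return save_volume(VolumeMap(mask.astype(np.uint8), units="mask",
                                 voxel_size_mm=voxel_size_mm), path)


def save_series(series: BoldSeries, path: str | Path,
                sidecar: dict | None = None) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(series.values, dtype=np.float32),
                          _affine(series.voxel_size_mm))
    img.header.set_zooms(tuple(series.voxel_size_mm) + (series.tr,))
    nib.save(img, str(path))
    payload = {"tr": series.tr, **series.meta}
    if sidecar:
        payload.update(sidecar)
    write_sidecar(path, payload)
    return path


def load_series(path: str | Path) -> BoldSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ConfigurationError(f"{path}: expected a 4D series")
    zooms = img.header.get_zooms()
    vs = tuple(float(z) for z in zooms[:3])
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 0.0
    side = Path(path).parent / (Path(path).name.split(".")[0] + ".json")
    meta: dict[str, Any] = {}
    if side.exists():
        meta = json.loads(side.read_text())
        tr = float(meta.pop("tr", tr))
    if tr <= 0:
        raise ConfigurationError(f"{path}: repetition time not recorded")
    return BoldSeries(data, tr=tr, voxel_size_mm=vs, meta=meta)


def save_motion(motion: MotionTrace, tr: float, path: str | Path) -> Path:
    t = np.arange(motion.n_timepoints) * tr
    df = pd.DataFrame(
        np.column_stack([t, motion.values]),
        columns=["time_s", "trans_x_mm", "trans_y_mm", "trans_z_mm",
                 "rot_x_rad", "rot_y_rad", "rot_z_rad"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return Path(path)


def load_motion(path: str | Path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c != "time_s"]
    if len(cols) != 6:
        raise ConfigurationError(f"{path}: expected 6 motion columns")
    return MotionTrace(df[cols].to_numpy())


def save_etco2(trace: EtCo2Trace, path: str | Path) -> Path:
    df = pd.DataFrame({"time_s": trace.timestamps,
                       "petco2_mmHg": trace.values})
    if trace.baseline_mask is not None:
        df["baseline_block"] = trace.baseline_mask.astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    write_sidecar(path, {"baseline_mmHg": trace.baseline})
    return Path(path)


def load_etco2(path: str | Path) -> EtCo2Trace:
    df = pd.read_csv(path, sep="\t")
    if not {"time_s", "petco2_mmHg"} <= set(df.columns):
        raise ConfigurationError(
            f"{path}: EtCO2 TSV needs columns time_s, petco2_mmHg")
    mask = (df["baseline_block"].to_numpy().astype(bool)
            if "baseline_block" in df.columns else None)
    side = Path(path).parent / (Path(path).name.split(".")[0] + ".json")
    baseline = 40.0
    if side.exists():
        baseline = float(json.loads(side.read_text()).get("baseline_mmHg", 40.0))
    return EtCo2Trace(df["time_s"].to_numpy(), df["petco2_mmHg"].to_numpy(),
                      baseline=baseline, baseline_mask=mask)
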