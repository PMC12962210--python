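"""File formats: HDF5 k-space containers, NIfTI volumes, CSV/JSON reports.

The k-space container stores ``/kspace`` (complex, channels x kx x ky x kz),
``/noise_block`` and ``/sampling_mask`` datasets with grid metadata as
attributes.  Volumes and label masks go through NIfTI with the voxel size
on the affine diagonal; tabular outputs are tidy CSVs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .acquisition import KSpaceDataset
from .geometry import CoilGeometry, DistanceProfile
from .regions import RegionMaskSet


def save_kspace(path, kspace: KSpaceDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kspace.data)
        f.create_dataset("noise_block", data=kspace.noise_block)
        f.create_dataset("sampling_mask", data=kspace.sampling_mask.astype(np.uint8))
        f.attrs["voxel_size_mm"] = kspace.voxel_size_mm
        f.attrs["origin_mm"] = kspace.origin_mm
        f.attrs["axis_tags"] = list(kspace.axis_tags)
        f.attrs["coil_name"] = kspace.coil_name
        if kspace.seed is not None:
            f.attrs["seed"] = kspace.seed


def load_kspace(path) -> KSpaceDataset:
    with h5py.File(path, "r") as f:
        return KSpaceDataset(
            data=f["kspace"][()],
            noise_block=f["noise_block"][()],
            sampling_mask=f["sampling_mask"][()].astype(bool),
            voxel_size_mm=f.attrs["voxel_size_mm"],
            origin_mm=f.attrs.get("origin_mm", np.zeros(3)),
            axis_tags=tuple(f.attrs.get("axis_tags", ("A/P", "R/L", "S/I"))),
            coil_name=str(f.attrs.get("coil_name", "")),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def _affine(voxel_size_mm) -> np.ndarray:
    vox = np.asarray(voxel_size_mm, dtype=float).reshape(-1)
    if vox.size == 1:
        vox = np.repeat(vox, 3)
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vox
    return aff


def save_nifti(path, array: np.ndarray, voxel_size_mm, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(array).astype(dtype), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_nifti(path):
    """Returns (array, voxel_size_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    vox = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, vox


def save_region_masks(path, masks: RegionMaskSet) -> None:
    save_nifti(path, masks.labels, masks.voxel_size_mm, dtype=np.int16)


def load_region_masks(path) -> RegionMaskSet:
    data, vox = load_nifti(path)
    return RegionMaskSet(labels=data.astype(np.int16), voxel_size_mm=vox)


def save_geometry_json(path, geometry: CoilGeometry) -> None:
    payload = {
        "model_tag": geometry.model_tag,
        "element_points_mm": geometry.element_points_mm.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_geometry_json(path) -> CoilGeometry:
    payload = json.loads(Path(path).read_text())
    return CoilGeometry(
        element_points_mm=np.asarray(payload["element_points_mm"], dtype=float),
        model_tag=payload["model_tag"],
    )


def region_values_to_csv(path, values: np.ndarray, region: str) -> None:
    """Exact round-trip export: values serialised with full precision."""
    df = pd.DataFrame({"region": region, "rsnr": np.asarray(values, dtype=float)})
    df.to_csv(path, index=False, float_format="%.17g")


def region_values_from_csv(path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    return df["rsnr"].to_numpy(dtype=float)


def distance_profile_to_frame(profiles: dict[str, DistanceProfile]) -> pd.DataFrame:
    rows = []
    for name, prof in profiles.items():
        for left, med, cnt in zip(
            prof.bin_edges_mm[:-1], prof.median_rsnr, prof.voxel_count
        ):
            rows.append(
                {"region": name, "bin_left_mm": float(left),
                 "median_rsnr": float(med) if np.isfinite(med) else np.nan,
                 "count": int(cnt)}
            )
    return pd.DataFrame(rows)


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def save_report_json(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, cls=_ReportEncoder, indent=1))


def load_config_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
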