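"""NIfTI + JSON-sidecar I/O for series, phantoms and perfusion maps.

A 4D series is stored as ``<stem>.nii.gz`` in (X, Y, Z, T) NIfTI axis order
with a ``<stem>.json`` sidecar carrying frame times, ROI voxel lists, the
seed and any phantom parameters; the sidecar is required on read (a missing
sidecar is an explicit error, not a silent default).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .containers import CTPSeries, PerfusionMaps, PerfusionPhantom


def _affine(voxel_spacing) -> np.ndarray:
    # (Z, Y, X) spacing -> NIfTI (X, Y, Z) diagonal
    dz, dy, dx = voxel_spacing
    return np.diag([dx, dy, dz, 1.0])


def write_series(series: CTPSeries, stem: str | Path, extra: dict | None = None) -> None:
    stem = Path(stem)
    img = nib.Nifti1Image(np.transpose(series.data, (3, 2, 1, 0)), _affine(series.voxel_spacing))
    nib.save(img, str(stem) + ".nii.gz")
    sidecar = {
        "frame_times": series.frame_times.tolist(),
        "voxel_spacing": list(series.voxel_spacing),
        "aif_roi": series.aif_roi.tolist() if series.aif_roi is not None else None,
        "vof_roi": series.vof_roi.tolist() if series.vof_roi is not None else None,
    }
    if extra:
        sidecar.update(extra)
    with open(str(stem) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    if series.brain_mask is not None:
        write_volume(series.brain_mask.astype(np.uint8), series.voxel_spacing, str(stem) + "_mask")


def read_series(stem: str | Path) -> CTPSeries:
    stem = Path(stem)
    nii = Path(str(stem) + ".nii.gz")
    sidecar_path = Path(str(stem) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"timing sidecar {sidecar_path} is missing; frame times cannot be defaulted"
        )
    data = np.asarray(nib.load(str(nii)).dataobj)
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    mask_path = Path(str(stem) + "_mask.nii.gz")
    mask = None
    if mask_path.exists():
        mask = read_volume(mask_path)[0].astype(bool)
    return CTPSeries(
        data=np.transpose(data, (3, 2, 1, 0)),
        frame_times=np.array(sidecar["frame_times"], dtype=float),
        voxel_spacing=tuple(sidecar["voxel_spacing"]),
        aif_roi=np.array(sidecar["aif_roi"], dtype=int) if sidecar.get("aif_roi") else None,
        vof_roi=np.array(sidecar["vof_roi"], dtype=int) if sidecar.get("vof_roi") else None,
        brain_mask=mask,
    )


def write_volume(volume: np.ndarray, voxel_spacing, path: str | Path) -> None:
    """Write a 3D (Z, Y, X) volume as NIfTI."""
    img = nib.Nifti1Image(np.transpose(np.asarray(volume), (2, 1, 0)), _affine(voxel_spacing))
    path = str(path)
    if not path.endswith(".nii.gz"):
        path += ".nii.gz"
    nib.save(img, path)


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.transpose(np.asarray(img.dataobj), (2, 1, 0))
    dx, dy, dz = img.header.get_zooms()[:3]
    return data, (float(dz), float(dy), float(dx))


def write_phantom(phantom: PerfusionPhantom, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp = phantom.voxel_spacing
    write_volume(phantom.cbf_map, sp, out / "cbf_truth")
    write_volume(phantom.mtt_map, sp, out / "mtt_truth")
    write_volume(phantom.delay_map, sp, out / "delay_truth")
    for name in ("core_mask", "hypo_mask", "brain_mask"):
        write_volume(getattr(phantom, name).astype(np.uint8), sp, out / name)


def write_maps(maps: PerfusionMaps, stem: str | Path) -> None:
    write_volume(maps.cbf, maps.voxel_spacing, str(stem) + "_cbf")
    write_volume(maps.tmax, maps.voxel_spacing, str(stem) + "_tmax")
    with open(str(stem) + ".json", "w") as fh:
        json.dump({"provenance": maps.provenance, "voxel_spacing": list(maps.voxel_spacing)}, fh)


def read_maps(stem: str | Path, brain_mask: np.ndarray) -> PerfusionMaps:
    meta_path = Path(str(stem) + ".json")
    if not meta_path.exists():
        raise FileNotFoundError(f"maps metadata {meta_path} is missing")
    with open(meta_path) as fh:
        meta = json.load(fh)
    cbf, spacing = read_volume(str(stem) + "_cbf.nii.gz")
    tmax, _ = read_volume(str(stem) + "_tmax.nii.gz")
    return PerfusionMaps(
        cbf=cbf, tmax=tmax, brain_mask=brain_mask,
        provenance=meta["provenance"], voxel_spacing=tuple(meta["voxel_spacing"]),
    )
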