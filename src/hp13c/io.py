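"""NIfTI / JSON / CSV input-output helpers.

Volumes are written as NIfTI with a diagonal affine built from the
voxel size; dynamic series are 4-D (x, y, z, t) files, one per
metabolite, with the acquisition parameters in a JSON sidecar.  The
multichannel stage stores one 4-D file per channel per metabolite.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import AcquisitionParams, KineticMap, MetaboliteSeries, METABOLITES

__all__ = [
    "save_volume",
    "load_volume",
    "save_series",
    "load_series",
    "save_kinetic_map",
    "load_kinetic_map",
    "save_table",
]


def _affine(voxel_size_mm=(15.0, 15.0, 15.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_volume(path, volume: np.ndarray, voxel_size_mm=(15.0, 15.0, 15.0)) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path, expect_affine: np.ndarray | None = None) -> np.ndarray:
    img = nib.load(str(path))
    if expect_affine is not None and not np.allclose(img.affine, expect_affine, atol=1e-6):
        raise ValueError(f"{path}: affine does not match the reference grid")
    return np.asarray(img.get_fdata())


def save_series(out_dir, series: MetaboliteSeries, voxel_size_mm=(15.0, 15.0, 15.0)) -> None:
    """Write one 4-D NIfTI per metabolite plus an acquisition sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m in METABOLITES:
        # (t, z, r, c) -> (c, r, z, t) spatial-first layout
        vol = np.transpose(series[m], (3, 2, 1, 0))
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), _affine(voxel_size_mm)),
                 str(out / f"{m}_dynamic.nii"))
    sidecar = {"acquisition": (series.acq or AcquisitionParams(
        n_timepoints=len(series.time))).to_dict(),
        "time_s": np.asarray(series.time).tolist(),
        "noise_sd": series.noise_sd}
    (out / "series.json").write_text(json.dumps(sidecar, indent=2))


def load_series(in_dir) -> MetaboliteSeries:
    src = Path(in_dir)
    sidecar_path = src / "series.json"
    if not sidecar_path.exists():
        raise ValueError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    acq = AcquisitionParams.from_dict(sidecar["acquisition"])
    arrays = {}
    for m in METABOLITES:
        img = nib.load(str(src / f"{m}_dynamic.nii"))
        arrays[m] = np.transpose(np.asarray(img.get_fdata()), (3, 2, 1, 0))
    return MetaboliteSeries(
        pyr=arrays["pyr"], lac=arrays["lac"], bic=arrays["bic"],
        time=np.asarray(sidecar["time_s"], dtype=float),
        acq=acq, noise_sd=sidecar.get("noise_sd"),
    )


_MAP_FIELDS = ("k_pl", "k_pb", "k_pl_error", "k_pb_error", "valid_mask")


def save_kinetic_map(out_dir, kmap: KineticMap, voxel_size_mm=(15.0, 15.0, 15.0)) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for f in _MAP_FIELDS:
        vol = np.transpose(np.asarray(getattr(kmap, f), dtype=np.float64), (2, 1, 0))
        save_volume(out / f"{f}.nii", vol, voxel_size_mm)
    (out / "provenance.json").write_text(
        json.dumps(kmap.provenance, indent=2, default=str)
    )


def load_kinetic_map(in_dir) -> KineticMap:
    src = Path(in_dir)
    vols = {
        f: np.transpose(load_volume(src / f"{f}.nii"), (2, 1, 0)) for f in _MAP_FIELDS
    }
    prov_path = src / "provenance.json"
    prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    return KineticMap(
        k_pl=vols["k_pl"], k_pb=vols["k_pb"],
        k_pl_error=vols["k_pl_error"], k_pb_error=vols["k_pb_error"],
        valid_mask=vols["valid_mask"] > 0.5,
        provenance=prov,
    )


def save_table(path, rows: list[dict]) -> pd.DataFrame:
    """Write a list of records as CSV with stable column order."""
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
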