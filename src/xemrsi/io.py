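"""File formats: NIfTI volumes, HDF5 k-space, CSV tables, JSON/YAML configs.

Every writer has a matching reader and round trips losslessly.  NIfTI
volumes are written in RAS orientation with the voxel size from the
acquisition geometry; k-space goes to HDF5 with the centered index
convention recorded in the file; non-finite (flagged) voxels serialize
as NaN.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .config import AcquisitionConfig
from .fitting import PriorKnowledge
from .recon import KSpaceMRSI
from .synthetic import BloodGasRecord, PhantomTruth

__all__ = [
    "save_volume", "load_volume",
    "save_kspace", "load_kspace",
    "save_phantom", "load_phantom",
    "blood_gas_to_frame", "save_blood_gas", "load_blood_gas",
    "save_prior", "load_prior",
]

BLOOD_GAS_COLUMNS = ["animal", "fio2", "pao2_mmHg", "pco2_mmHg", "ph",
                     "so2", "hct", "hb_mmol_l"]


def _affine(voxel_mm) -> np.ndarray:
    aff = np.diag(list(voxel_mm) + [1.0])
    return aff


def save_volume(vol: np.ndarray, path, voxel_mm=(1.0, 1.0, 1.0)) -> None:
    """Write a 3D volume as NIfTI (RAS, diagonal affine from voxel size)."""
    vol = np.asarray(vol)
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    img = nib.Nifti1Image(vol.astype(np.float32) if vol.dtype.kind == "f" else vol,
                          _affine(voxel_mm))
    nib.save(img, str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def save_kspace(ksp: KSpaceMRSI, path) -> None:
    """HDF5 layout: datasets ``locations`` (N x 3 centered integer grid
    indices; DC at 0, even axes span [-N/2, N/2-1]) and ``fids``
    (N x n_samples complex); the acquisition config as a JSON attribute."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("locations", data=ksp.locations)
        f.create_dataset("fids", data=ksp.fids)
        f.attrs["acq_json"] = json.dumps(ksp.acq.to_dict())
        f.attrs["index_convention"] = "centered; DC at 0; even axes [-N/2, N/2-1]"


def load_kspace(path) -> KSpaceMRSI:
    path = Path(path)
    try:
        with h5py.File(str(path), "r") as f:
            locations = f["locations"][()]
            fids = f["fids"][()]
            acq = AcquisitionConfig.from_dict(json.loads(f.attrs["acq_json"]))
    except (OSError, KeyError) as e:
        raise IOError(f"cannot read k-space file {path}: {e}") from e
    return KSpaceMRSI(locations=locations, fids=fids, acq=acq)


def save_phantom(phantom: PhantomTruth, out_dir, voxel_mm=(1, 1, 1)) -> None:
    """One NIfTI per parameter map plus a JSON sidecar with the scalars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, vol in phantom.maps.items():
        save_volume(vol, out / f"{name}.nii.gz", voxel_mm)
    save_volume(phantom.lung_mask, out / "lung_mask.nii.gz", voxel_mm)
    save_volume(phantom.lobe_labels.astype(np.int16), out / "lobe_labels.nii.gz",
                voxel_mm)
    sidecar = {
        "grid": list(phantom.grid),
        "fio2": phantom.fio2,
        "pao2_mmHg": phantom.pao2_mmHg,
        "so2": phantom.so2,
        "gas_t2star_ms": phantom.gas_t2star_ms,
        "animal": phantom.animal,
        "label_map": {str(k): v for k, v in phantom.label_map.items()},
        "meta": phantom.meta,
    }
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(out_dir) -> PhantomTruth:
    out = Path(out_dir)
    sidecar = json.loads((out / "phantom.json").read_text())
    maps = {}
    for p in sorted(out.glob("*.nii.gz")):
        name = p.name.replace(".nii.gz", "")
        if name in ("lung_mask", "lobe_labels"):
            continue
        maps[name] = np.asarray(load_volume(p), dtype=float)
    return PhantomTruth(
        grid=tuple(sidecar["grid"]),
        fio2=sidecar["fio2"],
        maps=maps,
        lung_mask=load_volume(out / "lung_mask.nii.gz").astype(bool),
        lobe_labels=load_volume(out / "lobe_labels.nii.gz").astype(np.int16),
        label_map={int(k): v for k, v in sidecar["label_map"].items()},
        pao2_mmHg=sidecar["pao2_mmHg"],
        so2=sidecar["so2"],
        gas_t2star_ms=sidecar["gas_t2star_ms"],
        animal=sidecar["animal"],
        meta=sidecar["meta"],
    )


def blood_gas_to_frame(records: list[BloodGasRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=BLOOD_GAS_COLUMNS)


def save_blood_gas(records: list[BloodGasRecord], path) -> None:
    blood_gas_to_frame(records).to_csv(path, index=False)


def load_blood_gas(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BLOOD_GAS_COLUMNS) - set(df.columns)
    if missing:
        raise IOError(f"blood-gas table {path} missing columns {sorted(missing)}")
    return df


def save_prior(prior: PriorKnowledge, path) -> None:
    path = Path(path)
    d = prior.to_dict()
    text = json.dumps(d, indent=2) if path.suffix == ".json" else yaml.safe_dump(d)
    path.write_text(text)


def load_prior(path) -> PriorKnowledge:
    path = Path(path)
    raw = path.read_text()
    d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    return PriorKnowledge.from_dict(d)
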