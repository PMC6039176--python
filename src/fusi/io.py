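"""Container I/O: NIfTI volumes (1 Hz %CBV / maps), HDF5 frame blocks,
CSV event tables and JSON configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .core import AcquisitionConfig, CBVSeries, FrameBlock, TrialProtocol

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_cbv",
    "load_cbv",
    "save_frame_blocks",
    "load_frame_blocks",
    "save_events",
    "load_events",
    "save_config",
    "load_config",
]


def save_nifti(path, data: np.ndarray, voxel_size_mm=(0.1, 0.1, 0.4), tr_s: float = 1.0):
    """Write an array as NIfTI; for 4-D data the TR is recorded in the header."""
    data = np.asarray(data)
    affine = np.diag(list(voxel_size_mm[: min(3, data.ndim)])
                     + [1.0] * (4 - min(3, data.ndim)))
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    if data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr_s
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_cbv(path, cbv: CBVSeries, voxel_size_mm=(0.1, 0.1, 0.4)):
    """Write a %CBV series as 4-D NIfTI (time last, TR 1 s); 2-D grids get
    a singleton third axis."""
    values = cbv.values
    if values.ndim == 3:  # (z, x, t) -> (z, x, 1, t)
        values = values[:, :, None, :]
    save_nifti(path, values, voxel_size_mm=voxel_size_mm, tr_s=1.0)


def load_cbv(path) -> CBVSeries:
    return CBVSeries(values=load_nifti(path))


def save_frame_blocks(path, blocks: list[FrameBlock]):
    """Write frame blocks as complex64 HDF5 datasets with the acquisition
    config stored as attributes."""
    with h5py.File(str(path), "w") as f:
        for i, b in enumerate(blocks):
            d = f.create_dataset(f"block_{i:05d}", data=b.data.astype(np.complex64))
            for fld in dataclasses.fields(b.config):
                d.attrs[fld.name] = getattr(b.config, fld.name)


def load_frame_blocks(path) -> list[FrameBlock]:
    blocks = []
    with h5py.File(str(path), "r") as f:
        for name in sorted(f.keys()):
            d = f[name]
            kw = {k: d.attrs[k] for k in d.attrs}
            if "voxel_pitch" in kw:
                kw["voxel_pitch"] = tuple(float(v) for v in kw["voxel_pitch"])
            cfg = AcquisitionConfig(
                frame_rate=float(kw["frame_rate"]),
                frames_per_block=int(kw["frames_per_block"]),
                block_period=float(kw["block_period"]),
                transmit_frequency=float(kw["transmit_frequency"]),
                speed_of_sound=float(kw["speed_of_sound"]),
                voxel_pitch=kw.get("voxel_pitch", (100.0, 100.0, 400.0)),
            )
            blocks.append(FrameBlock(data=np.asarray(d[...], dtype=np.complex128),
                                     config=cfg))
    return blocks


def save_events(path, events: pd.DataFrame):
    events[["onset_s", "label"]].to_csv(str(path), index=False)


def load_events(path) -> pd.DataFrame:
    return pd.read_csv(str(path))


def save_config(path, config):
    d = dataclasses.asdict(config)
    d["_type"] = type(config).__name__
    Path(path).write_text(json.dumps(d, indent=2))


def load_config(path):
    d = json.loads(Path(path).read_text())
    kind = d.pop("_type")
    cls = {"AcquisitionConfig": AcquisitionConfig, "TrialProtocol": TrialProtocol}[kind]
    for key in ("voxel_pitch", "jitter_range_s", "frequencies"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return cls(**d)
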