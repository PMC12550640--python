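"""File formats: cohort/score CSVs, mesh CSV pairs, NIfTI volumes, HDF5 epochs."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .erp import EpochSet
from .fusion import ContrastVolume, ROIMaskVolume, TetMesh

__all__ = [
    "write_table", "read_table", "write_mesh", "read_mesh",
    "write_volume", "read_volume", "read_mask", "write_mask",
    "EpochWriter", "read_epochs", "list_epoch_keys", "tidy_to_wide",
]

FLOAT_FMT = "%.10g"


def write_table(frame: pd.DataFrame, path) -> Path:
    """CSV with header, one row per record, empty cell = missing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_mesh(mesh: TetMesh, nodes_path, elements_path):
    nodes = pd.DataFrame(mesh.nodes, columns=["x", "y", "z"])
    nodes.insert(0, "id", np.arange(len(nodes)))
    elems = pd.DataFrame(mesh.elements, columns=["n1", "n2", "n3", "n4"])
    elems.insert(0, "id", np.arange(len(elems)))
    if mesh.cdr_error is not None:
        elems["cdr_error"] = mesh.cdr_error
    if mesh.cdr_correct is not None:
        elems["cdr_correct"] = mesh.cdr_correct
    write_table(nodes, nodes_path)
    write_table(elems, elements_path)


def read_mesh(nodes_path, elements_path) -> TetMesh:
    nodes = pd.read_csv(nodes_path).sort_values("id")
    elems = pd.read_csv(elements_path).sort_values("id")
    return TetMesh(
        nodes[["x", "y", "z"]].to_numpy(float),
        elems[["n1", "n2", "n3", "n4"]].to_numpy(int),
        cdr_error=elems["cdr_error"].to_numpy(float)
        if "cdr_error" in elems else None,
        cdr_correct=elems["cdr_correct"].to_numpy(float)
        if "cdr_correct" in elems else None,
    )


def write_volume(vol: ContrastVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.Nifti1Image(vol.data.astype(np.float32), vol.affine).to_filename(
        str(path))
    return path


def read_volume(path) -> ContrastVolume:
    img = nib.load(str(path))
    return ContrastVolume(np.asarray(img.dataobj, dtype=float), img.affine)


def write_mask(mask: ROIMaskVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.Nifti1Image(mask.labels.astype(np.int16), mask.affine).to_filename(
        str(path))
    return path


def read_mask(path) -> ROIMaskVolume:
    img = nib.load(str(path))
    return ROIMaskVolume(np.asarray(img.dataobj, dtype=np.int16), img.affine)


class EpochWriter:
    """Streams per-subject/wave epoch sets into one HDF5 container.

    Layout: ``/<subject>/<wave>/{data, time_ms, channel_names, condition}``
    with ``data`` shaped (channels, time, trials).
    """

    def __init__(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self._h5 = h5py.File(path, "w")

    def write(self, subject: str, wave: str, epochs: EpochSet):
        grp = self._h5.require_group(subject).create_group(wave)
        grp.create_dataset("data", data=epochs.data, dtype="f4")
        grp.create_dataset("time_ms", data=epochs.time_ms)
        grp.attrs["sampling_rate"] = epochs.sampling_rate
        str_dt = h5py.string_dtype()
        grp.create_dataset("channel_names",
                           data=np.array(epochs.channels, dtype=str_dt))
        grp.create_dataset("condition",
                           data=np.array(epochs.condition, dtype=str_dt))

    def close(self):
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_epochs(path, subject: str, wave: str) -> EpochSet:
    with h5py.File(path, "r") as h5:
        grp = h5[subject][wave]
        return EpochSet(
            float(grp.attrs["sampling_rate"]),
            grp["time_ms"][()],
            tuple(s.decode() if isinstance(s, bytes) else str(s)
                  for s in grp["channel_names"][()]),
            grp["data"][()].astype(float),
            np.array([s.decode() if isinstance(s, bytes) else str(s)
                      for s in grp["condition"][()]]),
        )


def list_epoch_keys(path):
    with h5py.File(path, "r") as h5:
        return [(s, w) for s in h5 for w in h5[s]]


def tidy_to_wide(tidy: pd.DataFrame) -> pd.DataFrame:
    """Tidy ROI score table to one row per subject, column ``{m}_{r}_{wave}``."""
    out = tidy.pivot_table(index="subject", values="score",
                           columns=["modality", "region", "wave"],
                           aggfunc="first", dropna=False)
    out.columns = [f"{m}_{r}_{w}" for m, r, w in out.columns]
    return out.reset_index().rename(columns={"subject": "subject_id"})
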