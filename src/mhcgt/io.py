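"""Dataset serialization: CSV dialect and an HDF5 container.

CSV schema (UTF-8, header required)::

    sample_id, species, year, month, b400.0, b404.8, ..., b1000.0

One row per record; band columns are named by the band center rounded to
one decimal. The HDF5 container mirrors the same schema for large N.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .dataset import SPECIES, SpectralDataset, WavelengthGrid

__all__ = ["read_dataset", "write_dataset"]

_META_COLUMNS = ["sample_id", "species", "year", "month"]


class DatasetFormatError(ValueError):
    """Raised when a serialized dataset violates the schema."""


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "hdf5"):
            raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'hdf5'")
        return fmt
    ext = os.path.splitext(path)[1].lower()
    return "hdf5" if ext in (".h5", ".hdf5") else "csv"


def write_dataset(ds: SpectralDataset, path: str, fmt: str | None = None) -> None:
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        frame = pd.DataFrame(
            {
                "sample_id": ds.ids,
                "species": [ds.class_names[l - 1] for l in ds.labels],
                "year": ds.years,
                "month": ds.months,
            }
        )
        bands = pd.DataFrame(ds.data[:, :, 0], columns=ds.grid.band_names())
        pd.concat([frame, bands], axis=1).to_csv(path, index=False)
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=ds.data)
            f.create_dataset("labels", data=ds.labels)
            f.create_dataset("years", data=ds.years)
            str_dt = h5py.string_dtype("utf-8")
            f.create_dataset("months", data=[str(m) for m in ds.months], dtype=str_dt)
            f.create_dataset("ids", data=[str(i) for i in ds.ids], dtype=str_dt)
            f.create_dataset("band_centers", data=ds.grid.band_centers)
            f.attrs["class_names"] = list(ds.class_names)


def read_dataset(
    path: str,
    fmt: str | None = None,
    class_names: tuple[str, ...] = SPECIES,
) -> SpectralDataset:
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            return SpectralDataset(
                data=f["data"][...],
                labels=f["labels"][...],
                years=f["years"][...],
                months=np.array([m.decode() for m in f["months"][...]], dtype=object),
                ids=np.array([i.decode() for i in f["ids"][...]], dtype=object),
                grid=WavelengthGrid(f["band_centers"][...]),
                class_names=tuple(f.attrs["class_names"]),
            )

    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DatasetFormatError(f"{path}: no records (empty file)") from None
    if len(frame) == 0:
        raise DatasetFormatError(f"{path}: no records")
    grid = WavelengthGrid()
    expected_bands = grid.band_names()
    missing = [c for c in _META_COLUMNS + expected_bands if c not in frame.columns]
    if missing:
        raise DatasetFormatError(
            f"{path}: missing required column(s): {', '.join(missing[:5])}"
            + (" ..." if len(missing) > 5 else "")
        )
    label_of = {name: i + 1 for i, name in enumerate(class_names)}
    labels = np.empty(len(frame), dtype=np.int64)
    for row, name in enumerate(frame["species"]):
        if name not in label_of:
            raise DatasetFormatError(
                f"{path}: unknown species label {name!r} at data row {row + 1}"
            )
        labels[row] = label_of[name]
    data = frame[expected_bands].to_numpy(dtype=np.float64)[:, :, None]
    return SpectralDataset(
        data=data,
        labels=labels,
        years=frame["year"].to_numpy(dtype=np.int64),
        months=frame["month"].astype(str).to_numpy(dtype=object),
        ids=frame["sample_id"].astype(str).to_numpy(dtype=object),
        grid=grid,
        class_names=class_names,
    )
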