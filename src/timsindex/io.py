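"""Persistence and export.

An :class:`~timsindex.core.IndexedDataset` is saved to a single HDF5 file
holding the CSR event arrays, the three reference axes, the sparse
quadrupole record and scalar metadata.  Loading performs no re-indexing:
arrays come back exactly as stored (bit-exact, with or without
compression), then the dataset invariants are checked.

Event tables, profiles and heatmaps export to CSV; MS/MS spectra grouped
by precursor export to Mascot generic format (MGF).

The HDF5 layout is this package's own (guarded by a ``schema_version``
attribute) and is not interchangeable with other HDF5-based MS formats.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd

from .aggregate import Heatmap2D, Profile1D, spectrum
from .core import (
    AxisSet,
    IndexedDataset,
    QuadIndex,
    SCHEMA_VERSION,
    SparseEventMatrix,
    TimsIndexError,
)
from .slicing import SliceRequest, select_indices

__all__ = [
    "FormatError",
    "SchemaVersionError",
    "save_hdf5",
    "load_hdf5",
    "export_csv",
    "export_mgf",
]


class FormatError(TimsIndexError):
    """A file does not conform to the expected layout."""


class SchemaVersionError(FormatError):
    """The file was written with an incompatible schema version."""


_RAW = ("push_indptr", "tof_indices", "intensities")
_AXES = ("rt_values", "mobility_values", "mz_values")
_QUAD = ("change_indices", "bounds", "precursor_indices")
_META_SCALARS = ("n_frames", "n_scans", "n_tof")


def save_hdf5(ds: IndexedDataset, path, compress: bool = False) -> None:
    """Write a dataset to HDF5.

    With ``compress`` the arrays are stored with gzip (lossless); loading
    always yields bit-identical arrays either way.
    """
    opts = {"compression": "gzip", "compression_opts": 4, "shuffle": True} if compress else {}

    def dset(group, name, data):
        kw = opts if np.asarray(data).size else {}
        group.create_dataset(name, data=data, **kw)

    with h5py.File(path, "w") as fh:
        raw = fh.create_group("raw")
        dset(raw, "push_indptr", ds.matrix.push_indptr)
        dset(raw, "tof_indices", ds.matrix.tof_indices)
        dset(raw, "intensities", ds.matrix.intensities)
        axes = fh.create_group("axes")
        dset(axes, "rt_values", ds.axes.rt_values)
        dset(axes, "mobility_values", ds.axes.mobility_values)
        dset(axes, "mz_values", ds.axes.mz_values)
        quad = fh.create_group("quad")
        dset(quad, "change_indices", ds.quad.quad_change_indices)
        dset(quad, "bounds", ds.quad.quad_bounds)
        dset(quad, "precursor_indices", ds.quad.precursor_indices)
        meta = fh.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        meta.attrs["n_frames"] = ds.n_frames
        meta.attrs["n_scans"] = ds.n_scans
        meta.attrs["n_tof"] = ds.n_tof
        for key, value in ds.meta.items():
            meta.attrs[f"x_{key}"] = str(value)


def load_hdf5(path) -> IndexedDataset:
    """Read a dataset written by :func:`save_hdf5` and verify its invariants.

    Raises :class:`FormatError` naming the first missing dataset or
    attribute, :class:`SchemaVersionError` on a schema mismatch, and the
    usual invariant errors if the stored arrays are inconsistent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as fh:
        for group, names in (("raw", _RAW), ("axes", _AXES), ("quad", _QUAD)):
            if group not in fh:
                raise FormatError(f"missing group {group!r}")
            for name in names:
                if name not in fh[group]:
                    raise FormatError(f"missing dataset '{group}/{name}'")
        if "meta" not in fh:
            raise FormatError("missing group 'meta'")
        attrs = fh["meta"].attrs
        for name in ("schema_version",) + tuple(_META_SCALARS):
            if name not in attrs:
                raise FormatError(f"missing attribute 'meta/{name}'")
        version = str(attrs["schema_version"])
        if version != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"schema version {version!r} != supported {SCHEMA_VERSION!r}"
            )
        meta = {
            key[2:]: str(attrs[key]) for key in attrs if key.startswith("x_")
        }
        return IndexedDataset(
            axes=AxisSet(
                rt_values=fh["axes/rt_values"][...],
                mobility_values=fh["axes/mobility_values"][...],
                mz_values=fh["axes/mz_values"][...],
            ),
            matrix=SparseEventMatrix(
                push_indptr=fh["raw/push_indptr"][...],
                tof_indices=fh["raw/tof_indices"][...],
                intensities=fh["raw/intensities"][...],
            ),
            quad=QuadIndex(
                quad_change_indices=fh["quad/change_indices"][...],
                quad_bounds=fh["quad/bounds"][...],
                precursor_indices=fh["quad/precursor_indices"][...],
            ),
            n_frames=int(attrs["n_frames"]),
            n_scans=int(attrs["n_scans"]),
            n_tof=int(attrs["n_tof"]),
            meta=meta,
        )


def export_csv(obj: Union[pd.DataFrame, Profile1D, Heatmap2D], path) -> None:
    """Write an event table, profile or heatmap as CSV.

    A header row is always present; floats keep full precision and row
    order is deterministic (event tables arrive (push, tof)-ordered,
    profiles axis-ordered, heatmaps in x-major bin order).
    """
    if isinstance(obj, (Profile1D, Heatmap2D)):
        frame = obj.to_frame()
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        raise TypeError(f"cannot export {type(obj).__name__} as CSV")
    frame.to_csv(path, index=False)


def export_mgf(ds: IndexedDataset, path) -> int:
    """Export MS/MS spectra to Mascot generic format, one block per precursor.

    Every distinct precursor index >= 1 yields one BEGIN IONS/END IONS
    block.  PEPMASS is the isolation-window centre (no centroiding or
    feature detection is attempted); RTINSECONDS is the intensity-weighted
    mean retention time of the block's events (or the window's first-push
    RT when the selection is empty); the peak list is the selection's mass
    spectrum in ascending m/z.  Returns the number of blocks written.
    """
    sample = str(ds.meta.get("sample_name", "sample"))
    precursors = np.unique(ds.quad.precursor_indices)
    precursors = precursors[precursors >= 1]
    n_blocks = 0
    with Path(path).open("w") as fh:
        for p in precursors:
            seg = np.flatnonzero(ds.quad.precursor_indices == p)
            low, high = ds.quad.quad_bounds[seg[0]]
            pepmass = float(low + high) / 2.0
            offsets = select_indices(ds, SliceRequest(precursors=[int(p)]))
            if offsets.size:
                frames = ds.frame_of_offset(offsets)
                weights = ds.matrix.intensities[offsets].astype(np.float64)
                rt = float(
                    np.average(ds.axes.rt_values[frames], weights=weights)
                )
            else:
                first_push = int(ds.quad.quad_change_indices[seg[0]])
                rt = float(ds.axes.rt_values[first_push // ds.n_scans])
            prof = spectrum(ds, SliceRequest(precursors=[int(p)]))
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sample}.{int(p)}\n")
            fh.write(f"PEPMASS={pepmass!r}\n")
            fh.write(f"RTINSECONDS={rt!r}\n")
            for mz, inten in zip(prof.values, prof.intensities):
                fh.write(f"{float(mz)!r} {float(inten)!r}\n")
            fh.write("END IONS\n")
            n_blocks += 1
    return n_blocks
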