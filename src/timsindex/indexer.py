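"""Build an :class:`~timsindex.core.IndexedDataset` from a raw event stream.

The raw stream is the logical content of an acquisition: one record per
detector event (push index, TOF index, intensity) plus the axis metadata
needed to reconstruct physical values, and a separate list of quadrupole
switch events.  Records may arrive in any order; indexing sorts them by
(push, tof), counts events per push and cumulatively sums those counts into
the CSR row pointers.

A plain-text TSV interchange format is provided for feeding streams from
other tools (and for the CLI); parsing is bit-exact for integer columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .core import (
    AxisSet,
    IndexedDataset,
    InvalidCoordinateError,
    InvalidInputError,
    QuadIndex,
    SparseEventMatrix,
    TimsIndexError,
    estimate_mobility_axis,
    estimate_mz_axis,
)

__all__ = [
    "IndexingError",
    "DuplicateEventError",
    "RawEventStream",
    "QuadSwitchEvents",
    "build_index",
    "memory_footprint",
    "write_stream_tsv",
    "read_stream_tsv",
    "write_quad_tsv",
    "read_quad_tsv",
]


class IndexingError(TimsIndexError, ValueError):
    """A stream record is inconsistent with the declared acquisition bounds."""


class DuplicateEventError(IndexingError):
    """Two records share the same (push, tof) coordinate."""


@dataclass
class RawEventStream:
    """Unindexed detector events plus the acquisition header.

    ``pushes``, ``tofs`` and ``intensities`` are parallel arrays, one entry
    per detector event, in arbitrary order.
    """

    pushes: np.ndarray
    tofs: np.ndarray
    intensities: np.ndarray
    n_frames: int
    n_scans: int
    n_tof: int
    rt_values: np.ndarray
    mz_min: float = 100.0
    mz_max: float = 1700.0
    k0_min: float = 0.6
    k0_max: float = 1.6
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.pushes = np.asarray(self.pushes, np.int64)
        self.tofs = np.asarray(self.tofs, np.int64)
        self.intensities = np.asarray(self.intensities, np.int64)
        self.rt_values = np.asarray(self.rt_values, np.float64)
        if not (self.pushes.size == self.tofs.size == self.intensities.size):
            raise InvalidInputError("event arrays must have equal length")
        if self.rt_values.size != self.n_frames:
            raise InvalidInputError(
                f"rt_values has {self.rt_values.size} entries, expected {self.n_frames}"
            )

    @property
    def n_events(self) -> int:
        return self.pushes.size


@dataclass
class QuadSwitchEvents:
    """Quadrupole switch records: (push, low Th, high Th, precursor index).

    Pushes strictly increasing with the first record at push 0; bounds of
    (-1, -1) denote full transmission (MS1, precursor 0).
    """

    pushes: np.ndarray
    lows: np.ndarray
    highs: np.ndarray
    precursors: np.ndarray
    #: frame-local fragments (e.g. one frame's topN schedule) need not start
    #: at push 0; full-run switch lists must.
    full_run: bool = True

    def __post_init__(self):
        self.pushes = np.asarray(self.pushes, np.int64)
        self.lows = np.asarray(self.lows, np.float64)
        self.highs = np.asarray(self.highs, np.float64)
        self.precursors = np.asarray(self.precursors, np.int64)
        n = self.pushes.size
        if not (self.lows.size == self.highs.size == self.precursors.size == n):
            raise InvalidInputError("quad switch arrays must have equal length")
        if n == 0 or (self.full_run and self.pushes[0] != 0):
            raise InvalidInputError("first quad switch record must be at push 0")
        if n > 1 and not np.all(np.diff(self.pushes) > 0):
            raise InvalidInputError("quad switch pushes must be strictly increasing")

    @classmethod
    def ms1_only(cls) -> "QuadSwitchEvents":
        """A single sentinel record at push 0: the whole run is MS1."""
        return cls(np.array([0]), np.array([-1.0]), np.array([-1.0]), np.array([0]))

    @property
    def n_records(self) -> int:
        return self.pushes.size


def build_index(stream: RawEventStream, quad_events: QuadSwitchEvents) -> IndexedDataset:
    """Index a raw event stream into a CSR-backed :class:`IndexedDataset`.

    Events are sorted by (push, tof); per-push event counts are cumulatively
    summed into the row pointer array.  Output is independent of input
    record order.  Duplicate (push, tof) records and coordinates outside
    the declared bounds are hard errors.
    """
    n_pushes = stream.n_frames * stream.n_scans
    pushes, tofs, intens = stream.pushes, stream.tofs, stream.intensities

    for name, arr, bound in (
        ("push", pushes, n_pushes),
        ("tof", tofs, stream.n_tof),
    ):
        bad = np.flatnonzero((arr < 0) | (arr >= bound))
        if bad.size:
            i = int(bad[0])
            raise IndexingError(
                f"record {i}: {name} index {int(arr[i])} outside [0, {bound})"
            )
    bad = np.flatnonzero(intens < 1)
    if bad.size:
        i = int(bad[0])
        raise IndexingError(f"record {i}: intensity {int(intens[i])} < 1")
    if np.any(intens > np.iinfo(np.uint16).max):
        i = int(np.flatnonzero(intens > np.iinfo(np.uint16).max)[0])
        raise IndexingError(
            f"record {i}: intensity {int(intens[i])} exceeds uint16 range"
        )

    order = np.lexsort((tofs, pushes))
    pushes, tofs, intens = pushes[order], tofs[order], intens[order]
    if pushes.size > 1:
        dup = np.flatnonzero((np.diff(pushes) == 0) & (np.diff(tofs) == 0))
        if dup.size:
            i = int(dup[0])
            raise DuplicateEventError(
                f"duplicate detector event at push={int(pushes[i])}, tof={int(tofs[i])}"
            )

    counts = np.bincount(pushes, minlength=n_pushes)
    push_indptr = np.zeros(n_pushes + 1, np.int64)
    np.cumsum(counts, out=push_indptr[1:])

    matrix = SparseEventMatrix(push_indptr, tofs, intens)
    quad = QuadIndex(
        quad_events.pushes,
        np.column_stack([quad_events.lows, quad_events.highs]),
        quad_events.precursors,
    )
    if stream.n_scans == 1:  # degenerate geometry: a single mid-range mobility
        mobility_values = np.array([(stream.k0_min + stream.k0_max) / 2.0])
    else:
        mobility_values = estimate_mobility_axis(
            stream.n_scans, stream.k0_min, stream.k0_max
        )
    axes = AxisSet(
        rt_values=stream.rt_values,
        mobility_values=mobility_values,
        mz_values=estimate_mz_axis(stream.n_tof, stream.mz_min, stream.mz_max),
    )
    return IndexedDataset(
        axes=axes,
        matrix=matrix,
        quad=quad,
        n_frames=stream.n_frames,
        n_scans=stream.n_scans,
        n_tof=stream.n_tof,
        meta=dict(stream.meta),
    )


def memory_footprint(ds: IndexedDataset) -> int:
    """Exact byte count of all arrays in the dataset.

    The event-proportional part (TOF indices + intensities) is exactly
    6 bytes per detector event; pointers and reference axes add a fixed,
    geometry-dependent overhead.
    """
    arrays = [
        ds.matrix.push_indptr,
        ds.matrix.tof_indices,
        ds.matrix.intensities,
        ds.axes.rt_values,
        ds.axes.mobility_values,
        ds.axes.mz_values,
        ds.quad.quad_change_indices,
        ds.quad.quad_bounds,
        ds.quad.precursor_indices,
    ]
    return int(sum(a.nbytes for a in arrays))


def event_bytes(ds: IndexedDataset) -> int:
    """Bytes used by the per-event arrays alone (6 per detector event)."""
    return int(ds.matrix.tof_indices.nbytes + ds.matrix.intensities.nbytes)


# ---------------------------------------------------------------------------
# plain-text interchange format


def write_stream_tsv(stream: RawEventStream, path) -> None:
    """Write a raw event stream as the TSV interchange format.

    Header lines ``#n_frames=``, ``#n_scans=``, ``#n_tof=``,
    ``#mz_range=low,high``, ``#k0_range=low,high``, ``#rt_seconds=v0,v1,...``
    followed by a column header and one ``push\\ttof\\tintensity`` row per
    event.  Integers are written verbatim so re-parsing is bit-exact.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#n_frames={stream.n_frames}\n")
        fh.write(f"#n_scans={stream.n_scans}\n")
        fh.write(f"#n_tof={stream.n_tof}\n")
        fh.write(f"#mz_range={stream.mz_min!r},{stream.mz_max!r}\n")
        fh.write(f"#k0_range={stream.k0_min!r},{stream.k0_max!r}\n")
        fh.write("#rt_seconds=" + ",".join(repr(float(v)) for v in stream.rt_values) + "\n")
        fh.write("push\ttof\tintensity\n")
        np.savetxt(
            fh,
            np.column_stack([stream.pushes, stream.tofs, stream.intensities]),
            fmt="%d",
            delimiter="\t",
        )


def read_stream_tsv(path) -> RawEventStream:
    """Parse the TSV interchange format written by :func:`write_stream_tsv`."""
    path = Path(path)
    header: dict[str, str] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].rstrip("\n").partition("=")
            header[key] = value
            n_header += 1
    required = ["n_frames", "n_scans", "n_tof", "mz_range", "k0_range", "rt_seconds"]
    missing = [k for k in required if k not in header]
    if missing:
        raise InvalidInputError(f"stream TSV missing header line(s): {missing}")
    mz_min, mz_max = (float(v) for v in header["mz_range"].split(","))
    k0_min, k0_max = (float(v) for v in header["k0_range"].split(","))
    rt_values = np.array([float(v) for v in header["rt_seconds"].split(",")])
    data = np.loadtxt(path, dtype=np.int64, skiprows=n_header + 1, ndmin=2)
    if data.size == 0:
        data = data.reshape(0, 3)
    return RawEventStream(
        pushes=data[:, 0],
        tofs=data[:, 1],
        intensities=data[:, 2],
        n_frames=int(header["n_frames"]),
        n_scans=int(header["n_scans"]),
        n_tof=int(header["n_tof"]),
        rt_values=rt_values,
        mz_min=mz_min,
        mz_max=mz_max,
        k0_min=k0_min,
        k0_max=k0_max,
    )


def write_quad_tsv(quad: QuadSwitchEvents, path) -> None:
    """Write quadrupole switch events as a TSV with a column header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("push\tlow\thigh\tprecursor\n")
        for p, lo, hi, pr in zip(quad.pushes, quad.lows, quad.highs, quad.precursors):
            fh.write(f"{int(p)}\t{float(lo)!r}\t{float(hi)!r}\t{int(pr)}\n")


def read_quad_tsv(path) -> QuadSwitchEvents:
    """Parse the quadrupole switch TSV written by :func:`write_quad_tsv`."""
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    if data.size == 0:
        raise InvalidInputError("quad TSV holds no records (need one at push 0)")
    return QuadSwitchEvents(
        pushes=data[:, 0].astype(np.int64),
        lows=data[:, 1],
        highs=data[:, 2],
        precursors=data[:, 3].astype(np.int64),
    )
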