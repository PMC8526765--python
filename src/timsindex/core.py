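"""Domain model for indexed LC-TIMS-Q-TOF data.

An acquisition is a stack of *frames* (one ~100 ms TIMS ramp each, sharing a
retention time), each made of ``n_scans`` *scans* (one ~100 µs TOF pusher
event each, sharing an ion mobility).  A pusher event is globally identified
by its *push index* ``push = scan + frame * n_scans``.  Detector events are
stored as a compressed sparse row (CSR) matrix with push indices as rows and
TOF indices as columns; quadrupole isolation settings are recorded sparsely
at the push indices where they change.

Discrete indices (frame, scan, TOF) convert to continuous physical values
(retention time in seconds, reduced mobility 1/K0 in Vs cm^-2, m/z in Th)
through three reference axes held in :class:`AxisSet`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "TimsIndexError",
    "InvalidCoordinateError",
    "InvalidInputError",
    "AxisSet",
    "SparseEventMatrix",
    "QuadIndex",
    "IndexedDataset",
    "QUAD_SENTINEL",
    "push_index",
    "push_to_frame_scan",
    "closest_index",
    "estimate_mz_axis",
    "estimate_mobility_axis",
]

#: quadrupole bound recorded when no isolation is applied (MS1, full transmission)
QUAD_SENTINEL = -1.0

SCHEMA_VERSION = "1"


class TimsIndexError(Exception):
    """Base class for all errors raised by this package."""


class InvalidCoordinateError(TimsIndexError, ValueError):
    """A frame/scan/push/TOF coordinate is outside its declared bounds."""


class InvalidInputError(TimsIndexError, ValueError):
    """An argument violates a precondition (empty axis, bad range, ...)."""


# ---------------------------------------------------------------------------
# index <-> value conversions


def push_index(frame, scan, n_scans: int):
    """Convert (frame, scan) coordinates to a global push index.

    ``push = scan + frame * n_scans``.  Accepts scalars or numpy arrays.
    """
    frame = np.asarray(frame)
    scan = np.asarray(scan)
    if n_scans < 1:
        raise InvalidCoordinateError(f"n_scans must be >= 1, got {n_scans}")
    if np.any(frame < 0) or np.any(scan < 0):
        raise InvalidCoordinateError("frame and scan indices must be non-negative")
    if np.any(scan >= n_scans):
        raise InvalidCoordinateError(
            f"scan index out of range: max {int(np.max(scan))} >= n_scans={n_scans}"
        )
    out = scan.astype(np.int64) + frame.astype(np.int64) * n_scans
    return out if out.ndim else int(out)


def push_to_frame_scan(push, n_scans: int):
    """Invert :func:`push_index`: return ``(push // n_scans, push % n_scans)``."""
    if n_scans < 1:
        raise InvalidCoordinateError(f"n_scans must be >= 1, got {n_scans}")
    push = np.asarray(push)
    if np.any(push < 0):
        raise InvalidCoordinateError("push index must be non-negative")
    frame = push.astype(np.int64) // n_scans
    scan = push.astype(np.int64) % n_scans
    if frame.ndim:
        return frame, scan
    return int(frame), int(scan)


def closest_index(value, axis: np.ndarray):
    """Index of the axis element nearest ``value`` (O(log n) binary search).

    ``axis`` must be strictly monotone, ascending or descending.  Values
    beyond either end clamp to the first/last index; an exact midpoint
    between two elements resolves to the lower index.  ``value`` may be a
    scalar or an array (vectorised lookup).
    """
    axis = np.asarray(axis, dtype=np.float64)
    if axis.size == 0:
        raise InvalidInputError("axis is empty")
    scalar = np.ndim(value) == 0
    value = np.atleast_1d(np.asarray(value, dtype=np.float64))
    if axis.size == 1:
        out = np.zeros(value.shape, dtype=np.int64)
        return int(out[0]) if scalar else out
    descending = axis[1] < axis[0]
    if descending:
        j = np.searchsorted(-axis, -value, side="left")
    else:
        j = np.searchsorted(axis, value, side="left")
    lo = np.clip(j - 1, 0, axis.size - 1)
    hi = np.clip(j, 0, axis.size - 1)
    pick_lo = np.abs(axis[lo] - value) <= np.abs(axis[hi] - value)
    out = np.where(pick_lo, lo, hi).astype(np.int64)
    return int(out[0]) if scalar else out


def estimate_mz_axis(n_tof: int, mz_min: float, mz_max: float) -> np.ndarray:
    """Estimated m/z value per TOF index.

    TOF flight time scales with sqrt(m/z), so interior points are linearly
    interpolated in sqrt-space between the declared acquisition bounds.
    This is an estimation, not a vendor calibration.
    """
    if n_tof < 2:
        raise InvalidInputError(f"n_tof must be >= 2, got {n_tof}")
    if not (0 < mz_min < mz_max):
        raise InvalidInputError(f"need 0 < mz_min < mz_max, got ({mz_min}, {mz_max})")
    mz = np.linspace(np.sqrt(mz_min), np.sqrt(mz_max), n_tof) ** 2
    mz[0] = mz_min
    mz[-1] = mz_max
    return mz


def estimate_mobility_axis(n_scans: int, k0_min: float, k0_max: float) -> np.ndarray:
    """Estimated 1/K0 value per scan index, descending (scan 0 = highest 1/K0).

    TIMS elutes high-mobility-parameter ions first, so the axis decreases
    linearly from ``k0_max`` at scan 0 to ``k0_min`` at the last scan.
    """
    if n_scans < 2:
        raise InvalidInputError(f"n_scans must be >= 2, got {n_scans}")
    if not (0 < k0_min < k0_max):
        raise InvalidInputError(f"need 0 < k0_min < k0_max, got ({k0_min}, {k0_max})")
    return np.linspace(k0_max, k0_min, n_scans)


# ---------------------------------------------------------------------------
# container types


def _strictly_increasing(a: np.ndarray) -> bool:
    return bool(np.all(np.diff(a) > 0))


@dataclass(frozen=True)
class AxisSet:
    """The three continuous reference axes of a dataset.

    rt_values
        Retention time (s) per frame index; strictly increasing, >= 0.
    mobility_values
        1/K0 (Vs cm^-2) per scan index; strictly decreasing.
    mz_values
        m/z (Th) per TOF index; strictly increasing, positive.
    """

    rt_values: np.ndarray
    mobility_values: np.ndarray
    mz_values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rt_values", np.asarray(self.rt_values, np.float64))
        object.__setattr__(
            self, "mobility_values", np.asarray(self.mobility_values, np.float64)
        )
        object.__setattr__(self, "mz_values", np.asarray(self.mz_values, np.float64))
        if self.rt_values.size == 0 or self.rt_values[0] < 0:
            raise InvalidInputError("rt_values must be non-empty with rt_values[0] >= 0")
        if not _strictly_increasing(self.rt_values):
            raise InvalidInputError("rt_values must be strictly increasing")
        if self.mobility_values.size and not np.all(np.diff(self.mobility_values) < 0):
            raise InvalidInputError("mobility_values must be strictly decreasing")
        if not _strictly_increasing(self.mz_values) or np.any(self.mz_values <= 0):
            raise InvalidInputError("mz_values must be strictly increasing and positive")


@dataclass(frozen=True)
class SparseEventMatrix:
    """CSR intensity matrix: push indices as rows, TOF indices as columns.

    A single detector event occupies exactly 6 bytes: a uint32 TOF index
    plus a uint16 intensity.  ``push_indptr`` (int64, length n_pushes + 1)
    delimits each push's events; within a push the TOF indices are strictly
    increasing and all stored intensities are non-zero.
    """

    push_indptr: np.ndarray
    tof_indices: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "push_indptr", np.asarray(self.push_indptr, np.int64))
        object.__setattr__(self, "tof_indices", np.asarray(self.tof_indices, np.uint32))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, np.uint16))
        indptr = self.push_indptr
        if indptr.size < 1 or indptr[0] != 0:
            raise InvalidInputError("push_indptr must start with 0")
        if np.any(np.diff(indptr) < 0):
            raise InvalidInputError("push_indptr must be non-decreasing")
        n_events = self.tof_indices.size
        if self.intensities.size != n_events:
            raise InvalidInputError("tof_indices and intensities differ in length")
        if indptr[-1] != n_events:
            raise InvalidInputError(
                f"push_indptr[-1]={indptr[-1]} does not match n_events={n_events}"
            )
        if np.any(self.intensities == 0):
            raise InvalidInputError("zero-intensity events are never stored")
        # strictly increasing TOF indices within each push: global diff is
        # allowed to reset only at push boundaries
        if n_events > 1:
            tof = self.tof_indices.astype(np.int64)
            bad = np.flatnonzero(np.diff(tof) <= 0) + 1
            starts = indptr[1:-1]  # positions where a new push may begin
            if bad.size and not np.all(np.isin(bad, starts)):
                raise InvalidInputError("tof_indices not strictly increasing within a push")

    @property
    def n_pushes(self) -> int:
        return self.push_indptr.size - 1

    @property
    def n_events(self) -> int:
        return int(self.push_indptr[-1])


@dataclass(frozen=True)
class QuadIndex:
    """Sparse record of quadrupole setting changes.

    ``quad_change_indices`` holds the push indices at which the isolation
    window changes (first entry 0).  ``quad_bounds`` holds the selected
    (low, high) m/z per change, with the sentinel (-1, -1) meaning full
    transmission (MS1).  ``precursor_indices`` identifies each selection;
    0 means MS1 and corresponds exactly to sentinel bounds.
    """

    quad_change_indices: np.ndarray
    quad_bounds: np.ndarray
    precursor_indices: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "quad_change_indices", np.asarray(self.quad_change_indices, np.int64)
        )
        object.__setattr__(self, "quad_bounds", np.asarray(self.quad_bounds, np.float64))
        object.__setattr__(
            self, "precursor_indices", np.asarray(self.precursor_indices, np.int64)
        )
        qci = self.quad_change_indices
        if qci.size == 0 or qci[0] != 0:
            raise InvalidInputError("quad_change_indices must start at push 0")
        if not _strictly_increasing(qci) and qci.size > 1:
            raise InvalidInputError("quad_change_indices must be strictly increasing")
        if self.quad_bounds.shape != (qci.size, 2):
            raise InvalidInputError("quad_bounds must have shape (n_quad, 2)")
        if self.precursor_indices.shape != (qci.size,):
            raise InvalidInputError("precursor_indices must have length n_quad")
        if np.any(self.precursor_indices < 0):
            raise InvalidInputError("precursor_indices must be non-negative")
        low, high = self.quad_bounds[:, 0], self.quad_bounds[:, 1]
        sentinel = low == QUAD_SENTINEL
        if np.any(sentinel != (high == QUAD_SENTINEL)):
            raise InvalidInputError("sentinel bounds must be (-1, -1) in both columns")
        if np.any(low[~sentinel] > high[~sentinel]):
            raise InvalidInputError("non-sentinel quad bounds must satisfy low <= high")
        if np.any(sentinel != (self.precursor_indices == 0)):
            raise InvalidInputError("precursor index 0 iff sentinel bounds")

    @property
    def n_quad(self) -> int:
        return self.quad_change_indices.size


@dataclass
class IndexedDataset:
    """A fully indexed acquisition: the object all accession operates on.

    Behaves as a sparse four-dimensional matrix over (frame, scan,
    quadrupole, TOF) with intensity as the stored value.  ``n_pushes`` is
    always ``n_frames * n_scans``; the frame/scan <-> push relation is
    bijective, so no frame-scan matrix is ever materialised.
    """

    axes: AxisSet
    matrix: SparseEventMatrix
    quad: QuadIndex
    n_frames: int
    n_scans: int
    n_tof: int
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.axes.rt_values.size != self.n_frames:
            raise InvalidInputError(
                f"len(rt_values)={self.axes.rt_values.size} != n_frames={self.n_frames}"
            )
        if self.axes.mobility_values.size != self.n_scans:
            raise InvalidInputError(
                f"len(mobility_values)={self.axes.mobility_values.size}"
                f" != n_scans={self.n_scans}"
            )
        if self.axes.mz_values.size != self.n_tof:
            raise InvalidInputError(
                f"len(mz_values)={self.axes.mz_values.size} != n_tof={self.n_tof}"
            )
        if self.matrix.n_pushes != self.n_frames * self.n_scans:
            raise InvalidInputError(
                f"n_pushes={self.matrix.n_pushes} != n_frames*n_scans="
                f"{self.n_frames * self.n_scans}"
            )
        if self.matrix.n_events and int(self.matrix.tof_indices.max()) >= self.n_tof:
            raise InvalidCoordinateError(
                f"max tof index {int(self.matrix.tof_indices.max())} >= n_tof={self.n_tof}"
            )
        if np.any(self.quad.quad_change_indices >= self.matrix.n_pushes):
            raise InvalidCoordinateError("quad change index beyond last push")

    @property
    def n_pushes(self) -> int:
        return self.matrix.n_pushes

    @property
    def n_events(self) -> int:
        return self.matrix.n_events

    def frame_of_offset(self, offsets: np.ndarray) -> np.ndarray:
        """Frame index of each event offset into the event arrays."""
        return self.push_of_offset(offsets) // self.n_scans

    def push_of_offset(self, offsets: np.ndarray) -> np.ndarray:
        """Push index of each event offset into the event arrays."""
        return (
            np.searchsorted(self.matrix.push_indptr, np.asarray(offsets), side="right")
            - 1
        )

    def copy(self) -> "IndexedDataset":
        return dataclasses.replace(self, meta=dict(self.meta))
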