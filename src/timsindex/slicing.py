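"""Multidimensional accession of an indexed dataset.

A selection runs simultaneously over six dimensions — LC (frame/retention
time), TIMS (scan/mobility), quadrupole m/z, precursor index, TOF m/z and
detector intensity — and returns the exact set of detector events matching
all of them.  The algorithm mirrors the index structure:

1. frame and scan selections become push indices through the bijection
   ``push = scan + frame * n_scans`` (no searching);
2. quadrupole and precursor selections are resolved with a single linear
   pass over the sparse quadrupole arrays, then intersected with the
   selected pushes;
3. the TOF range is located with one binary search per surviving push
   (the TOF indices are sorted within each push);
4. intensity bounds are applied in one pass over the candidate events.

Per-push work is therefore independent of the total number of detector
events in the dataset.

Selector convention (shared with the CLI): an integer is an index, a
decimal number is a physical value (retention time, 1/K0 or m/z) that is
converted to the closest index by binary search.  Value ranges are
half-open ``[start, stop)``.  Use :class:`ValueRange` / :class:`IndexRange`
to override the dispatch explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from numba import njit

from .core import (
    IndexedDataset,
    InvalidInputError,
    QUAD_SENTINEL,
    closest_index,
)

__all__ = [
    "ValueRange",
    "IndexRange",
    "SliceRequest",
    "SliceStats",
    "resolve_selector",
    "select",
    "select_indices",
    "EVENT_TABLE_COLUMNS",
]

EVENT_TABLE_COLUMNS = [
    "push_index",
    "frame_index",
    "scan_index",
    "tof_index",
    "rt",
    "mobility",
    "mz",
    "quad_low",
    "quad_high",
    "precursor_index",
    "intensity",
]


@dataclass(frozen=True)
class ValueRange:
    """Half-open physical-value range [start, stop) on an axis dimension."""

    start: float
    stop: float


@dataclass(frozen=True)
class IndexRange:
    """Half-open index range [start, stop) with an optional step >= 1."""

    start: int
    stop: int
    step: int = 1


Selector = Union[None, int, float, tuple, slice, ValueRange, IndexRange]


@dataclass(frozen=True)
class SliceRequest:
    """A simultaneous selection over all dimensions; defaults select everything.

    ``frames``/``scans``/``tof`` accept a single index (int), a single value
    (float), an (start, stop[, step]) tuple or slice with the int/float
    dispatch applied per bound, or explicit :class:`IndexRange` /
    :class:`ValueRange`.  ``quad`` and ``intensity`` are half-open value
    ranges (never index-converted); ``precursors`` is a set of precursor
    indices.
    """

    frames: Selector = None
    scans: Selector = None
    tof: Selector = None
    quad: Optional[tuple] = None
    precursors: Optional[Iterable[int]] = None
    intensity: Optional[tuple] = None


@dataclass
class SliceStats:
    """Instrumentation counters for the accession algorithm."""

    pushes_selected: int = 0
    tof_binary_searches: int = 0
    quad_linear_passes: int = 0


def _is_int(x) -> bool:
    return isinstance(x, (int, np.integer)) and not isinstance(x, bool)


def _bound_to_index(bound, axis, descending: bool):
    """Resolve one selector bound: int -> index (clamped), float -> closest index."""
    if _is_int(bound):
        return int(np.clip(bound, 0, axis.size)), "index"
    if isinstance(bound, (float, np.floating)):
        return int(closest_index(float(bound), axis)), "value"
    raise InvalidInputError(f"selector bound must be int or float, got {bound!r}")


def resolve_selector(sel: Selector, axis: np.ndarray, *, step_allowed: bool = True):
    """Resolve a dimension selector to an ascending index range (start, stop, step).

    Value bounds are converted with closest-index semantics; on a descending
    axis (mobility) the converted bounds are swapped so the returned index
    range is ascending.  An empty selection (start >= stop after conversion)
    is returned as-is, never an error.
    """
    axis = np.asarray(axis)
    n = axis.size
    descending = n > 1 and axis[1] < axis[0]
    if sel is None:
        return (0, n, 1)
    if isinstance(sel, IndexRange):
        if sel.step < 1:
            raise InvalidInputError(f"step must be >= 1, got {sel.step}")
        return (max(int(sel.start), 0), min(int(sel.stop), n), int(sel.step))
    if isinstance(sel, ValueRange):
        sel = (float(sel.start), float(sel.stop))
    if _is_int(sel):
        if not 0 <= sel < n:
            raise InvalidInputError(f"index {sel} out of range [0, {n})")
        return (int(sel), int(sel) + 1, 1)
    if isinstance(sel, (float, np.floating)):
        i = int(closest_index(float(sel), axis))
        return (i, i + 1, 1)
    if isinstance(sel, slice):
        sel = (
            sel.start if sel.start is not None else 0,
            sel.stop if sel.stop is not None else n,
            *(() if sel.step is None else (sel.step,)),
        )
    if isinstance(sel, tuple):
        if len(sel) == 3:
            start, stop, step = sel
            if not (_is_int(start) and _is_int(stop)):
                raise InvalidInputError("value ranges have no step")
        elif len(sel) == 2:
            (start, stop), step = sel, 1
        else:
            raise InvalidInputError(f"selector tuple must have 2 or 3 items: {sel!r}")
        if not _is_int(step) or step < 1:
            raise InvalidInputError(f"step must be an integer >= 1, got {step!r}")
        if not step_allowed and step != 1:
            raise InvalidInputError("step is not supported for this dimension")
        i0, kind0 = _bound_to_index(start, axis, descending)
        i1, kind1 = _bound_to_index(stop, axis, descending)
        if descending and (kind0 == "value" or kind1 == "value"):
            if kind0 != kind1:
                raise InvalidInputError(
                    "cannot mix index and value bounds on a descending axis"
                )
            i0, i1 = i1, i0  # swap so the index range ascends
        return (i0, max(i1, i0), int(step))
    raise InvalidInputError(f"unsupported selector: {sel!r}")


# ---------------------------------------------------------------------------
# numba kernel: per-push binary searches for the TOF range


@njit(cache=True)
def _tof_range_offsets(starts, ends, tof_indices, tof_lo, tof_hi):  # pragma: no cover
    n = starts.size
    los = np.empty(n, np.int64)
    counts = np.empty(n, np.int64)
    total = 0
    for i in range(n):
        s, e = starts[i], ends[i]
        seg = tof_indices[s:e]
        lo = s + np.searchsorted(seg, tof_lo, side="left")
        hi = s + np.searchsorted(seg, tof_hi, side="left")
        los[i] = lo
        counts[i] = hi - lo
        total += hi - lo
    out = np.empty(total, np.int64)
    k = 0
    for i in range(n):
        for j in range(los[i], los[i] + counts[i]):
            out[k] = j
            k += 1
    return out


def _concat_ranges(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Concatenate [starts[i], ends[i]) ranges without a Python loop."""
    lens = ends - starts
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, np.int64)
    shifts = np.zeros(lens.size, np.int64)
    np.cumsum(lens[:-1], out=shifts[1:])
    return np.repeat(starts - shifts, lens) + np.arange(total, dtype=np.int64)


def _quad_segment_mask(ds: IndexedDataset, quad, precursors) -> np.ndarray:
    """One linear pass over the quadrupole arrays: which segments match.

    A non-sentinel window [low, high) matches a quad value range [a, b)
    when the two overlap; sentinel (MS1) windows match only when no quad
    range is given or the range starts at or below the sentinel.
    """
    low = ds.quad.quad_bounds[:, 0]
    high = ds.quad.quad_bounds[:, 1]
    sentinel = low == QUAD_SENTINEL
    mask = np.ones(ds.quad.n_quad, dtype=bool)
    if quad is not None:
        a, b = float(quad[0]), float(quad[1])
        if a > b:
            raise InvalidInputError(f"quad range start {a} > stop {b}")
        overlap = (~sentinel) & (low < b) & (a < high)
        if a <= QUAD_SENTINEL:
            overlap |= sentinel
        mask &= overlap
    if precursors is not None:
        wanted = np.asarray(sorted(set(int(p) for p in precursors)), np.int64)
        mask &= np.isin(ds.quad.precursor_indices, wanted)
    return mask


def select_indices(
    ds: IndexedDataset,
    req: SliceRequest = SliceRequest(),
    stats: Optional[SliceStats] = None,
) -> np.ndarray:
    """Offsets (into the event arrays) of every event matching the request.

    Offsets come back ascending, i.e. ordered by (push, tof).
    """
    f0, f1, fstep = resolve_selector(req.frames, ds.axes.rt_values)
    s0, s1, sstep = resolve_selector(req.scans, ds.axes.mobility_values)
    t0, t1, _ = resolve_selector(req.tof, ds.axes.mz_values, step_allowed=False)

    frames = np.arange(f0, f1, fstep, dtype=np.int64)
    scans = np.arange(s0, s1, sstep, dtype=np.int64)
    if frames.size == 0 or scans.size == 0 or t0 >= t1:
        return np.empty(0, np.int64)
    pushes = (frames[:, None] * ds.n_scans + scans[None, :]).ravel()

    seg_mask = _quad_segment_mask(ds, req.quad, req.precursors)
    if stats is not None:
        stats.quad_linear_passes += 1
    if not seg_mask.all():
        seg_of_push = (
            np.searchsorted(ds.quad.quad_change_indices, pushes, side="right") - 1
        )
        pushes = pushes[seg_mask[seg_of_push]]

    indptr = ds.matrix.push_indptr
    starts = indptr[pushes]
    ends = indptr[pushes + 1]
    if stats is not None:
        stats.pushes_selected += int(pushes.size)

    full_tof = t0 == 0 and t1 >= ds.n_tof
    if full_tof:
        nonempty = starts < ends
        offsets = _concat_ranges(starts[nonempty], ends[nonempty])
    else:
        offsets = _tof_range_offsets(
            starts, ends, ds.matrix.tof_indices, np.uint32(t0), np.uint32(t1)
        )
        if stats is not None:
            stats.tof_binary_searches += int(starts.size)

    if req.intensity is not None:
        lo, hi = req.intensity
        v = ds.matrix.intensities[offsets]
        offsets = offsets[(v >= lo) & (v < hi)]
    return offsets


def select(
    ds: IndexedDataset,
    req: SliceRequest = SliceRequest(),
    stats: Optional[SliceStats] = None,
) -> pd.DataFrame:
    """Resolve a request into an event table (one row per detector event).

    Columns carry both the discrete indices and the corresponding physical
    values, plus the quadrupole window and precursor active at each event's
    push.  Rows are ordered by (push, tof).
    """
    offsets = select_indices(ds, req, stats=stats)
    return events_at(ds, offsets)


def events_at(ds: IndexedDataset, offsets: np.ndarray) -> pd.DataFrame:
    """Materialise an event table for the given event-array offsets."""
    offsets = np.asarray(offsets, np.int64)
    push = ds.push_of_offset(offsets)
    frame = push // ds.n_scans
    scan = push % ds.n_scans
    tof = ds.matrix.tof_indices[offsets].astype(np.int64)
    seg = np.searchsorted(ds.quad.quad_change_indices, push, side="right") - 1
    return pd.DataFrame(
        {
            "push_index": push,
            "frame_index": frame,
            "scan_index": scan,
            "tof_index": tof,
            "rt": ds.axes.rt_values[frame],
            "mobility": ds.axes.mobility_values[scan],
            "mz": ds.axes.mz_values[tof],
            "quad_low": ds.quad.quad_bounds[seg, 0],
            "quad_high": ds.quad.quad_bounds[seg, 1],
            "precursor_index": ds.quad.precursor_indices[seg],
            "intensity": ds.matrix.intensities[offsets].astype(np.int64),
        },
        columns=EVENT_TABLE_COLUMNS,
    )
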