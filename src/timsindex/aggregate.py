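"""Projections of selections onto one or two axes.

These are the computations behind the classic LC-MS visualisations: total
ion current (TIC) and extracted ion chromatograms (XIC) over frames, mass
spectra over TOF indices, ion mobilograms over scans, and binned 2D
heatmaps over any pair of physical axes.  All aggregations conserve the
total intensity of their input selection and are order-invariant.

``qc_tic_drop`` formalises the visual quality-control check of spotting a
temporary loss of ion current: frames whose rolling-median TIC falls below
a fraction of the run's global median are flagged as contiguous ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import IndexedDataset, InvalidInputError, QUAD_SENTINEL
from .slicing import SliceRequest, ValueRange, select_indices

__all__ = [
    "Profile1D",
    "Heatmap2D",
    "tic",
    "xic",
    "spectrum",
    "mobilogram",
    "heatmap",
    "qc_tic_drop",
]

_AXIS_NAMES = ("rt", "mobility", "mz")


@dataclass(frozen=True)
class Profile1D:
    """Summed intensity along one axis.

    ``indices`` are the axis elements represented (all of them for dense
    profiles such as the TIC, only the occupied ones for sparse profiles
    such as a mass spectrum); ``values`` are their physical axis values and
    ``intensities`` the per-element intensity sums.
    """

    axis: str
    indices: np.ndarray
    values: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        if self.axis not in _AXIS_NAMES:
            raise InvalidInputError(f"axis must be one of {_AXIS_NAMES}")
        if not (self.indices.size == self.values.size == self.intensities.size):
            raise InvalidInputError("profile arrays must have equal length")

    @property
    def total(self) -> float:
        return float(self.intensities.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"index": self.indices, self.axis: self.values, "intensity": self.intensities}
        )


@dataclass(frozen=True)
class Heatmap2D:
    """Intensities of a selection summed into a 2D grid of physical-value bins.

    Bins are half-open with the last bin closed; the matrix total equals
    the total intensity of the underlying selection.
    """

    x_axis: str
    y_axis: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    matrix: np.ndarray

    @property
    def total(self) -> float:
        return float(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per bin with its edges and summed intensity."""
        nx, ny = self.matrix.shape
        xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        return pd.DataFrame(
            {
                f"{self.x_axis}_lo": self.x_edges[xi.ravel()],
                f"{self.x_axis}_hi": self.x_edges[xi.ravel() + 1],
                f"{self.y_axis}_lo": self.y_edges[yi.ravel()],
                f"{self.y_axis}_hi": self.y_edges[yi.ravel() + 1],
                "intensity": self.matrix.ravel(),
            }
        )


def _per_push_sums(ds: IndexedDataset) -> np.ndarray:
    csum = np.zeros(ds.n_events + 1, np.float64)
    np.cumsum(ds.matrix.intensities, out=csum[1:])
    indptr = ds.matrix.push_indptr
    return csum[indptr[1:]] - csum[indptr[:-1]]


def tic(ds: IndexedDataset, ms1_only: bool = False) -> Profile1D:
    """Total ion current: summed intensity per frame, over all frames.

    With ``ms1_only`` the sum is restricted to pushes under a sentinel
    (full-transmission) quadrupole window.
    """
    sums = _per_push_sums(ds)
    if ms1_only:
        seg = (
            np.searchsorted(
                ds.quad.quad_change_indices, np.arange(ds.n_pushes), side="right"
            )
            - 1
        )
        sums = sums * (ds.quad.quad_bounds[seg, 0] == QUAD_SENTINEL)
    per_frame = sums.reshape(ds.n_frames, ds.n_scans).sum(axis=1)
    return Profile1D(
        axis="rt",
        indices=np.arange(ds.n_frames, dtype=np.int64),
        values=ds.axes.rt_values,
        intensities=per_frame,
    )


def _frame_profile(ds: IndexedDataset, offsets: np.ndarray) -> Profile1D:
    frames = ds.frame_of_offset(offsets)
    sums = np.bincount(
        frames, weights=ds.matrix.intensities[offsets], minlength=ds.n_frames
    )
    return Profile1D(
        axis="rt",
        indices=np.arange(ds.n_frames, dtype=np.int64),
        values=ds.axes.rt_values,
        intensities=sums,
    )


def xic(
    ds: IndexedDataset,
    mz_range: Optional[tuple] = None,
    mobility_range: Optional[tuple] = None,
    quad: Optional[tuple] = None,
    precursors=None,
) -> Profile1D:
    """Extracted ion chromatogram: per-frame summed intensity of a selection.

    With all ranges left open this degenerates to the TIC.
    """
    req = SliceRequest(
        tof=ValueRange(*mz_range) if mz_range is not None else None,
        scans=ValueRange(*mobility_range) if mobility_range is not None else None,
        quad=quad,
        precursors=precursors,
    )
    return _frame_profile(ds, select_indices(ds, req))


def spectrum(ds: IndexedDataset, req: SliceRequest = SliceRequest()) -> Profile1D:
    """Mass spectrum of a selection: intensity summed per occupied TOF index."""
    offsets = select_indices(ds, req)
    tofs = ds.matrix.tof_indices[offsets].astype(np.int64)
    uniq, inverse = np.unique(tofs, return_inverse=True)
    sums = np.bincount(inverse, weights=ds.matrix.intensities[offsets])
    if uniq.size == 0:
        sums = np.empty(0, np.float64)
    return Profile1D(
        axis="mz", indices=uniq, values=ds.axes.mz_values[uniq], intensities=sums
    )


def mobilogram(ds: IndexedDataset, req: SliceRequest = SliceRequest()) -> Profile1D:
    """Ion mobilogram of a selection: intensity summed per scan, over all scans."""
    offsets = select_indices(ds, req)
    scans = ds.push_of_offset(offsets) % ds.n_scans
    sums = np.bincount(
        scans, weights=ds.matrix.intensities[offsets], minlength=ds.n_scans
    )
    return Profile1D(
        axis="mobility",
        indices=np.arange(ds.n_scans, dtype=np.int64),
        values=ds.axes.mobility_values,
        intensities=sums,
    )


def _axis_values(ds: IndexedDataset, dim: str, offsets: np.ndarray, req: SliceRequest):
    """Per-event physical values for one dimension plus the selection's extent."""
    from .slicing import resolve_selector

    if dim == "rt":
        vals = ds.axes.rt_values[ds.frame_of_offset(offsets)]
        lo, hi, step = resolve_selector(req.frames, ds.axes.rt_values)
        axis_slice = ds.axes.rt_values[lo:hi:step]
    elif dim == "mobility":
        vals = ds.axes.mobility_values[ds.push_of_offset(offsets) % ds.n_scans]
        lo, hi, step = resolve_selector(req.scans, ds.axes.mobility_values)
        axis_slice = ds.axes.mobility_values[lo:hi:step]
    elif dim == "mz":
        vals = ds.axes.mz_values[ds.matrix.tof_indices[offsets].astype(np.int64)]
        lo, hi, _ = resolve_selector(req.tof, ds.axes.mz_values, step_allowed=False)
        axis_slice = ds.axes.mz_values[lo:hi]
    else:
        raise InvalidInputError(f"heatmap dimension must be one of {_AXIS_NAMES}")
    if axis_slice.size:
        extent = (float(axis_slice.min()), float(axis_slice.max()))
    else:
        extent = (0.0, 1.0)
    if extent[0] == extent[1]:
        pad = max(abs(extent[0]) * 1e-9, 1e-9)
        extent = (extent[0] - pad, extent[1] + pad)
    return vals, extent


def heatmap(
    ds: IndexedDataset,
    req: SliceRequest = SliceRequest(),
    x_dim: str = "rt",
    y_dim: str = "mz",
    x_bins: int = 100,
    y_bins: int = 100,
) -> Heatmap2D:
    """Sum a selection's intensities into a 2D grid of equal-width value bins.

    Bin edges span the physical extent of the resolved selection in each
    dimension, so every selected event lands in a bin and the matrix total
    equals the selection total.
    """
    if x_dim == y_dim:
        raise InvalidInputError("heatmap x and y dimensions must differ")
    if x_bins < 1 or y_bins < 1:
        raise InvalidInputError("bin counts must be >= 1")
    offsets = select_indices(ds, req)
    weights = ds.matrix.intensities[offsets].astype(np.float64)
    xv, x_extent = _axis_values(ds, x_dim, offsets, req)
    yv, y_extent = _axis_values(ds, y_dim, offsets, req)
    x_edges = np.linspace(*x_extent, x_bins + 1)
    y_edges = np.linspace(*y_extent, y_bins + 1)
    matrix, _, _ = np.histogram2d(xv, yv, bins=[x_edges, y_edges], weights=weights)
    return Heatmap2D(
        x_axis=x_dim,
        y_axis=y_dim,
        x_edges=x_edges,
        y_edges=y_edges,
        matrix=matrix,
    )


def qc_tic_drop(
    profile: Profile1D, window_frames: int, drop_fraction: float
) -> list[tuple[int, int]]:
    """Flag contiguous frame ranges where the TIC collapses.

    A frame is flagged when the centred rolling median (window
    ``window_frames``) of the TIC falls below ``drop_fraction`` times the
    global median.  Returns half-open (start_frame, stop_frame) ranges.
    A run whose global median is zero is degenerate and flagged in full.
    """
    if window_frames < 1:
        raise InvalidInputError(f"window_frames must be >= 1, got {window_frames}")
    if not 0 < drop_fraction < 1:
        raise InvalidInputError(f"drop_fraction must be in (0, 1), got {drop_fraction}")
    values = np.asarray(profile.intensities, np.float64)
    n = values.size
    if n == 0:
        return []
    global_median = float(np.median(values))
    if global_median == 0:
        return [(0, n)]
    rolling = (
        pd.Series(values)
        .rolling(window_frames, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    flagged = rolling < drop_fraction * global_median
    ranges: list[tuple[int, int]] = []
    start = None
    for i, f in enumerate(flagged):
        if f and start is None:
            start = i
        elif not f and start is not None:
            ranges.append((start, i))
            start = None
    if start is not None:
        ranges.append((start, n))
    return ranges
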