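"""Independent oracles and random-request generation for the test suite.

The dense oracle deliberately avoids the package's accession machinery:
it flattens the CSR arrays with ``np.repeat``, resolves value bounds with
an O(n) linear-scan nearest-neighbour lookup, and filters every event with
plain boolean masks.  Agreement between :func:`timsindex.select_indices`
and this oracle is the central correctness check.
"""

from __future__ import annotations

import numpy as np

from timsindex import IndexedDataset, SliceRequest
from timsindex.slicing import IndexRange, ValueRange


def linear_closest(value: float, axis: np.ndarray) -> int:
    """O(n) argmin of |axis - value| with ties resolved to the lower index."""
    d = np.abs(np.asarray(axis, float) - value)
    return int(np.argmin(d))  # argmin returns the first (lowest) minimiser


def oracle_resolve(sel, axis) -> np.ndarray:
    """Resolve a selector to an index array using the linear-scan lookup."""
    axis = np.asarray(axis)
    n = axis.size
    descending = n > 1 and axis[1] < axis[0]
    if sel is None:
        return np.arange(n)
    if isinstance(sel, IndexRange):
        return np.arange(max(sel.start, 0), min(sel.stop, n), sel.step)
    if isinstance(sel, ValueRange):
        sel = (float(sel.start), float(sel.stop))
    if isinstance(sel, (int, np.integer)) and not isinstance(sel, bool):
        return np.array([int(sel)])
    if isinstance(sel, float):
        return np.array([linear_closest(sel, axis)])
    if isinstance(sel, tuple):
        step = sel[2] if len(sel) == 3 else 1
        bounds = []
        for b in sel[:2]:
            if isinstance(b, (int, np.integer)) and not isinstance(b, bool):
                bounds.append(("index", int(np.clip(b, 0, n))))
            else:
                bounds.append(("value", linear_closest(float(b), axis)))
        (k0, i0), (k1, i1) = bounds
        if descending and (k0 == "value" or k1 == "value"):
            i0, i1 = i1, i0
        return np.arange(i0, max(i1, i0), step)
    raise AssertionError(f"oracle cannot resolve {sel!r}")


def flatten_events(ds: IndexedDataset) -> dict:
    """Per-event coordinate arrays built without the accession code path."""
    counts = np.diff(ds.matrix.push_indptr)
    push = np.repeat(np.arange(ds.n_pushes), counts)
    qci = ds.quad.quad_change_indices
    seg_lens = np.diff(np.append(qci, ds.n_pushes))
    seg_of_push = np.repeat(np.arange(qci.size), seg_lens)
    seg = seg_of_push[push]
    return {
        "push": push,
        "frame": push // ds.n_scans,
        "scan": push % ds.n_scans,
        "tof": ds.matrix.tof_indices.astype(np.int64),
        "intensity": ds.matrix.intensities.astype(np.int64),
        "quad_low": ds.quad.quad_bounds[seg, 0],
        "quad_high": ds.quad.quad_bounds[seg, 1],
        "precursor": ds.quad.precursor_indices[seg],
    }


def oracle_select(ds: IndexedDataset, req: SliceRequest, flat: dict | None = None):
    """Dense per-event filter: offsets of all events matching the request."""
    if flat is None:
        flat = flatten_events(ds)
    frames = oracle_resolve(req.frames, ds.axes.rt_values)
    scans = oracle_resolve(req.scans, ds.axes.mobility_values)
    tofs = oracle_resolve(req.tof, ds.axes.mz_values)
    mask = np.isin(flat["frame"], frames)
    mask &= np.isin(flat["scan"], scans)
    if tofs.size:
        mask &= (flat["tof"] >= tofs[0]) & (flat["tof"] <= tofs[-1])
    else:
        mask &= False
    if req.quad is not None:
        a, b = req.quad
        sentinel = flat["quad_low"] == -1.0
        ok = (~sentinel) & (flat["quad_low"] < b) & (flat["quad_high"] > a)
        if a <= -1.0:
            ok |= sentinel
        mask &= ok
    if req.precursors is not None:
        mask &= np.isin(flat["precursor"], np.asarray(list(req.precursors)))
    if req.intensity is not None:
        lo, hi = req.intensity
        mask &= (flat["intensity"] >= lo) & (flat["intensity"] < hi)
    return np.flatnonzero(mask)


def random_request(rng: np.random.Generator, ds: IndexedDataset) -> SliceRequest:
    """Draw a random multidimensional request mixing all selector forms."""

    def axis_selector(axis, allow_step=True):
        kind = rng.integers(0, 5)
        n = axis.size
        if kind == 0:
            return None
        if kind == 1:  # single index
            return int(rng.integers(0, n))
        if kind == 2:  # index range, sometimes stepped (frame/scan only)
            a, b = sorted(rng.integers(0, n, 2).tolist())
            step = int(rng.integers(1, 4))
            if allow_step and rng.random() < 0.5:
                return (int(a), int(b) + 1, step)
            return (int(a), int(b) + 1)
        lo, hi = float(axis.min()), float(axis.max())
        v = rng.uniform(lo, hi, 2)
        if kind == 3:  # single value
            return float(v[0])
        return (float(v.min()), float(v.max()))  # value range

    quad = None
    if rng.random() < 0.4:
        lo = rng.uniform(-2.0, 1100.0)
        quad = (lo, lo + rng.uniform(0.0, 400.0))
    precursors = None
    if rng.random() < 0.3:
        pool = np.unique(ds.quad.precursor_indices)
        precursors = rng.choice(pool, size=min(3, pool.size), replace=False).tolist()
    intensity = None
    if rng.random() < 0.3:
        lo = int(rng.integers(0, 50))
        intensity = (lo, lo + int(rng.integers(1, 200)))
    return SliceRequest(
        frames=axis_selector(ds.axes.rt_values),
        scans=axis_selector(ds.axes.mobility_values),
        tof=axis_selector(ds.axes.mz_values, allow_step=False),
        quad=quad,
        precursors=precursors,
        intensity=intensity,
    )
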