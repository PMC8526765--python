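"""Multidimensional accession: selector resolution, oracle equivalence,
separability, monotonicity and the per-push scaling contract."""

import numpy as np
import pytest

import timsindex as ti
from timsindex.slicing import (
    EVENT_TABLE_COLUMNS,
    IndexRange,
    SliceRequest,
    SliceStats,
    ValueRange,
    events_at,
    resolve_selector,
    select,
    select_indices,
)

from helpers import flatten_events, oracle_select, random_request


class TestResolveSelector:
    def test_rt_value_range(self):
        """100 <= rt < 100.5 on a 0.1 s grid selects frames 1000..1004."""
        axis = np.arange(2000) * 0.1
        assert resolve_selector((100.0, 100.5), axis) == (1000, 1005, 1)

    def test_default_selects_everything(self):
        assert resolve_selector(None, np.arange(10.0)) == (0, 10, 1)

    def test_descending_mobility_range_ascends(self):
        axis = np.linspace(1.6, 0.6, 101)  # 0.01 spacing
        start, stop, step = resolve_selector((0.9, 1.1), axis)
        assert step == 1 and start < stop
        vals = axis[start:stop]
        assert vals.max() <= 1.1 + 1e-9 and vals.min() >= 0.9 - 1e-9

    def test_single_index_and_single_value(self):
        axis = np.arange(10.0)
        assert resolve_selector(4, axis) == (4, 5, 1)
        assert resolve_selector(4.2, axis) == (4, 5, 1)

    def test_integer_bounds_are_indices(self):
        axis = np.arange(100) * 0.1
        assert resolve_selector((10, 20), axis) == (10, 20, 1)
        assert resolve_selector((10, 20, 2), axis) == (10, 20, 2)

    def test_explicit_overrides(self):
        axis = np.arange(100) * 0.1
        assert resolve_selector(ValueRange(1.0, 2.0), axis) == (10, 20, 1)
        assert resolve_selector(IndexRange(10, 20, 3), axis) == (10, 20, 3)

    def test_inverted_range_is_empty_not_error(self):
        axis = np.arange(10.0)
        start, stop, _ = resolve_selector((7.0, 2.0), axis)
        assert start >= stop

    def test_value_range_with_step_rejected(self):
        with pytest.raises(ti.InvalidInputError):
            resolve_selector((1.0, 2.0, 2), np.arange(10.0))


class TestSelectToy:
    def test_default_returns_all_events(self, toy_ds):
        table = select(toy_ds)
        assert len(table) == toy_ds.n_events == 3
        assert list(table.columns) == EVENT_TABLE_COLUMNS
        np.testing.assert_array_equal(table["intensity"], [10, 3, 7])

    def test_rows_carry_axis_values(self, toy_ds):
        table = select(toy_ds)
        np.testing.assert_array_equal(
            table["rt"], toy_ds.axes.rt_values[table["frame_index"]]
        )
        np.testing.assert_array_equal(
            table["mz"], toy_ds.axes.mz_values[table["tof_index"]]
        )

    def test_single_frame(self, toy_ds):
        table = select(toy_ds, SliceRequest(frames=0))
        np.testing.assert_array_equal(table["tof_index"], [5, 9])

    def test_intensity_filter(self, toy_ds):
        table = select(toy_ds, SliceRequest(intensity=(5, 100)))
        np.testing.assert_array_equal(table["intensity"], [10, 7])

    def test_select_indices_consistency(self, toy_ds):
        offsets = select_indices(toy_ds)
        np.testing.assert_array_equal(offsets, np.arange(3))
        table = events_at(toy_ds, offsets)
        np.testing.assert_array_equal(table.values, select(toy_ds).values)


class TestOracleEquivalence:
    def test_scan_slice_matches_oracle(self, dda_ds):
        """A single-scan TIMS slice equals the dense brute-force filter."""
        req = SliceRequest(scans=45)
        got = select(dda_ds, req)
        assert (got["scan_index"] == 45).all()
        np.testing.assert_array_equal(
            select_indices(dda_ds, req), oracle_select(dda_ds, req)
        )

    def test_quad_slice_selects_overlapping_windows(self, dia_ds):
        """700 <= quad m/z < 710 retrieves only the [700, 725) window."""
        req = SliceRequest(quad=(700.0, 710.0))
        got = select(dia_ds, req)
        assert len(got) > 0
        assert set(zip(got["quad_low"], got["quad_high"])) == {(700.0, 725.0)}
        np.testing.assert_array_equal(
            select_indices(dia_ds, req), oracle_select(dia_ds, req)
        )

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_requests_match_oracle(self, dda_ds, dia_ds, seed):
        """Random multidimensional requests agree with the dense filter."""
        rng = np.random.default_rng(seed)
        for ds in (dda_ds, dia_ds):
            flat = flatten_events(ds)
            for _ in range(25):
                req = random_request(rng, ds)
                np.testing.assert_array_equal(
                    select_indices(ds, req), oracle_select(ds, req, flat)
                )

    def test_separability(self, dia_ds):
        """A multidimensional selection equals the intersection of its
        single-dimension selections."""
        req = SliceRequest(
            frames=(5.0, 20.0), scans=(0.8, 1.3), tof=(600.0, 900.0),
            quad=(600.0, 800.0),
        )
        combined = set(select_indices(dia_ds, req))
        parts = [
            set(select_indices(dia_ds, SliceRequest(frames=req.frames))),
            set(select_indices(dia_ds, SliceRequest(scans=req.scans))),
            set(select_indices(dia_ds, SliceRequest(tof=req.tof))),
            set(select_indices(dia_ds, SliceRequest(quad=req.quad))),
        ]
        assert combined == set.intersection(*parts)

    def test_widening_never_removes_rows(self, dda_ds):
        narrow = SliceRequest(frames=(10.0, 12.0), tof=(600.0, 650.0))
        wide = SliceRequest(frames=(8.0, 14.0), tof=(550.0, 700.0))
        assert set(select_indices(dda_ds, narrow)) <= set(select_indices(dda_ds, wide))

    def test_rows_ordered_by_push_then_tof(self, dia_ds):
        table = select(dia_ds, SliceRequest(frames=(0, 50)))
        key = table["push_index"].to_numpy() * dia_ds.n_tof + table["tof_index"].to_numpy()
        assert np.all(np.diff(key) > 0)


class TestQuadSemantics:
    def test_ms1_excluded_by_positive_quad_range(self, dia_ds):
        table = select(dia_ds, SliceRequest(quad=(400.0, 1000.0)))
        assert (table["precursor_index"] >= 1).all()

    def test_ms1_included_when_range_reaches_sentinel(self, dia_ds):
        table = select(dia_ds, SliceRequest(quad=(-1.0, 1000.0)))
        assert (table["precursor_index"] == 0).any()

    def test_precursor_index_set(self, dia_ds):
        table = select(dia_ds, SliceRequest(precursors=[0]))
        assert (table["quad_low"] == -1.0).all()

    def test_narrow_dda_window_matches_wider_query(self, dda_ds):
        """A 2-3 Th dda window inside a 10 Th query range must match."""
        lows = dda_ds.quad.quad_bounds[:, 0]
        real = lows[lows > 0]
        centre = float(real[0] + 1.0)
        table = select(dda_ds, SliceRequest(quad=(centre - 5.0, centre + 5.0)))
        assert len(table) > 0


class TestScalingContract:
    def test_one_binary_search_per_selected_push(self, dda_ds):
        stats = SliceStats()
        req = SliceRequest(frames=(50, 60), tof=(620.0, 630.0))
        select_indices(dda_ds, req, stats=stats)
        assert stats.tof_binary_searches == stats.pushes_selected == 10 * dda_ds.n_scans
        assert stats.quad_linear_passes == 1

    def test_per_push_work_independent_of_event_count(self):
        """The same slice on a 10x denser dataset does identical per-push work."""
        counters = []
        for occupancy in (0.001, 0.01):
            spec = ti.AcquisitionSpec(
                gradient_seconds=5.0, n_scans=50, n_tof=2000,
                noise_occupancy=occupancy, seed=3,
            )
            stream, quad, _ = ti.simulate(spec, [ti.calibrant_species()])
            ds = ti.build_index(stream, quad)
            stats = SliceStats()
            select_indices(
                ds, SliceRequest(frames=(10, 20), tof=(500.0, 600.0)), stats=stats
            )
            counters.append((stats.pushes_selected, stats.tof_binary_searches))
        assert counters[0] == counters[1]
        assert counters[0][0] == counters[0][1] == 10 * 50
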