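"""Acquisition simulator: determinism, ground truth, quad scheduling,
collision energy and injected anomalies."""

import math

import numpy as np
import pytest

import timsindex as ti
from timsindex.simulate import (
    CALIBRANT_IONS,
    AcquisitionSpec,
    AnomalySpec,
    DdaScheme,
    DiaScheme,
    InvalidSpecError,
    Ms1Only,
    SpeciesDefinition,
    calibrant_species,
    collision_energy,
    dda_schedule,
    dia_window_scheme,
    max_events_per_minute,
    simulate,
)


def _small_spec(**kw):
    defaults = dict(
        gradient_seconds=10.0, frames_per_second=5.0, n_scans=40, n_tof=2000,
        noise_occupancy=0.0005, seed=21,
    )
    defaults.update(kw)
    return AcquisitionSpec(**defaults)


class TestDeterminism:
    def test_same_seed_identical_streams(self):
        sp = [calibrant_species(total_intensity=1e5)]
        a = simulate(_small_spec(), sp)
        b = simulate(_small_spec(), sp)
        for x, y in zip(a[0].__dict__.values(), b[0].__dict__.values()):
            if isinstance(x, np.ndarray):
                np.testing.assert_array_equal(x, y)

    def test_distinct_seeds_differ(self):
        sp = [calibrant_species(total_intensity=1e5)]
        a, _, _ = simulate(_small_spec(seed=1), sp)
        b, _, _ = simulate(_small_spec(seed=2), sp)
        assert a.n_events != b.n_events or not np.array_equal(a.tofs, b.tofs)


class TestGroundTruth:
    def test_species_count_matches_emitted_events(self):
        """Per-species ground-truth counts equal what is actually in the stream."""
        spec = _small_spec(noise_occupancy=0.0)
        species = [
            SpeciesDefinition(mz=500.0, apex_rt=5.0, rt_sigma=1.0, apex_k0=1.0,
                              k0_sigma=0.05, total_intensity=2e4, n_isotopes=2),
            SpeciesDefinition(mz=900.0, apex_rt=7.0, rt_sigma=1.0, apex_k0=1.3,
                              k0_sigma=0.05, total_intensity=1e4),
        ]
        stream, _, truth = simulate(spec, species)
        tof_500 = ti.closest_index(  # monoisotope + one isotope at +1/charge
            np.array([500.0, 501.0]), spec.mz_values
        )
        n_500 = int(np.isin(stream.tofs, tof_500).sum())
        assert truth.species_counts[0] == n_500
        assert truth.species_counts.sum() == stream.n_events
        assert truth.noise_count == 0

    def test_calibrant_present_in_every_frame(self):
        """A uniformly eluting calibrant hits the scan nearest 1.3820 Vs cm^-2
        in every frame."""
        spec = _small_spec(noise_occupancy=0.0)
        stream, _, truth = simulate(spec, [calibrant_species(total_intensity=1e6)])
        expected_scan = ti.closest_index(CALIBRANT_IONS[2][1], spec.mobility_values)
        assert truth.apex_scans[0] == expected_scan
        at_scan = stream.pushes[stream.pushes % spec.n_scans == expected_scan]
        frames = np.unique(at_scan // spec.n_scans)
        np.testing.assert_array_equal(frames, np.arange(spec.n_frames))

    def test_species_outside_bounds_rejected(self):
        with pytest.raises(InvalidSpecError):
            simulate(_small_spec(), [SpeciesDefinition(mz=5000.0)])
        with pytest.raises(InvalidSpecError):
            simulate(_small_spec(), [SpeciesDefinition(mz=500.0, apex_k0=2.5)])


class TestDiaWindowScheme:
    def test_printed_scheme_arithmetic(self):
        """8 x 25 Th over 400-1000 Th: 24 windows across 3 DIA frames."""
        frames = dia_window_scheme(400.0, 1000.0, 25.0, 8, 1000)
        assert len(frames) == 3
        windows = [(lo, hi) for frame in frames for _, lo, hi, _ in frame]
        assert len(windows) == 24 and len(set(windows)) == 24
        assert all(400.0 <= lo < hi <= 1000.0 for lo, hi in windows)
        precs = [p for frame in frames for _, _, _, p in frame]
        assert sorted(precs) == list(range(1, 25))
        assert all(len(frame) == 8 for frame in frames)

    def test_single_window_frame(self):
        frames = dia_window_scheme(400.0, 1000.0, 600.0, 1, 100)
        assert frames == [[(0, 400.0, 1000.0, 1)]]

    def test_every_push_in_exactly_one_window(self):
        """A DIA frame's scan segments partition the frame."""
        spec = _small_spec(scheme=DiaScheme(), n_scans=64)
        _, quad, _ = simulate(spec, [])
        # frame 1 is the first DIA frame of the cycle
        base = 1 * spec.n_scans
        in_frame = (quad.pushes >= base) & (quad.pushes < base + spec.n_scans)
        starts = np.sort(quad.pushes[in_frame]) - base
        assert starts[0] == 0 and np.all(np.diff(starts) > 0)
        assert starts.size == 8  # every scan falls in exactly one segment

    def test_bad_geometry_rejected(self):
        with pytest.raises(InvalidSpecError):
            dia_window_scheme(400.0, 1000.0, 23.0, 8, 1000)
        with pytest.raises(InvalidSpecError):
            dia_window_scheme(400.0, 1000.0, 25.0, 8, 4)


class TestDdaSchedule:
    def _schedule(self, mz):
        mobility = ti.estimate_mobility_axis(100, 0.6, 1.6)
        sp = SpeciesDefinition(mz=mz, apex_rt=5.0, rt_sigma=1.0, apex_k0=1.0)
        return dda_schedule(1, 0, [sp], 100, 1, mobility)

    def test_window_width_rule_below_700(self):
        sched = self._schedule(650.0)
        assert (sched.lows[0], sched.highs[0]) == (649.0, 651.0)

    def test_window_width_rule_at_or_above_700(self):
        sched = self._schedule(800.0)
        assert (sched.lows[0], sched.highs[0]) == (798.5, 801.5)

    def test_topn_one_whole_frame_single_window(self):
        sched = self._schedule(650.0)
        assert sched.n_records == 1 and sched.pushes[0] == 0

    def test_precursor_indices_increase_globally(self):
        spec = _small_spec(scheme=DdaScheme(top_n=2, msms_frames_per_cycle=2))
        species = [
            SpeciesDefinition(mz=500.0, apex_rt=5.0, rt_sigma=2.0, apex_k0=0.9,
                              total_intensity=1e4),
            SpeciesDefinition(mz=800.0, apex_rt=6.0, rt_sigma=2.0, apex_k0=1.2,
                              total_intensity=1e4),
        ]
        _, quad, _ = simulate(spec, species)
        real = quad.precursors[quad.precursors > 0]
        np.testing.assert_array_equal(real, np.arange(1, real.size + 1))


class TestCollisionEnergy:
    @pytest.mark.parametrize("k0,ev", [(1.6, 59.0), (0.6, 20.0), (1.1, 39.5)])
    def test_linear_ramp(self, k0, ev):
        assert collision_energy(k0) == pytest.approx(ev)

    def test_clamped_outside_range(self):
        assert collision_energy(2.0) == 59.0
        assert collision_energy(0.1) == 20.0


class TestAnomalies:
    def test_tic_drop_suppresses_window(self):
        """A 0.9 TIC drop leaves <20% of the outside-mean inside the window."""
        spec = AcquisitionSpec(
            gradient_seconds=900.0, frames_per_second=2.0, n_scans=20,
            n_tof=2000, noise_occupancy=0.001, seed=5,
        )
        stream, quad, truth = simulate(
            spec, [calibrant_species(total_intensity=1e7)],
            [AnomalySpec("tic_drop", (720.0, 780.0), 0.9)],
        )
        ds = ti.build_index(stream, quad)
        prof = ti.tic(ds)
        kind, f_lo, f_hi = truth.anomaly_frame_ranges[0]
        inside = prof.intensities[f_lo:f_hi].mean()
        outside = np.r_[prof.intensities[:f_lo], prof.intensities[f_hi:]].mean()
        assert inside < 0.2 * outside

    def test_mz_offset_shifts_calibrant(self):
        """A +1 Da TOF offset moves the apparent calibrant mass by ~1 Th."""
        spec = _small_spec(noise_occupancy=0.0)
        full = (0.0, spec.gradient_seconds)
        stream, quad, _ = simulate(
            spec, [calibrant_species(total_intensity=1e6)],
            [AnomalySpec("mz_offset", full, 1.0)],
        )
        ds = ti.build_index(stream, quad)
        prof = ti.spectrum(ds)
        apparent = prof.values[np.argmax(prof.intensities)]
        assert apparent == pytest.approx(CALIBRANT_IONS[2][0] + 1.0, abs=1.0)
        assert apparent > CALIBRANT_IONS[2][0] + 0.4

    def test_mobility_shift_moves_apparent_k0(self):
        """Blocking the gas flow drops the apparent 1/K0 inside the window."""
        spec = _small_spec(noise_occupancy=0.0, n_scans=200)
        stream, quad, truth = simulate(
            spec, [calibrant_species(total_intensity=1e6)],
            [AnomalySpec("mobility_shift", (4.0, 6.0), -0.28)],
        )
        ds = ti.build_index(stream, quad)
        kind, f_lo, f_hi = truth.anomaly_frame_ranges[0]
        inside = ti.mobilogram(ds, ti.SliceRequest(frames=(f_lo, f_hi)))
        outside = ti.mobilogram(ds, ti.SliceRequest(frames=(0, f_lo)))
        k0_in = inside.values[np.argmax(inside.intensities)]
        k0_out = outside.values[np.argmax(outside.intensities)]
        assert k0_out == pytest.approx(1.382, abs=0.02)
        assert k0_in == pytest.approx(1.382 - 0.28, abs=0.02)

    def test_anomaly_window_outside_gradient_rejected(self):
        with pytest.raises(InvalidSpecError):
            simulate(_small_spec(), [], [AnomalySpec("tic_drop", (5.0, 100.0), 0.5)])


class TestDensityBound:
    def test_default_conditions_yield_240_billion_per_minute(self):
        """400k TOF bins x 1000 scans x 600 frames/min = 2.4e11 events/min."""
        spec = AcquisitionSpec(gradient_seconds=60.0)
        assert max_events_per_minute(spec) == 240e9

    def test_simulated_occupancy_is_sparse(self, dia_sim):
        spec, stream, _, _ = dia_sim
        capacity = spec.n_tof * spec.n_scans * spec.n_frames
        assert stream.n_events / capacity < 0.0003 * 10  # well under 0.3%
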