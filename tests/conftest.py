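import math

import numpy as np
import pytest

import timsindex as ti
from timsindex.indexer import QuadSwitchEvents, RawEventStream


@pytest.fixture(scope="session")
def toy_stream():
    """3 frames x 1 scan, 10 TOF bins, 3 hand-placed events."""
    return RawEventStream(
        pushes=np.array([0, 0, 2]),
        tofs=np.array([5, 9, 5]),
        intensities=np.array([10, 3, 7]),
        n_frames=3,
        n_scans=1,
        n_tof=10,
        rt_values=np.array([0.0, 1.0, 2.0]),
    )


@pytest.fixture(scope="session")
def toy_ds(toy_stream):
    return ti.build_index(toy_stream, QuadSwitchEvents.ms1_only())


def _species_panel():
    """Well-separated precursors across RT, mobility and m/z, plus calibrant."""
    return [
        ti.calibrant_species(total_intensity=2e5, k0_sigma=0.02),
        ti.SpeciesDefinition(mz=450.5, charge=2, apex_rt=8.0, rt_sigma=1.5,
                             apex_k0=0.85, k0_sigma=0.04, total_intensity=4e5,
                             n_isotopes=3),
        ti.SpeciesDefinition(mz=622.1, charge=1, apex_rt=15.0, rt_sigma=2.0,
                             apex_k0=1.0, k0_sigma=0.04, total_intensity=6e5,
                             n_isotopes=2),
        ti.SpeciesDefinition(mz=710.3, charge=2, apex_rt=20.0, rt_sigma=1.5,
                             apex_k0=1.1, k0_sigma=0.04, total_intensity=5e5,
                             n_isotopes=3),
        ti.SpeciesDefinition(mz=850.4, charge=3, apex_rt=25.0, rt_sigma=2.0,
                             apex_k0=1.25, k0_sigma=0.05, total_intensity=3e5,
                             n_isotopes=2),
        ti.SpeciesDefinition(mz=333.3, charge=1, apex_rt=12.0, rt_sigma=1.0,
                             apex_k0=0.75, k0_sigma=0.03, total_intensity=2e5,
                             n_isotopes=1),
    ]


@pytest.fixture(scope="session")
def dda_sim():
    spec = ti.AcquisitionSpec(
        gradient_seconds=30.0,
        frames_per_second=10.0,
        n_scans=100,
        n_tof=5000,
        scheme=ti.DdaScheme(top_n=4, msms_frames_per_cycle=3),
        noise_occupancy=0.0006,
        seed=7,
        sample_name="dda_sim",
    )
    stream, quad, truth = ti.simulate(spec, _species_panel())
    return spec, stream, quad, truth


@pytest.fixture(scope="session")
def dda_ds(dda_sim):
    _, stream, quad, _ = dda_sim
    return ti.build_index(stream, quad)


@pytest.fixture(scope="session")
def dia_sim():
    spec = ti.AcquisitionSpec(
        gradient_seconds=30.0,
        frames_per_second=10.0,
        n_scans=100,
        n_tof=5000,
        scheme=ti.DiaScheme(),
        noise_occupancy=0.0006,
        seed=11,
        sample_name="dia_sim",
    )
    stream, quad, truth = ti.simulate(spec, _species_panel())
    return spec, stream, quad, truth


@pytest.fixture(scope="session")
def dia_ds(dia_sim):
    _, stream, quad, _ = dia_sim
    return ti.build_index(stream, quad)


@pytest.fixture(scope="session")
def ms1_sim():
    """MS1-only run: species are visible in every frame, so elution apexes
    are recoverable at single-frame resolution."""
    spec = ti.AcquisitionSpec(
        gradient_seconds=30.0,
        frames_per_second=10.0,
        n_scans=100,
        n_tof=5000,
        scheme=ti.Ms1Only(),
        noise_occupancy=0.0002,
        seed=13,
        sample_name="ms1_sim",
    )
    stream, quad, truth = ti.simulate(spec, _species_panel())
    return spec, stream, quad, truth


@pytest.fixture(scope="session")
def ms1_ds(ms1_sim):
    _, stream, quad, _ = ms1_sim
    return ti.build_index(stream, quad)
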