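"""Select detector events along any dimension of an indexed acquisition.

Integers are indices, decimals are physical values (retention time in
seconds, 1/K0 in Vs cm^-2, m/z in Th); value ranges are half-open.  The
result is an event table with one row per detector event carrying both
indices and converted physical values.
"""

import timsindex as ti

spec = ti.AcquisitionSpec(
    gradient_seconds=120.0, frames_per_second=10.0, n_scans=1000, n_tof=400_000,
    scheme=ti.DiaScheme(), noise_occupancy=8e-7, seed=101,
)
species = [
    ti.calibrant_species(mz=622.0289, apex_k0=0.9848, total_intensity=3e5, k0_sigma=0.01),
    ti.SpeciesDefinition(mz=705.2, charge=2, apex_rt=60.0, rt_sigma=5.0,
                         apex_k0=1.05, k0_sigma=0.03, total_intensity=5e5, n_isotopes=3),
]
stream, quad_events, _ = ti.simulate(spec, species)
ds = ti.build_index(stream, quad_events)
print(f"indexed {ds.n_events} events over {ds.n_frames} frames x {ds.n_scans} scans")

requests = {
    "LC slice   100.0 <= rt (s) < 100.5": ti.SliceRequest(frames=(100.0, 100.5)),
    "TIMS slice scan index = 450       ": ti.SliceRequest(scans=450),
    "Quad slice 700.0 <= m/z < 710.0   ": ti.SliceRequest(quad=(700.0, 710.0)),
    "TOF slice  621.9 <= m/z < 622.1   ": ti.SliceRequest(tof=(621.9, 622.1)),
}
for label, req in requests.items():
    table = ti.select(ds, req)
    print(f"{label}: {len(table):7d} events")

# Dimensions combine by intersection; the quad slice keeps only events
# recorded while the overlapping 700-725 Th isolation window was active.
combined = ti.select(
    ds, ti.SliceRequest(frames=(55.0, 65.0), quad=(700.0, 710.0), tof=(704.9, 705.5))
)
print(f"combined RT x quad x TOF slice    : {len(combined):7d} events")
print(combined.head())
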