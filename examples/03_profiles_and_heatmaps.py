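"""Project selections onto axes: TIC, XIC, spectrum, mobilogram, heatmap.

Every projection conserves the total intensity of its underlying
selection, so profiles and heatmaps are exact aggregations of the raw
detector events, not re-sampled approximations.
"""

import numpy as np

import timsindex as ti

spec = ti.AcquisitionSpec(
    gradient_seconds=30.0, frames_per_second=10.0, n_scans=100, n_tof=5000,
    scheme=ti.Ms1Only(), noise_occupancy=0.0002, seed=13,
)
species = [
    ti.calibrant_species(total_intensity=2e5, k0_sigma=0.02),
    ti.SpeciesDefinition(mz=622.1, apex_rt=15.0, rt_sigma=2.0, apex_k0=1.0,
                         k0_sigma=0.04, total_intensity=6e5, n_isotopes=2),
]
stream, quad_events, truth = ti.simulate(spec, species)
ds = ti.build_index(stream, quad_events)

tic = ti.tic(ds)
print(f"TIC total intensity        : {tic.total:.0f} (= all indexed intensity)")

xic = ti.xic(ds, mz_range=(621.6, 622.6))
apex_frame = int(np.argmax(xic.intensities))
print(f"XIC 621.6-622.6 Th apex    : frame {apex_frame} "
      f"(rt {xic.values[apex_frame]:.1f} s; species apex was 15.0 s)")

mob = ti.mobilogram(ds, ti.SliceRequest(tof=(621.6, 622.6)))
apex_scan = int(np.argmax(mob.intensities))
print(f"mobilogram apex            : scan {apex_scan} "
      f"(1/K0 {mob.values[apex_scan]:.3f}; species apex was 1.000)")

spec1d = ti.spectrum(ds, ti.SliceRequest(frames=(14.0, 16.0)))
top = np.argsort(spec1d.intensities)[-3:][::-1]
print("strongest spectrum peaks   :",
      ", ".join(f"{spec1d.values[i]:.2f} Th ({spec1d.intensities[i]:.0f})" for i in top))

hm = ti.heatmap(ds, ti.SliceRequest(), "rt", "mobility", 30, 30)
print(f"30x30 rt x mobility heatmap: matrix sum {hm.total:.0f} (conserved)")
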