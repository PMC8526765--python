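# Methods

## The data model

An LC-TIMS-Q-TOF acquisition separates ions four times before detection:
a liquid-chromatography gradient (minutes), a trapped-ion-mobility ramp
(~100 ms per *frame*), a quadrupole isolation window, and a time-of-flight
extraction (~100 µs per *scan*, triggered by the pusher).  Each detector
event is therefore addressable by four discrete coordinates — frame, scan,
quadrupole window, TOF bin — plus the measured intensity, and each
discrete coordinate converts to a continuous physical value (retention
time in seconds, reduced mobility 1/K0 in Vs cm⁻², isolation bounds and
TOF m/z in Th) through reference axes.

`timsindex` stores the events of one acquisition as a compressed sparse
row (CSR) matrix: rows are *push indices* — the bijection
`push = scan + frame · n_scans` makes a frame-scan matrix redundant —
columns are TOF indices, values are intensities.  Three arrays define the
matrix:

- `push_indptr` (int64, length `n_pushes + 1`): cumulative event counts
  per push, produced by summing a dense events-per-push histogram;
- `tof_indices` (uint32): the TOF column of each event, strictly
  increasing within each push;
- `intensities` (uint16): detector counts, never zero.

A detector event therefore occupies exactly 6 bytes (4 + 2), so memory in
gigabytes is roughly six times the event count in billions.  Quadrupole
state is sparse: an array of push indices at which the isolation window
changes, a `(n, 2)` array of (low, high) bounds with `(-1, -1)` as the
full-transmission (MS1) sentinel, and a precursor index per change (0 iff
sentinel).

## Accession

A selection is simultaneous over six dimensions: LC, TIMS, quadrupole
m/z, precursor index, TOF m/z, and intensity.  The convention for the
three axis dimensions is that integers are indices and decimals are
physical values; values are converted to the closest index by binary
search (O(log n), ties at exact midpoints resolve to the lower index,
out-of-range values clamp to the axis ends).  Explicit `IndexRange` /
`ValueRange` wrappers override the dispatch where an integral physical
value would be ambiguous.

Value ranges are half-open `[start, stop)` and resolve to the index range
`[closest(start), closest(stop))`.  On the descending mobility axis the
converted bounds are swapped so the returned index range ascends;
half-openness is applied in index space after the swap.  Two consequences
worth knowing: the bin closest to `stop` is excluded even when its value
is below `stop`, so a query window narrower than about two bin spacings
can miss its target bin; and an inverted range is an empty selection, not
an error.

The algorithm mirrors the index structure:

1. frame and scan ranges become push indices arithmetically (no search);
2. one linear pass over the sparse quadrupole arrays marks matching
   segments (a window matches a quad range when the two *overlap*, so a
   2–3 Th data-dependent window inside a 10 Th query matches; sentinel
   windows match only when no quad range is given or the range starts at
   or below −1), and selected pushes in non-matching segments are dropped;
3. the TOF range is located with one binary search per surviving push
   inside that push's sorted column slice (a numba-compiled kernel);
4. intensity bounds are applied in a single pass over the candidates.

Per-push work is thus independent of the dataset's total event count —
the property that keeps slicing at interactive latency on billion-event
acquisitions.  `SliceStats` counters expose the number of selected
pushes, per-push binary searches and quad passes so the contract is
testable, not just claimed.

Results come back as a pandas event table ordered by (push, tof), one row
per event with all indices, converted physical values, the active
quadrupole window and the precursor index — or as raw offsets into the
event arrays (`select_indices`).

## Aggregation

All projections are exact sums over a selection and conserve its total
intensity: TIC and XIC per frame, mass spectra per occupied TOF index,
mobilograms per scan, and 2D heatmaps with equal-width bins in physical
value (half-open bins, last bin closed, edges spanning the resolved
selection so conservation is exact).  `qc_tic_drop` formalises visual
ion-current QC: frames whose centred rolling-median TIC falls below
`drop_fraction` (default 0.5) times the run's global median are flagged
as contiguous ranges; the default window is one minute of frames.  A run
with zero global median is degenerate and flagged in full.  This detector
is an extension of the visual check, not a literature procedure.

## The simulator

The simulator generates the logical content of an acquisition so every
other component can be verified against exact ground truth.  Defaults are
the acquisition conditions of the instrument family this model targets:
600 frames/min, 1000 scans/frame, 400,000 TOF bins over 100–1700 Th,
1/K0 from 0.6 to 1.6 Vs cm⁻², and ~0.02% background occupancy (real runs
stay under 0.03%).  The m/z axis is interpolated in sqrt(m/z) space
between the declared bounds — TOF flight time scales with √(m/z) — and is
documented as an estimation, not a vendor calibration.  The mobility axis
descends linearly (scan 0 holds the highest 1/K0, matching TIMS elution
order).

Species elute as Gaussian profiles in RT and mobility; event intensities
are the *deterministically rounded* profile (no shot noise), so
ground-truth event counts are exact and apex-recovery tests can be tight.
Isotopes are spaced 1/charge Th with geometric (ratio 0.5) abundances.
Only the uniform background noise is stochastic, drawn from the seeded
generator; coinciding events merge by intensity summation at simulation
time.  Intensities clip at the uint16 maximum and a saturation flag is
recorded.  A continuously sprayed calibrant (1221.9906 Th at 1.3820
Vs cm⁻²; the uniform-elution `rt_sigma = inf` sentinel) is available as a
one-call species.

Quadrupole scheduling supports three schemes.  `Ms1Only` transmits
everything.  `DiaScheme` builds a recurring cycle of one MS1 frame plus
`ceil(n_windows / groups_per_frame)` DIA frames; each DIA frame splits
its scans into contiguous segments with fixed-width windows stepping
across the precursor range, higher m/z at lower scan index (higher
mobility).  The default is the 8 × 25 Th layout over 400–1000 Th.
Precursor indices for DIA are the global 1-based window number — unique
per window — which keeps precursor-wise selection and MGF export well
defined (the per-frame segment number would alias windows of different
frames).  `DdaScheme` is topN scheduling: each cycle holds one MS1 frame
and `msms_frames_per_cycle` MS/MS frames whose scans are partitioned into
`top_n` segments, each isolating one candidate with the standard width
rule (2 Th below 700 Th, 3 Th at or above), assigned in apex-scan order
so windows track precursor mobility; precursor indices increase globally.
The collision-energy ramp (59 eV at 1/K0 = 1.6 down to 20 eV at 0.6,
clamped) is metadata only — no fragmentation model exists.  Fragment
species, when wanted, are explicit species tied to a precursor window via
`precursor_mz`; they appear only in windows containing that precursor
m/z, never in MS1 frames.

Injectable anomalies emulate acquisition defects inside an RT window:
`tic_drop` scales intensities by `1 − magnitude`; `mz_offset` shifts
event m/z and re-bins to the nearest TOF index; `mobility_shift` shifts
1/K0 and re-bins to the nearest scan.

What the simulator does **not** emulate: chromatographic peak asymmetry
and tailing, correlated (chemical) noise, detector dead time, realistic
isotope fine structure, charge-state envelopes from a digest, or vendor
calibration functions.  Passing tests therefore demonstrate correctness
of indexing, accession and aggregation over realistic *geometry* and
density, not fidelity of any biological signal model.

## Persistence

HDF5 layout: groups `raw` (the three CSR arrays), `axes` (the three
reference axes), `quad` (change indices, bounds, precursor indices) and
`meta` (scalar attributes, including a `schema_version` guard and
free-form string metadata).  Loading performs no re-indexing and checks
all dataclass invariants, so a truncated or inconsistent file fails
loudly with the name of the offending piece.  Optional compression is
gzip level 4 with byte shuffling — lossless by construction and verified
bit-exact in tests; files are this package's own schema and deliberately
not claimed compatible with any other HDF5-based MS format.

MGF export writes one block per distinct precursor index ≥ 1 (also when
its selection is empty, keeping block count equal to precursor count).
PEPMASS is the isolation-window centre — there is no centroiding or
feature detection in scope — RTINSECONDS is the intensity-weighted mean
RT of the block's events, and the peak list is the block's mass spectrum
in ascending m/z.  CHARGE is omitted: the index does not know it.

## Interfaces and sizes

The library is the primary interface; the `timsindex` CLI is a thin
wrapper (simulate / index / slice / export / qc) whose outputs are
byte-identical to the corresponding library calls, plus an append-only
plain-text run log.  A TSV interchange format (header lines plus
push/tof/intensity rows, bit-exact integer parsing) feeds streams from
other tools.

Tests and the acceptance script run on scaled-down geometries — typically
10⁵–10⁶ events, 100–1000 scans, 2,000–400,000 TOF bins, 10–120 s
gradients, chosen so the full pipeline including the brute-force oracle
comparisons completes in seconds while still crossing all code paths; the
ion-current-drop scenario uses a 15-min gradient so the minute-12-to-13
window exists.  The indexing-throughput check uses a 10⁷-event stream.

## Known limitations

- m/z and mobility axes are estimations from declared bounds; absolute
  accuracy against vendor-calibrated values is out of scope.
- One fixed `n_scans` per dataset; per-frame variable scan counts are not
  modelled.
- Quadrupole selection is binary (transmitted or not); no transmission
  efficiency profile at window edges.
- Precursor "ranges" are index *sets*; arbitrary boolean combinations of
  slices (union, negation) are not supported.
- `closest`-based value ranges can clip the stop-side bin (see
  Accession); widen the window by a bin spacing when targeting single
  peaks.
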