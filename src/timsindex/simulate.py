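"""Synthetic LC-TIMS-Q-TOF acquisitions with exact ground truth.

The simulator emulates the logical content of a PASEF acquisition — frames
of TIMS ramps, ~100 µs pusher events, quadrupole scheduling (topN
data-dependent or fixed diaPASEF window groups), a continuously sprayed
calibrant ion and injectable anomalies — so that indexing, slicing,
aggregation and persistence can all be exercised and verified without
vendor raw data.

Defaults reproduce typical acquisition conditions of the instrument
family: 600 frames per minute, 1000 scans per frame, 400,000 TOF bins over
100-1700 Th, a 1/K0 range of 0.6-1.6 Vs cm^-2, and a detector occupancy of
about 0.02% (real runs stay below 0.03%).

Ion species elute as Gaussian profiles in retention time and mobility.
Their events are generated by deterministic rounding of the profile, so
per-species event counts in the ground truth are exact; only the uniform
background noise is stochastic (seeded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .core import InvalidInputError, TimsIndexError, closest_index, estimate_mobility_axis, estimate_mz_axis
from .indexer import QuadSwitchEvents, RawEventStream

__all__ = [
    "InvalidSpecError",
    "Ms1Only",
    "DiaScheme",
    "DdaScheme",
    "AcquisitionSpec",
    "SpeciesDefinition",
    "AnomalySpec",
    "GroundTruth",
    "simulate",
    "dia_window_scheme",
    "dda_schedule",
    "collision_energy",
    "calibrant_species",
    "max_events_per_minute",
    "CALIBRANT_IONS",
]

#: ESI tuning-mix calibrant ions: (m/z in Th, 1/K0 in Vs cm^-2)
CALIBRANT_IONS = (
    (622.0289, 0.9848),
    (922.0097, 1.1895),
    (1221.9906, 1.3820),
)

INTENSITY_MAX = 65535  # uint16 saturation


class InvalidSpecError(TimsIndexError, ValueError):
    """An acquisition or species specification is internally inconsistent."""


@dataclass(frozen=True)
class Ms1Only:
    """No quadrupole selection: every frame is a full-transmission MS1 frame."""


@dataclass(frozen=True)
class DiaScheme:
    """diaPASEF: a recurring cycle of one MS1 frame plus DIA frames.

    Each DIA frame is split into ``groups_per_frame`` contiguous scan
    segments; isolation windows of ``window_width`` Th step across
    [mz_lo, mz_hi], higher m/z at lower scan index (higher mobility).
    The default is the 'high-speed' 8 x 25 Th scheme over 400-1000 Th.
    """

    mz_lo: float = 400.0
    mz_hi: float = 1000.0
    window_width: float = 25.0
    groups_per_frame: int = 8


@dataclass(frozen=True)
class DdaScheme:
    """ddaPASEF: topN precursor scheduling.

    Each cycle holds one MS1 frame followed by ``msms_frames_per_cycle``
    MS/MS frames; every MS/MS frame isolates ``top_n`` precursors in
    contiguous scan segments, with the standard width rule (2 Th below
    700 Th, 3 Th at or above).
    """

    top_n: int = 10
    msms_frames_per_cycle: int = 4


Scheme = Union[Ms1Only, DiaScheme, DdaScheme]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry and schedule of a synthetic acquisition.

    ``noise_occupancy`` is the expected fraction of TOF bins hit by a
    background event per push (0.0002 = 0.02%).
    """

    gradient_seconds: float
    frames_per_second: float = 10.0
    n_scans: int = 1000
    n_tof: int = 400_000
    mz_min: float = 100.0
    mz_max: float = 1700.0
    k0_min: float = 0.6
    k0_max: float = 1.6
    scheme: Scheme = field(default_factory=Ms1Only)
    noise_occupancy: float = 0.0002
    seed: int = 0
    sample_name: str = "synthetic"

    def __post_init__(self):
        if self.gradient_seconds <= 0 or self.frames_per_second <= 0:
            raise InvalidSpecError("gradient and frame rate must be positive")
        if self.n_scans < 2 or self.n_tof < 2:
            raise InvalidSpecError("n_scans and n_tof must be >= 2")
        if not (0 < self.mz_min < self.mz_max) or not (0 < self.k0_min < self.k0_max):
            raise InvalidSpecError("axis bounds must be ordered and positive")
        if self.noise_occupancy < 0:
            raise InvalidSpecError("noise_occupancy must be >= 0")

    @property
    def n_frames(self) -> int:
        return max(1, round(self.gradient_seconds * self.frames_per_second))

    @property
    def rt_values(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frames_per_second

    @property
    def mobility_values(self) -> np.ndarray:
        return estimate_mobility_axis(self.n_scans, self.k0_min, self.k0_max)

    @property
    def mz_values(self) -> np.ndarray:
        return estimate_mz_axis(self.n_tof, self.mz_min, self.mz_max)


@dataclass(frozen=True)
class SpeciesDefinition:
    """One ion species with Gaussian elution profiles in RT and mobility.

    ``rt_sigma=inf`` means uniform elution across the whole gradient (used
    for the continuously sprayed calibrant).  ``precursor_mz`` marks a
    fragment species: it then appears only in quadrupole windows containing
    that precursor m/z, never in MS1 frames.
    """

    mz: float
    charge: int = 1
    apex_rt: float = 0.0
    rt_sigma: float = math.inf
    apex_k0: float = 1.0
    k0_sigma: float = 0.05
    total_intensity: float = 1e5
    n_isotopes: int = 1
    is_calibrant: bool = False
    precursor_mz: Optional[float] = None

    def __post_init__(self):
        if self.rt_sigma <= 0 or self.k0_sigma <= 0:
            raise InvalidSpecError("species sigmas must be positive")
        if self.charge < 1 or self.n_isotopes < 1:
            raise InvalidSpecError("charge and n_isotopes must be >= 1")


def calibrant_species(
    mz: float = CALIBRANT_IONS[2][0],
    apex_k0: float = CALIBRANT_IONS[2][1],
    total_intensity: float = 1e6,
    k0_sigma: float = 0.01,
) -> SpeciesDefinition:
    """The constant calibrant ion (default 1221.9906 Th at 1.3820 Vs cm^-2)."""
    return SpeciesDefinition(
        mz=mz,
        apex_k0=apex_k0,
        rt_sigma=math.inf,
        k0_sigma=k0_sigma,
        total_intensity=total_intensity,
        is_calibrant=True,
    )


@dataclass(frozen=True)
class AnomalySpec:
    """An injectable acquisition defect, active inside an RT window.

    kind 'tic_drop': intensities scale by (1 - magnitude);
    kind 'mz_offset': event m/z shifts by +magnitude Th (re-binned to the
    nearest TOF index); kind 'mobility_shift': event 1/K0 shifts by
    +magnitude Vs cm^-2 (re-binned to the nearest scan).
    """

    kind: str
    rt_window: tuple[float, float]
    magnitude: float

    def __post_init__(self):
        if self.kind not in ("tic_drop", "mz_offset", "mobility_shift"):
            raise InvalidSpecError(f"unknown anomaly kind {self.kind!r}")
        if self.rt_window[0] >= self.rt_window[1]:
            raise InvalidSpecError("anomaly rt_window must be a non-empty interval")
        if self.kind == "tic_drop" and not (0 < self.magnitude <= 1):
            raise InvalidSpecError("tic_drop magnitude must be in (0, 1]")


@dataclass
class GroundTruth:
    """What the simulator actually emitted, for exact verification."""

    species_counts: np.ndarray
    noise_count: int
    apex_frames: np.ndarray
    apex_scans: np.ndarray
    apex_tofs: np.ndarray
    anomaly_frame_ranges: list[tuple[str, int, int]]
    quad_events: QuadSwitchEvents
    saturated: bool


def max_events_per_minute(spec: AcquisitionSpec) -> float:
    """Theoretical maximum acquisition density: every TOF bin of every push
    of every frame in one minute registering an event."""
    return spec.n_tof * spec.n_scans * spec.frames_per_second * 60.0


def collision_energy(k0: float) -> float:
    """Collision energy ramp: linear from 59 eV at 1/K0=1.6 down to 20 eV at
    0.6 Vs cm^-2, clamped outside that range."""
    k0 = min(max(k0, 0.6), 1.6)
    return 20.0 + (k0 - 0.6) / (1.6 - 0.6) * (59.0 - 20.0)


# ---------------------------------------------------------------------------
# quadrupole scheduling


def dia_window_scheme(
    mz_lo: float,
    mz_hi: float,
    width: float,
    groups_per_frame: int,
    n_scans: int,
) -> list[list[tuple[int, float, float, int]]]:
    """Per-cycle diaPASEF frame template.

    Returns one list per DIA frame of the cycle; each entry is
    (scan_start, low, high, precursor_index) for one contiguous scan
    segment.  Windows of ``width`` Th step across [mz_lo, mz_hi]; precursor
    indices are 1-based and unique per window.  Within a frame, higher m/z
    windows sit at lower scan indices (higher mobility), matching the
    correlation of m/z and mobility.
    """
    if width <= 0 or groups_per_frame < 1:
        raise InvalidSpecError("window width and groups_per_frame must be positive")
    span = mz_hi - mz_lo
    n_windows = round(span / width)
    if n_windows < 1 or abs(n_windows * width - span) > 1e-9:
        raise InvalidSpecError(
            f"window width {width} does not tile [{mz_lo}, {mz_hi}]"
        )
    if n_scans < groups_per_frame:
        raise InvalidSpecError("need at least one scan per window group")
    n_dia_frames = math.ceil(n_windows / groups_per_frame)
    bounds = [(mz_lo + i * width, mz_lo + (i + 1) * width) for i in range(n_windows)]
    frames: list[list[tuple[int, float, float, int]]] = []
    for d in range(n_dia_frames):
        group = bounds[d * groups_per_frame : (d + 1) * groups_per_frame]
        k = len(group)
        seg_starts = [round(g * n_scans / k) for g in range(k)]
        # higher m/z first (lower scan index)
        segs = []
        for g, (lo, hi) in enumerate(reversed(group)):
            w = d * groups_per_frame + (k - 1 - g)
            segs.append((seg_starts[g], lo, hi, w + 1))
        frames.append(segs)
    return frames


def dda_schedule(
    top_n: int,
    frame: int,
    candidates: Sequence[SpeciesDefinition],
    n_scans: int,
    first_precursor_index: int,
    mobility_values: np.ndarray,
) -> QuadSwitchEvents:
    """topN quadrupole schedule for one MS/MS frame.

    The frame's scans are partitioned into ``top_n`` contiguous segments,
    each isolating one candidate with the standard window-width rule (2 Th
    below 700 Th, 3 Th at/above); candidates are assigned in order of
    their apex scan so the window tracks the precursor's mobility.
    Precursor indices increase globally starting at
    ``first_precursor_index``.
    """
    if top_n < 1:
        raise InvalidSpecError("top_n must be >= 1")
    chosen = sorted(
        candidates, key=lambda s: -s.total_intensity
    )[:top_n]
    chosen = sorted(chosen, key=lambda s: int(closest_index(s.apex_k0, mobility_values)))
    k = max(len(chosen), 1)
    pushes, lows, highs, precs = [], [], [], []
    base = frame * n_scans
    for i, sp in enumerate(chosen):
        width = 2.0 if sp.mz < 700.0 else 3.0
        start_scan = round(i * n_scans / k)
        pushes.append(base + start_scan)
        lows.append(sp.mz - width / 2)
        highs.append(sp.mz + width / 2)
        precs.append(first_precursor_index + i)
    if not chosen:  # no candidates: the frame transmits everything
        pushes, lows, highs, precs = [base], [-1.0], [-1.0], [0]
    if pushes[0] != base:
        raise InvalidSpecError("schedule must start at the frame's first push")
    return QuadSwitchEvents(
        np.array(pushes, np.int64),
        np.array(lows, np.float64),
        np.array(highs, np.float64),
        np.array(precs, np.int64),
        full_run=False,
    )


def _build_schedule(
    spec: AcquisitionSpec, species: Sequence[SpeciesDefinition]
) -> QuadSwitchEvents:
    """Full-run quadrupole switch events for the spec's scheme."""
    n_scans = spec.n_scans
    scheme = spec.scheme
    if isinstance(scheme, Ms1Only):
        return QuadSwitchEvents.ms1_only()

    pushes: list[int] = []
    lows: list[float] = []
    highs: list[float] = []
    precs: list[int] = []

    def add(push, lo, hi, pr):
        pushes.append(int(push))
        lows.append(float(lo))
        highs.append(float(hi))
        precs.append(int(pr))

    if isinstance(scheme, DiaScheme):
        template = dia_window_scheme(
            scheme.mz_lo, scheme.mz_hi, scheme.window_width,
            scheme.groups_per_frame, n_scans,
        )
        cycle = 1 + len(template)
        for f in range(spec.n_frames):
            pos = f % cycle
            if pos == 0:
                add(f * n_scans, -1.0, -1.0, 0)
            else:
                for scan_start, lo, hi, w in template[pos - 1]:
                    add(f * n_scans + scan_start, lo, hi, w)
    elif isinstance(scheme, DdaScheme):
        cycle = 1 + scheme.msms_frames_per_cycle
        candidates = [
            s for s in species if s.precursor_mz is None and not s.is_calibrant
        ]
        next_prec = 1
        for f in range(spec.n_frames):
            if f % cycle == 0 or not candidates:
                add(f * n_scans, -1.0, -1.0, 0)
            else:
                sched = dda_schedule(
                    scheme.top_n, f, candidates, n_scans, next_prec,
                    spec.mobility_values,
                )
                next_prec += sched.n_records
                for p, lo, hi, pr in zip(
                    sched.pushes, sched.lows, sched.highs, sched.precursors
                ):
                    add(p, lo, hi, pr)
    else:
        raise InvalidSpecError(f"unknown scheme {scheme!r}")
    return QuadSwitchEvents(
        np.array(pushes, np.int64),
        np.array(lows, np.float64),
        np.array(highs, np.float64),
        np.array(precs, np.int64),
    )


# ---------------------------------------------------------------------------
# event synthesis


def _species_events(
    spec: AcquisitionSpec,
    sp: SpeciesDefinition,
    quad: QuadSwitchEvents,
):
    """Deterministic (push, tof, intensity) triples for one species."""
    rt = spec.rt_values
    k0 = spec.mobility_values
    if math.isinf(sp.rt_sigma):
        rt_w = np.full(rt.size, 1.0 / rt.size)
    else:
        rt_w = np.exp(-0.5 * ((rt - sp.apex_rt) / sp.rt_sigma) ** 2)
        s = rt_w.sum()
        if s == 0:
            return (np.empty(0, np.int64),) * 3
        rt_w /= s
    k0_w = np.exp(-0.5 * ((k0 - sp.apex_k0) / sp.k0_sigma) ** 2)
    s = k0_w.sum()
    if s == 0:
        return (np.empty(0, np.int64),) * 3
    k0_w /= s

    base = sp.total_intensity * np.outer(rt_w, k0_w)  # (n_frames, n_scans)
    iso_frac = 0.5 ** np.arange(sp.n_isotopes)
    iso_frac /= iso_frac.sum()
    iso_mz = sp.mz + np.arange(sp.n_isotopes) / sp.charge
    if np.any((iso_mz < spec.mz_min) | (iso_mz > spec.mz_max)):
        raise InvalidSpecError(
            f"species at {sp.mz} Th: isotope envelope leaves the m/z range"
        )
    iso_tof = closest_index(iso_mz, spec.mz_values)

    gate_mz = sp.precursor_mz if sp.precursor_mz is not None else sp.mz
    fragment = sp.precursor_mz is not None

    all_push, all_tof, all_int = [], [], []
    for frac, tof in zip(iso_frac, np.atleast_1d(iso_tof)):
        grid = np.rint(base * frac).astype(np.int64)
        f_idx, s_idx = np.nonzero(grid)
        if f_idx.size == 0:
            continue
        push = f_idx * spec.n_scans + s_idx
        inten = grid[f_idx, s_idx]
        # quadrupole gating: which events are actually transmitted
        seg = np.searchsorted(quad.pushes, push, side="right") - 1
        lo, hi = quad.lows[seg], quad.highs[seg]
        sentinel = lo == -1.0
        in_window = (~sentinel) & (lo <= gate_mz) & (gate_mz < hi)
        keep = in_window if fragment else (in_window | sentinel)
        all_push.append(push[keep])
        all_tof.append(np.full(keep.sum(), tof, np.int64))
        all_int.append(inten[keep])
    if not all_push:
        return (np.empty(0, np.int64),) * 3
    return (
        np.concatenate(all_push),
        np.concatenate(all_tof),
        np.concatenate(all_int),
    )


def _merge_events(push, tof, inten, source, n_tof):
    """Sort by (push, tof); sum intensities of coinciding events.

    Attribution of a merged event goes to the earliest contributing source
    (species before noise, in species order).
    """
    key = push * np.int64(n_tof) + tof
    order = np.argsort(key, kind="stable")
    key, inten, source = key[order], inten[order], source[order]
    uniq_key, first, counts = np.unique(key, return_index=True, return_counts=True)
    sums = np.add.reduceat(inten, first) if inten.size else inten
    return (
        uniq_key // n_tof,
        uniq_key % n_tof,
        sums,
        source[first],
    )


def simulate(
    spec: AcquisitionSpec,
    species: Sequence[SpeciesDefinition] = (),
    anomalies: Sequence[AnomalySpec] = (),
):
    """Generate a full synthetic acquisition.

    Returns ``(RawEventStream, QuadSwitchEvents, GroundTruth)``.  Species
    events are deterministic; background noise is drawn from the seeded
    generator.  Events coinciding at the same (push, tof) are merged by
    intensity summation; intensities clip at the uint16 maximum (recorded
    in ``GroundTruth.saturated``).
    """
    for sp in species:
        if not (spec.mz_min <= sp.mz <= spec.mz_max):
            raise InvalidSpecError(f"species m/z {sp.mz} outside axis bounds")
        if not (spec.k0_min <= sp.apex_k0 <= spec.k0_max):
            raise InvalidSpecError(f"species 1/K0 {sp.apex_k0} outside axis bounds")
        if not math.isinf(sp.rt_sigma) and not (
            0 <= sp.apex_rt <= spec.gradient_seconds
        ):
            raise InvalidSpecError(f"species apex RT {sp.apex_rt} outside gradient")
    for an in anomalies:
        if an.rt_window[0] < 0 or an.rt_window[1] > spec.gradient_seconds:
            raise InvalidSpecError("anomaly window outside gradient")

    rng = np.random.default_rng(spec.seed)
    quad = _build_schedule(spec, species)
    n_pushes = spec.n_frames * spec.n_scans

    pushes, tofs, intens, sources = [], [], [], []
    for k, sp in enumerate(species):
        p, t, i = _species_events(spec, sp, quad)
        pushes.append(p)
        tofs.append(t)
        intens.append(i)
        sources.append(np.full(p.size, k, np.int64))

    noise_rate = spec.noise_occupancy * spec.n_tof
    n_noise = int(rng.poisson(noise_rate * n_pushes)) if noise_rate > 0 else 0
    if n_noise:
        pushes.append(rng.integers(0, n_pushes, n_noise))
        tofs.append(rng.integers(0, spec.n_tof, n_noise))
        intens.append(rng.integers(1, 10, n_noise))
        sources.append(np.full(n_noise, -1, np.int64))

    if pushes:
        push = np.concatenate(pushes)
        tof = np.concatenate(tofs)
        inten = np.concatenate(intens)
        source = np.concatenate(sources)
    else:
        push = tof = inten = source = np.empty(0, np.int64)

    push, tof, inten, source = _merge_events(push, tof, inten, source, spec.n_tof)

    # --- anomalies -----------------------------------------------------
    rt = spec.rt_values
    anomaly_ranges: list[tuple[str, int, int]] = []
    for an in anomalies:
        f_lo = int(np.searchsorted(rt, an.rt_window[0], side="left"))
        f_hi = int(np.searchsorted(rt, an.rt_window[1], side="left"))
        anomaly_ranges.append((an.kind, f_lo, f_hi))
        frame = push // spec.n_scans
        inside = (frame >= f_lo) & (frame < f_hi)
        if an.kind == "tic_drop":
            inten = np.where(
                inside, np.rint(inten * (1.0 - an.magnitude)).astype(np.int64), inten
            )
        elif an.kind == "mz_offset":
            new_tof = closest_index(
                spec.mz_values[tof[inside]] + an.magnitude, spec.mz_values
            )
            tof = tof.copy()
            tof[inside] = new_tof
        elif an.kind == "mobility_shift":
            scan = push % spec.n_scans
            new_scan = closest_index(
                spec.mobility_values[scan[inside]] + an.magnitude,
                spec.mobility_values,
            )
            push = push.copy()
            push[inside] = frame[inside] * spec.n_scans + new_scan
        push, tof, inten, source = _merge_events(push, tof, inten, source, spec.n_tof)

    keep = inten > 0
    push, tof, inten, source = push[keep], tof[keep], inten[keep], source[keep]
    saturated = bool(np.any(inten > INTENSITY_MAX))
    inten = np.minimum(inten, INTENSITY_MAX)

    species_counts = np.bincount(
        source[source >= 0], minlength=len(species)
    ) if len(species) else np.zeros(0, np.int64)
    truth = GroundTruth(
        species_counts=species_counts.astype(np.int64),
        noise_count=int(np.sum(source == -1)),
        apex_frames=np.array(
            [int(closest_index(sp.apex_rt, rt)) if not math.isinf(sp.rt_sigma) else -1
             for sp in species], np.int64
        ),
        apex_scans=np.array(
            [int(closest_index(sp.apex_k0, spec.mobility_values)) for sp in species],
            np.int64,
        ),
        apex_tofs=np.array(
            [int(closest_index(sp.mz, spec.mz_values)) for sp in species], np.int64
        ),
        anomaly_frame_ranges=anomaly_ranges,
        quad_events=quad,
        saturated=saturated,
    )
    stream = RawEventStream(
        pushes=push,
        tofs=tof,
        intensities=inten,
        n_frames=spec.n_frames,
        n_scans=spec.n_scans,
        n_tof=spec.n_tof,
        rt_values=rt,
        mz_min=spec.mz_min,
        mz_max=spec.mz_max,
        k0_min=spec.k0_min,
        k0_max=spec.k0_max,
        meta={
            "sample_name": spec.sample_name,
            "scheme": type(spec.scheme).__name__,
            "seed": spec.seed,
        },
    )
    return stream, quad, truth
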