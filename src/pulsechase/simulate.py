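"""Synthetic syncytial-embryo movies with known degradation kinetics.

The early fly embryo runs meta-synchronous nuclear cycles 10-14 in a shared
cytoplasm: nuclei accumulate a maternally translated reporter during
interphase, disperse it at nuclear envelope breakdown (NEB), and re-import it
after nuclear envelope formation (NEF).  A photoswitchable (Dronpa-like)
reporter adds a second, optically marked pool: 488-nm light drives a fraction
of the fluorescent ("light") pool dark, 405-nm light restores it.  This module
simulates the two-pool kinetics

    dL/dt = s - k(t) L        (synthesis enters the light pool)
    dD/dt =     - k(t) D      (degradation acts equally on both pools)

with instantaneous pool transfers at photoswitch events, and renders the
result as a two-channel movie (histone channel for segmentation, reporter
channel for quantification) with Poisson shot noise and Gaussian read noise.
Every movie carries its ground truth, so the downstream estimators can be
tested without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RateSchedule",
    "Cycle",
    "CyclePlan",
    "KineticParams",
    "PhotoswitchEvent",
    "EventRecord",
    "KineticTrajectory",
    "MovieLayout",
    "NoiseParams",
    "GroundTruth",
    "ImagingMovie",
    "make_cycle_plan",
    "simulate_kinetics",
    "peak_pulse_events",
    "render_movie",
    "add_measurement_noise",
    "decay_trace",
]

CONVERT_488 = "convert_488"
RESTORE_405 = "restore_405"


# ---------------------------------------------------------------------------
# degradation-rate schedules


@dataclass(frozen=True)
class RateSchedule:
    """Logistic degradation-rate profile k(t), in 1/min.

    k(t) = k_base + (k_max - k_base) / (1 + exp(-(t - t_half)/steepness))

    ``steepness`` (minutes) sets how abruptly the rate rises around
    ``t_half``: small values give a switch-like step (the wild-type Twine
    pattern at the MZT), large values a gradual ramp (the wild-type String
    pattern driven by the DNA replication checkpoint).
    """

    k_base: float
    k_max: float
    t_half: float
    steepness: float
    kind: str | None = None  # optional declared class: "switch" | "gradual"

    def __post_init__(self) -> None:
        if self.k_base < 0:
            raise ValueError("k_base must be >= 0")
        if self.k_max < self.k_base:
            raise ValueError("k_max must be >= k_base")
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")
        if self.kind not in (None, "switch", "gradual"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        z = -(t - self.t_half) / self.steepness
        out = self.k_base + (self.k_max - self.k_base) / (1.0 + np.exp(z))
        return out if out.ndim else float(out)

    @property
    def is_constant(self) -> bool:
        return self.k_max == self.k_base

    @staticmethod
    def constant(k: float) -> "RateSchedule":
        return RateSchedule(k_base=k, k_max=k, t_half=0.0, steepness=1.0)

    @staticmethod
    def switch_like(k_base: float, k_max: float, t_half: float,
                    steepness: float = 0.5) -> "RateSchedule":
        return RateSchedule(k_base, k_max, t_half, steepness, kind="switch")

    @staticmethod
    def gradual(k_base: float, k_max: float, t_half: float,
                steepness: float = 15.0) -> "RateSchedule":
        return RateSchedule(k_base, k_max, t_half, steepness, kind="gradual")


# ---------------------------------------------------------------------------
# nuclear-cycle plan


@dataclass(frozen=True)
class Cycle:
    index: int
    nef_time: float  # minutes
    neb_time: float | None  # None for the final (open) cycle


@dataclass(frozen=True)
class CyclePlan:
    """Ordered NEF/NEB event times for nuclear cycles 10-14.

    The final cycle has no NEB (cycle 14 does not divide within the modelled
    window); ``end_time`` closes the simulation horizon instead.
    """

    cycles: tuple[Cycle, ...]
    end_time: float

    def __post_init__(self) -> None:
        if not self.cycles:
            raise ValueError("plan must contain at least one cycle")
        prev_end = -math.inf
        for i, c in enumerate(self.cycles):
            last = i == len(self.cycles) - 1
            if c.neb_time is None and not last:
                raise ValueError("only the final cycle may lack neb_time")
            if c.neb_time is not None and not c.nef_time < c.neb_time:
                raise ValueError(f"cycle {c.index}: nef_time must precede neb_time")
            if c.nef_time < prev_end:
                raise ValueError("cycles must be ordered and non-overlapping")
            prev_end = c.neb_time if c.neb_time is not None else c.nef_time
        if self.end_time <= self.cycles[-1].nef_time:
            raise ValueError("end_time must lie beyond the final NEF")

    @property
    def start_time(self) -> float:
        return self.cycles[0].nef_time

    def interphase_durations(self) -> list[float]:
        out = []
        for c in self.cycles:
            end = c.neb_time if c.neb_time is not None else self.end_time
            out.append(end - c.nef_time)
        return out

    def cycle_lengths(self) -> list[float]:
        """NEF-to-NEF lengths (final cycle: NEF to end of window)."""
        starts = [c.nef_time for c in self.cycles] + [self.end_time]
        return [b - a for a, b in zip(starts[:-1], starts[1:])]

    def phase_at(self, t: float) -> tuple[str, Cycle]:
        """Return ('interphase'|'mitosis', cycle) for time t within the plan."""
        for i, c in enumerate(self.cycles):
            end = c.neb_time if c.neb_time is not None else self.end_time
            if c.nef_time <= t < end or (i == len(self.cycles) - 1 and t == end):
                return "interphase", c
            nxt = self.cycles[i + 1] if i + 1 < len(self.cycles) else None
            if c.neb_time is not None and nxt is not None and c.neb_time <= t < nxt.nef_time:
                return "mitosis", nxt
        raise ValueError(f"time {t} outside plan [{self.start_time}, {self.end_time}]")

    def cycle(self, index: int) -> Cycle:
        for c in self.cycles:
            if c.index == index:
                return c
        raise KeyError(index)


def make_cycle_plan(
    n_cycles: int,
    interphase_durations: Sequence[float],
    mitosis_duration: float,
    *,
    start: float = 0.0,
    last_cycle_index: int = 14,
) -> CyclePlan:
    """Build a gap-free alternation of interphases and mitoses.

    ``interphase_durations`` has one entry per cycle; the final entry sets the
    open last cycle's simulated span (that cycle gets no NEB).  Cycle indices
    count back from ``last_cycle_index`` so a 5-cycle plan covers cycles
    10-14.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if len(interphase_durations) != n_cycles:
        raise ValueError("need one interphase duration per cycle")
    if any(d <= 0 for d in interphase_durations) or mitosis_duration <= 0:
        raise ValueError("durations must be > 0")
    first_index = last_cycle_index - n_cycles + 1
    cycles = []
    t = float(start)
    for i, dur in enumerate(interphase_durations):
        last = i == n_cycles - 1
        neb = None if last else t + dur
        cycles.append(Cycle(index=first_index + i, nef_time=t, neb_time=neb))
        if not last:
            t = neb + mitosis_duration
    end_time = cycles[-1].nef_time + interphase_durations[-1]
    return CyclePlan(cycles=tuple(cycles), end_time=end_time)


# ---------------------------------------------------------------------------
# kinetics


@dataclass(frozen=True)
class KineticParams:
    """Reporter synthesis/degradation/photoswitching parameters.

    ``synthesis_rate`` is the maternal translation rate feeding the light
    pool (concentration/min); it may be a constant or a callable s(t).
    ``eps_off`` and ``eps_on`` are the fractions of the pool actually switched
    by a 488-nm conversion or 405-nm restoration pulse.
    """

    synthesis_rate: float | Callable[[float], float] = 0.0
    schedule: RateSchedule = field(default_factory=lambda: RateSchedule.constant(0.0))
    eps_off: float = 1.0
    eps_on: float = 1.0
    L0: float = 1.0
    D0: float = 0.0

    def __post_init__(self) -> None:
        if not callable(self.synthesis_rate) and self.synthesis_rate < 0:
            raise ValueError("synthesis_rate must be >= 0")
        for name in ("eps_off", "eps_on"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.L0 < 0 or self.D0 < 0:
            raise ValueError("initial pools must be >= 0")

    def s_at(self, t: float) -> float:
        s = self.synthesis_rate
        return float(s(t)) if callable(s) else float(s)

    @property
    def s_is_constant(self) -> bool:
        return not callable(self.synthesis_rate)


@dataclass(frozen=True)
class PhotoswitchEvent:
    time: float  # minutes
    action: str  # CONVERT_488 | RESTORE_405

    def __post_init__(self) -> None:
        if self.action not in (CONVERT_488, RESTORE_405):
            raise ValueError(f"unknown action {self.action!r}")


@dataclass(frozen=True)
class EventRecord:
    """Pool snapshot around an applied photoswitch event."""

    event: PhotoswitchEvent
    L_before: float
    D_before: float
    L_after: float
    D_after: float


@dataclass
class KineticTrajectory:
    """Light/dark pools and instantaneous rate on a time grid.

    Values at an event time are the post-event (right-limit) state; the
    pre-event state is preserved in ``event_records``.
    """

    time: np.ndarray  # minutes
    L: np.ndarray
    D: np.ndarray
    k: np.ndarray
    event_records: list[EventRecord] = field(default_factory=list)

    @property
    def total(self) -> np.ndarray:
        return self.L + self.D

    def L_at(self, t) -> np.ndarray | float:
        return np.interp(t, self.time, self.L)

    def D_at(self, t) -> np.ndarray | float:
        return np.interp(t, self.time, self.D)


def _validate_events(events: Sequence[PhotoswitchEvent]) -> None:
    times = [e.time for e in events]
    if any(b <= a for a, b in zip(times[:-1], times[1:])):
        raise ValueError("photoswitch events must be strictly time-ordered")


def _step_exact(L: float, D: float, s: float, k: float, h: float) -> tuple[float, float]:
    """Exact solution over a step where both s and k are constant."""
    if k == 0.0:
        return L + s * h, D
    decay = math.exp(-k * h)
    return L * decay + (s / k) * (1.0 - decay), D * decay


def _step_rk4(L: float, D: float, params: KineticParams, t: float, h: float,
              max_step: float = 0.01) -> tuple[float, float]:
    """RK4 with fixed substep <= max_step for time-varying k(t) (or s(t))."""
    n = max(1, math.ceil(h / max_step))
    dt = h / n
    k_of = params.schedule
    for i in range(n):
        ti = t + i * dt

        def deriv(tt: float, l: float, d: float) -> tuple[float, float]:
            kk = k_of(tt)
            return params.s_at(tt) - kk * l, -kk * d

        d1 = deriv(ti, L, D)
        d2 = deriv(ti + dt / 2, L + dt / 2 * d1[0], D + dt / 2 * d1[1])
        d3 = deriv(ti + dt / 2, L + dt / 2 * d2[0], D + dt / 2 * d2[1])
        d4 = deriv(ti + dt, L + dt * d3[0], D + dt * d3[1])
        L += dt / 6 * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0])
        D += dt / 6 * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1])
    return L, D


def simulate_kinetics(
    params: KineticParams,
    plan: CyclePlan,
    events: Sequence[PhotoswitchEvent] = (),
    time_grid: np.ndarray | None = None,
    *,
    dt: float = 1.0 / 60.0,
) -> KineticTrajectory:
    """Integrate the two-pool model over the plan, applying pulse events.

    Intervals with constant k and s use the exact exponential solution;
    otherwise fixed-step RK4 (substep <= 0.01 min).  Events transfer pool
    fractions instantaneously and conserve L + D exactly.
    """
    events = list(events)
    _validate_events(events)
    if time_grid is None:
        t0, t1 = plan.start_time, plan.end_time
        time_grid = np.linspace(t0, t1, int(round((t1 - t0) / dt)) + 1)
    else:
        time_grid = np.asarray(time_grid, dtype=float)
        if time_grid.ndim != 1 or time_grid.size < 2 or np.any(np.diff(time_grid) <= 0):
            raise ValueError("time_grid must be strictly increasing with >= 2 points")
    for e in events:
        if not time_grid[0] <= e.time <= time_grid[-1]:
            raise ValueError(f"event at t={e.time} outside the time grid")
    k_grid = np.asarray(params.schedule(time_grid), dtype=float)
    if np.any(k_grid < 0):
        raise ValueError("negative degradation rate on the time grid")

    # breakpoints: every grid point plus every event time
    exact_ok = params.schedule.is_constant and params.s_is_constant
    L, D = float(params.L0), float(params.D0)
    records: list[EventRecord] = []
    out_L = np.empty_like(time_grid)
    out_D = np.empty_like(time_grid)
    ev_iter = iter(events)
    next_ev = next(ev_iter, None)

    def apply_events_at(t: float) -> None:
        nonlocal L, D, next_ev
        while next_ev is not None and np.isclose(next_ev.time, t, atol=1e-12, rtol=0.0):
            Lb, Db = L, D
            if next_ev.action == CONVERT_488:
                moved = params.eps_off * L
                L, D = L - moved, D + moved
            else:
                moved = params.eps_on * D
                L, D = L + moved, D - moved
            records.append(EventRecord(next_ev, Lb, Db, L, D))
            next_ev = next(ev_iter, None)

    def advance(t_from: float, t_to: float) -> None:
        nonlocal L, D
        h = t_to - t_from
        if h <= 0:
            return
        if exact_ok:
            L, D = _step_exact(L, D, params.s_at(t_from), params.schedule.k_base, h)
        else:
            L, D = _step_rk4(L, D, params, t_from, h)
        L, D = max(L, 0.0), max(D, 0.0)

    apply_events_at(time_grid[0])
    out_L[0], out_D[0] = L, D
    for i in range(1, time_grid.size):
        t_prev, t_cur = time_grid[i - 1], time_grid[i]
        t = t_prev
        while next_ev is not None and t < next_ev.time <= t_cur:
            advance(t, next_ev.time)
            t = next_ev.time
            apply_events_at(t)
        advance(t, t_cur)
        out_L[i], out_D[i] = L, D
    return KineticTrajectory(time=time_grid, L=out_L, D=out_D, k=k_grid,
                             event_records=records)


def peak_pulse_events(
    plan: CyclePlan,
    *,
    offset: float = 4.5,
    stagger: float = 0.5,
    cycles: Sequence[int] | None = None,
) -> list[PhotoswitchEvent]:
    """Convert/restore event pairs at consecutive nuclear-concentration peaks.

    For each consecutive cycle pair (i, i+1): a 488-nm conversion at the peak
    of cycle i and a 405-nm restoration at the peak of cycle i+1, the peak
    taken as NEF + ``offset`` minutes.  When a restoration and the next
    conversion share a peak, the conversion is delayed by ``stagger`` minutes
    so events stay strictly ordered (both still on the 1-2 min plateau).
    """
    idx = [c.index for c in plan.cycles] if cycles is None else list(cycles)
    events: list[PhotoswitchEvent] = []
    for a, b in zip(idx[:-1], idx[1:]):
        t_conv = plan.cycle(a).nef_time + offset
        if events and events[-1].time >= t_conv:
            t_conv = events[-1].time + stagger
        events.append(PhotoswitchEvent(t_conv, CONVERT_488))
        events.append(PhotoswitchEvent(plan.cycle(b).nef_time + offset, RESTORE_405))
    return events


# ---------------------------------------------------------------------------
# rendering


@dataclass(frozen=True)
class MovieLayout:
    """Field-of-view geometry and optical parameters of the rendered movie.

    Defaults mirror a 20x confocal acquisition (1024x512 px, 0.6 um pixels,
    one frame per 20 s).  The nucleus count doubles each cycle, emulating the
    syncytial divisions; centers sit on a jittered hexagonal lattice.
    """

    height: int = 512
    width: int = 1024
    pixel_size_um: float = 0.6
    frame_interval_s: float = 20.0
    nuclear_radius_um: float = 3.0
    n_initial: int = 24  # nuclei in the first simulated cycle
    histone_amplitude: float = 120.0
    histone_background: float = 10.0
    enrichment_max: float = 3.0  # nuclear/cytoplasmic reporter ratio at peak
    enrichment_ramp_min: float = 4.0  # NEF -> plateau, minutes
    reporter_radius_factor: float = 1.5  # nucleoplasm extends past the chromatin spot
    jitter_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("degenerate field of view")
        if self.n_initial < 1:
            raise ValueError("need at least one nucleus")
        if self.enrichment_max <= 1.0:
            raise ValueError("enrichment_max must exceed the cytoplasmic level (1.0)")

    @property
    def nuclear_radius_px(self) -> float:
        return self.nuclear_radius_um / self.pixel_size_um

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval_s / 60.0


@dataclass(frozen=True)
class NoiseParams:
    """Poisson shot noise on expected photon counts plus Gaussian read noise.

    ``photons_per_unit`` converts model intensity units to expected photon
    counts (0 disables shot noise); ``read_sigma`` is in photon counts.  The
    seed is mandatory: every stochastic output is reproducible from it.
    """

    seed: int
    photons_per_unit: float = 20.0
    read_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.photons_per_unit < 0 or self.read_sigma < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def noiseless(self) -> bool:
        return self.photons_per_unit == 0 and self.read_sigma == 0


@dataclass
class GroundTruth:
    plan: CyclePlan
    trajectory: KineticTrajectory
    centers_by_cycle: dict[int, np.ndarray]  # (n, 2) row/col pixel coords
    nuclear_radius_px: float


@dataclass
class ImagingMovie:
    """Two-channel photon-count stack: channel 0 histone, channel 1 reporter."""

    frames: np.ndarray  # (T, 2, H, W), nonnegative
    frame_interval_s: float
    pixel_size_um: float
    event_log: list[PhotoswitchEvent] = field(default_factory=list)
    ground_truth: GroundTruth | None = None
    start_time_min: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 4 or f.shape[1] != 2:
            raise ValueError("frames must have shape (T, 2, H, W)")
        if f.shape[0] < 2:
            raise ValueError("movie must have at least 2 frames")
        if np.any(f < 0):
            raise ValueError("intensities must be >= 0")
        span = self.times_min
        for e in self.event_log:
            if not span[0] <= e.time <= span[-1]:
                raise ValueError(f"event at t={e.time} outside movie time span")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_min(self) -> np.ndarray:
        return self.start_time_min + np.arange(self.n_frames) * self.frame_interval_s / 60.0


def _hex_lattice_centers(n: int, height: int, width: int, margin: float,
                         jitter_frac: float, rng: np.random.Generator) -> np.ndarray:
    """n jittered centers on a hexagonal lattice filling the field of view."""
    usable = max((height - 2 * margin) * (width - 2 * margin), 1.0)
    spacing = math.sqrt(2.0 * usable / (math.sqrt(3.0) * n))
    while True:
        rows = []
        y = margin
        r = 0
        while y <= height - margin:
            x0 = margin + (spacing / 2.0 if r % 2 else 0.0)
            xs = np.arange(x0, width - margin + 1e-9, spacing)
            rows.append(np.column_stack([np.full_like(xs, y), xs]))
            y += spacing * math.sqrt(3.0) / 2.0
            r += 1
        pts = np.concatenate(rows, axis=0) if rows else np.empty((0, 2))
        if pts.shape[0] >= n:
            break
        spacing *= 0.95  # tighten until the lattice holds n points
        if spacing < 1.0:
            raise ValueError("field of view too small for requested nucleus count")
    order = rng.permutation(pts.shape[0])[:n]
    pts = pts[np.sort(order)]
    pts = pts + rng.normal(0.0, jitter_frac * spacing, size=pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], margin, height - margin)
    pts[:, 1] = np.clip(pts[:, 1], margin, width - margin)
    return pts


def _enrichment(dt_since_nef: float, layout: MovieLayout) -> float:
    """Nuclear/cytoplasmic reporter ratio as a function of time since NEF."""
    ramp = layout.enrichment_ramp_min
    if dt_since_nef < 0:
        return 1.0
    if dt_since_nef < ramp:
        return 1.0 + (layout.enrichment_max - 1.0) * dt_since_nef / ramp
    return layout.enrichment_max


def render_movie(
    traj: KineticTrajectory,
    plan: CyclePlan,
    layout: MovieLayout,
    noise: NoiseParams,
    event_log: Sequence[PhotoswitchEvent] = (),
) -> ImagingMovie:
    """Render the trajectory as a two-channel movie with embedded ground truth.

    Histone channel: Gaussian-profile nuclei during interphase, near-uniform
    dispersed signal during mitosis.  Reporter channel: cytoplasmic level
    L(t) everywhere, raised to enrichment(t - NEF) x L(t) inside nuclear
    disks; nuclear signal collapses to the cytoplasmic level at NEB.
    """
    if not (traj.time[0] <= plan.start_time and traj.time[-1] >= plan.end_time - 1e-9):
        raise ValueError("trajectory does not cover the cycle plan")
    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 0x5eed]))
    H, W = layout.height, layout.width
    r_px = layout.nuclear_radius_px
    margin = 2.5 * r_px
    sigma = r_px / 2.0

    centers_by_cycle: dict[int, np.ndarray] = {}
    first = plan.cycles[0].index
    for c in plan.cycles:
        n = layout.n_initial * 2 ** (c.index - first)
        centers_by_cycle[c.index] = _hex_lattice_centers(
            n, H, W, margin, layout.jitter_frac, rng)

    dt_min = layout.frame_interval_min
    n_frames = int(math.floor((plan.end_time - plan.start_time) / dt_min)) + 1
    times = plan.start_time + np.arange(n_frames) * dt_min
    frames = np.empty((n_frames, 2, H, W), dtype=np.float64)

    yy, xx = np.mgrid[0:H, 0:W]
    r_rep = layout.reporter_radius_factor * r_px
    patch = int(math.ceil(max(4 * sigma, r_rep + 1)))
    for i, t in enumerate(times):
        phase, cyc = plan.phase_at(t)
        L = float(traj.L_at(t))
        if phase == "interphase":
            centers = centers_by_cycle[cyc.index]
            hist = np.full((H, W), layout.histone_background, dtype=np.float64)
            rep = np.full((H, W), L, dtype=np.float64)
            enr = _enrichment(t - cyc.nef_time, layout)
            for (cy, cx) in centers:
                y0, y1 = max(int(cy) - patch, 0), min(int(cy) + patch + 1, H)
                x0, x1 = max(int(cx) - patch, 0), min(int(cx) + patch + 1, W)
                dy = yy[y0:y1, x0:x1] - cy
                dx = xx[y0:y1, x0:x1] - cx
                d2 = dy * dy + dx * dx
                hist[y0:y1, x0:x1] += layout.histone_amplitude * np.exp(-d2 / (2 * sigma * sigma))
                rep[y0:y1, x0:x1] = np.where(d2 <= r_rep * r_rep, enr * L, rep[y0:y1, x0:x1])
        else:
            # chromatin and reporter dispersed through the shared cytoplasm
            n_prev = centers_by_cycle[cyc.index - 1].shape[0] if (cyc.index - 1) in centers_by_cycle else layout.n_initial
            dispersed = layout.histone_amplitude * n_prev * 2 * math.pi * sigma * sigma / (H * W)
            hist = np.full((H, W), layout.histone_background + dispersed, dtype=np.float64)
            rep = np.full((H, W), L, dtype=np.float64)
        frames[i, 0] = hist
        frames[i, 1] = rep

    if not noise.noiseless:
        g = noise.photons_per_unit
        if g > 0:
            frames = rng.poisson(frames * g).astype(np.float64) / g
        if noise.read_sigma > 0:
            gain = g if g > 0 else 1.0
            frames = frames + rng.normal(0.0, noise.read_sigma / gain, size=frames.shape)
        np.clip(frames, 0.0, None, out=frames)

    gt = GroundTruth(plan=plan, trajectory=traj, centers_by_cycle=centers_by_cycle,
                     nuclear_radius_px=r_px)
    return ImagingMovie(frames=frames, frame_interval_s=layout.frame_interval_s,
                        pixel_size_um=layout.pixel_size_um,
                        event_log=list(event_log), ground_truth=gt,
                        start_time_min=plan.start_time)


# ---------------------------------------------------------------------------
# trace-level noise helper (shared noise model without full rendering)


def add_measurement_noise(values: np.ndarray, noise: NoiseParams,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply the movie noise model to a mean-intensity trace.

    Used for simulation studies that operate on nuclear traces directly; the
    noise model (Poisson on expected counts + Gaussian read noise) is the same
    one ``render_movie`` applies per pixel.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 0x7a5]))
    v = np.asarray(values, dtype=float)
    out = v.copy()
    g = noise.photons_per_unit
    if g > 0:
        out = rng.poisson(np.clip(v, 0, None) * g).astype(float) / g
    if noise.read_sigma > 0:
        gain = g if g > 0 else 1.0
        out = out + rng.normal(0.0, noise.read_sigma / gain, size=out.shape)
    return np.clip(out, 0.0, None)


def decay_trace(
    tau: float,
    *,
    I0: float = 100.0,
    t_rise: float = 4.0,
    t_onset: float = 6.0,
    duration: float = 25.0,
    dt: float = 1.0 / 3.0,
    noise: NoiseParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic final-cycle nuclear trace: import ramp, plateau, exponential
    decay with lifetime ``tau`` from ``t_onset`` — the shape seen when the
    degradation machinery engages during the last, open cycle."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.arange(0.0, duration + 1e-9, dt)
    I = np.where(t < t_rise, I0 * t / t_rise,
                 np.where(t < t_onset, I0, I0 * np.exp(-(t - t_onset) / tau)))
    if noise is not None:
        I = add_measurement_noise(I, noise, rng=rng)
    return t, I
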