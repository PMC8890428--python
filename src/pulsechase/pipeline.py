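"""End-to-end pipeline: simulate -> quantify -> kinetics (-> domains).

Given one configuration (and its single seed) the pipeline renders a
synthetic embryo movie, segments it, extracts the cycle-aligned nuclear
trace and per-cycle peaks, estimates per-cycle degradation rates from the
photoswitch pulse pairs, fits the final-cycle lifetime, classifies the rate
schedule, and runs the sequence-level degron mapping on supplied (or seeded
synthetic) inputs.  Identical config + seed give byte-identical CSV/JSON
outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .config import PipelineConfig, default_config
from .domains import (AMINO_ACIDS, DELAYED, NORMAL, DeletionConstruct,
                      localize_required_region, scan_conserved_window,
                      windows_to_frame)
from .kinetics import classify_schedule, fit_decay_time, rate_trajectory
from .quantify import detect_cycles, extract_peaks, measure_trace, segment_movie
from .simulate import (CyclePlan, ImagingMovie, KineticParams, NoiseParams,
                       make_cycle_plan, peak_pulse_events, render_movie,
                       simulate_kinetics)

__all__ = ["build_plan", "simulate_movie", "run_pipeline", "make_fixtures",
           "demo_constructs", "random_protein", "planted_motif_pair"]


def _sub_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    ss = np.random.SeedSequence([seed, stage])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def build_plan(cfg: PipelineConfig) -> CyclePlan:
    cp = cfg.cycle_plan
    return make_cycle_plan(cp.n_cycles, list(cp.interphase_durations),
                           cp.mitosis_duration,
                           last_cycle_index=cp.last_cycle_index)


def simulate_movie(cfg: PipelineConfig) -> ImagingMovie:
    """Simulate kinetics under the configured schedule and render the movie."""
    plan = build_plan(cfg)
    t_half_default = plan.cycles[-1].nef_time + 2.0  # rate rises at final-cycle onset
    schedule = cfg.schedule(t_half_default)
    params = KineticParams(synthesis_rate=cfg.kinetics.synthesis_rate,
                           schedule=schedule, eps_off=cfg.kinetics.eps_off,
                           eps_on=cfg.kinetics.eps_on, L0=cfg.kinetics.L0,
                           D0=cfg.kinetics.D0)
    events = peak_pulse_events(plan, offset=cfg.events.offset_min,
                               stagger=cfg.events.stagger_min)
    traj = simulate_kinetics(params, plan, events)
    noise = NoiseParams(seed=_sub_seed(cfg.seed, 1),
                        photons_per_unit=cfg.noise.photons_per_unit,
                        read_sigma=cfg.noise.read_sigma)
    return render_movie(traj, plan, cfg.imaging, noise, event_log=events)


def demo_constructs() -> list[DeletionConstruct]:
    """Three-construct worked example: two delayed-degradation deletions
    overlapping in 105-135 and one normally degrading N-terminal deletion."""
    return [
        DeletionConstruct("del60-135", 60, 135, DELAYED),
        DeletionConstruct("del105-180", 105, 180, DELAYED),
        DeletionConstruct("del5-80", 5, 80, NORMAL, note="overlaps NLS 36-41"),
    ]


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def planted_motif_pair(seed: int, *, length_a: int = 200, length_b: int = 200,
                       motif_len: int = 12, pos_a: int = 40, pos_b: int = 90
                       ) -> tuple[str, str, str]:
    """Seeded synthetic protein pair sharing one planted ungapped motif.

    Positions are 1-based.  These are synthetic stand-in sequences for
    testing the window scan; real paralog sequences are user-supplied FASTA.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFA57A]))
    a = list(random_protein(rng, length_a))
    b = list(random_protein(rng, length_b))
    motif = random_protein(rng, motif_len)
    a[pos_a - 1: pos_a - 1 + motif_len] = motif
    b[pos_b - 1: pos_b - 1 + motif_len] = motif
    return "".join(a), "".join(b), motif


def _rates_frame(rates) -> pd.DataFrame:
    return pd.DataFrame([{
        "from_cycle": r.from_cycle if r.from_cycle is not None else -1,
        "to_cycle": r.to_cycle if r.to_cycle is not None else -1,
        "t_mid_min": r.t_mid,
        "delta_t_min": r.delta_t,
        "ratio": r.ratio if r.ratio is not None else np.nan,
        "k_per_min": r.k if r.k is not None else np.nan,
        "flag": r.flag,
    } for r in rates], columns=["from_cycle", "to_cycle", "t_mid_min",
                                "delta_t_min", "ratio", "k_per_min", "flag"])


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path,
                 *, sequences: tuple[str, str] | None = None,
                 constructs: list[DeletionConstruct] | None = None) -> dict:
    """Run all stages, write stage outputs plus a JSON run report.

    ``sequences``/``constructs`` override the seeded synthetic demo inputs of
    the domain-mapping stage.  Returns the run report (also written as
    ``report.json``), which records the resolved config, per-stage status and
    SHA-256 checksums of every CSV/JSON output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "config": cfg.resolved(), "stages": [],
                    "checksums": {}}

    # --- stage 1: simulate -------------------------------------------------
    movie = simulate_movie(cfg)
    pio.write_movie(out / "movie.tif", movie)
    report["stages"].append("simulate")

    # --- stage 2: quantify -------------------------------------------------
    masks = segment_movie(movie, cfg.segmentation)
    pio.write_masks(out / "masks.tif", masks)
    trace = measure_trace(movie, masks)
    pio.write_trace(out / "trace.csv", trace)
    cycles = detect_cycles(movie, masks, cfg.cycle_detection)
    cycles.to_frame().to_csv(out / "cycles.csv", index=False)
    peaks = extract_peaks(trace, cycles, offset=cfg.peaks.offset_min,
                          window=cfg.peaks.window_min)
    peaks.table.to_csv(out / "peaks.csv", index=False)
    report["stages"].append("quantify")

    # --- stage 3: kinetics -------------------------------------------------
    def cycle_of_time(t: float) -> int:
        idx = -1
        for e in cycles.entries:
            if cycles.frame_time(e.nef_frame) <= t + 1e-9:
                idx = e.cycle_index
        return idx

    rates = rate_trajectory(trace, movie.event_log, eps_off=cfg.kinetics.eps_off,
                            eps_on=cfg.kinetics.eps_on, cycle_of_time=cycle_of_time)
    _rates_frame(rates).to_csv(out / "rates.csv", index=False)

    last = cycles.entries[-1]
    t0 = cycles.frame_time(last.nef_frame)
    sel = trace.time_min >= t0
    fit = fit_decay_time(trace.time_min[sel], trace.mean_corrected[sel])
    fits = pd.DataFrame([{
        "sample": "final_cycle", "tau_min": fit.tau, "tau_se": fit.tau_se,
        "r2": fit.r_squared, "onset_min": fit.t_onset, "flag": fit.flag,
    }])
    fits.to_csv(out / "decay_fits.csv", index=False)

    schedule_info: dict = {"classified": False}
    usable = [r for r in rates if r.k is not None]
    if len(usable) >= 3:
        plan = build_plan(cfg)
        sf = classify_schedule(usable, cycle_length=float(np.median(plan.cycle_lengths())),
                               threshold=cfg.classify.threshold)
        schedule_info = {
            "classified": True, "class": sf.klass, "abruptness": sf.abruptness,
            "threshold": sf.threshold, "k_base": sf.schedule.k_base,
            "k_max": sf.schedule.k_max, "t_half": sf.schedule.t_half,
            "steepness": sf.schedule.steepness, "residual_sse": sf.residual_sse,
            "flags": list(sf.flags),
        }
    pio.write_json(out / "schedule.json", schedule_info)
    report["stages"].append("kinetics")

    # --- stage 4: domains --------------------------------------------------
    if sequences is None:
        seq_a, seq_b, _ = planted_motif_pair(_sub_seed(cfg.seed, 4))
    else:
        seq_a, seq_b = sequences
    cons = constructs if constructs is not None else demo_constructs()
    call = localize_required_region(cons)
    pio.write_json(out / "region_call.json", call.to_dict())
    hits = scan_conserved_window(seq_a, seq_b, L=12, min_identity=0.9)
    windows_to_frame(hits).to_csv(out / "conserved_windows.csv", index=False)
    report["stages"].append("domains")

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if f.name == "report.json":
            continue
        report["checksums"][f.name] = pio.sha256_file(f)
    pio.write_json(out / "report.json", report)
    return report


# ---------------------------------------------------------------------------
# canonical fixtures


def make_fixtures(out_dir: str | Path, seed: int) -> dict:
    """Write the canonical seeded test fixtures and a checksum manifest.

    Contents: one small movie per rate-schedule class, a trapezoid trace CSV
    with a known plateau, the three-construct deletion table, and a planted-
    motif FASTA pair.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}}

    for kind in ("switch", "gradual"):
        base = default_config(seed=_sub_seed(seed, 10 if kind == "switch" else 11))
        cfg = dataclasses.replace(
            base, kinetics=dataclasses.replace(base.kinetics, schedule_kind=kind))
        movie = simulate_movie(cfg)
        pio.write_movie(out / f"movie_{kind}.tif", movie)

    t = np.arange(0.0, 10.0 + 1e-9, 1.0 / 3.0)
    plateau = np.where((t >= 4.0) & (t <= 6.0), 10.0,
                       np.where(t < 4.0, 10.0 * t / 4.0,
                                np.clip(10.0 * (10.0 - t) / 4.0, 0, None)))
    pd.DataFrame({"time_min": t, "mean_corrected": plateau,
                  "n_nuclei": np.full(t.size, 10), "background": np.zeros(t.size)}
                 ).to_csv(out / "trapezoid_trace.csv", index=False)

    pd.DataFrame([{"name": c.name, "start": c.start, "end": c.end,
                   "phenotype": c.phenotype, "note": c.note}
                  for c in demo_constructs()]).to_csv(out / "constructs.csv", index=False)

    seq_a, seq_b, motif = planted_motif_pair(seed)
    (out / "seq_a.fasta").write_text(f">synthetic_seq_a planted motif at 40\n{seq_a}\n")
    (out / "seq_b.fasta").write_text(f">synthetic_seq_b planted motif at 90\n{seq_b}\n")
    (out / "motif.txt").write_text(motif + "\n")

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = pio.sha256_file(f)
    pio.write_json(out / "manifest.json", manifest)
    return manifest
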