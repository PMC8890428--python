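# pulsechase

Quantitative inference of protein degradation dynamics from optical
pulse-chase movies of early (syncytial) fly embryos — with a fully synthetic,
ground-truth-carrying data generator, so the whole chain is testable end to
end without any microscope.

## The problem

At the *Drosophila* maternal-to-zygotic transition (MZT) the cell cycle is
remodelled by downregulating Cdc25 phosphatase activity. The two Cdc25
paralogs behave differently: one is degraded gradually over the last few
nuclear cycles, the other in a switch-like burst at the MZT. Measuring these
dynamics from live imaging is awkward because the nuclear envelope breaks
down every cycle (NEB) and reforms (NEF), so nuclear reporter intensity
oscillates; only the per-cycle peak — reached about 4 minutes after NEF and
stable for 1–2 minutes — is a usable proxy for concentration.

A reversibly photoswitchable fluorophore (Dronpa-like: 488-nm light drives it
dark, 405-nm light restores it) turns this into an optical pulse chase.
Darken the fluorescent pool at the peak of one cycle, restore it at the peak
of the next; the restored increment reveals how much of the marked ("old")
protein survived the chase interval Δt:

```
r = (I_post405 − I_pre405) / (ε_on · ε_off · I_preconvert),      k = −ln(r) / Δt
```

where `I_preconvert` is the peak intensity just before conversion,
`I_pre405`/`I_post405` are the next peak's intensities just before/after
restoration, and ε_off, ε_on are the switching efficiencies. Subtracting
`I_pre405` removes newly synthesized protein, which makes the estimate
independent of the maternal translation rate — the property that makes the
estimator trustworthy in a system with ongoing synthesis.

## What the package does

- **`simulate`** — two-pool kinetics (light/dark) `dL/dt = s − k(t)L`,
  `dD/dt = −k(t)D` with instantaneous pulse transfers, logistic rate
  schedules `k(t)` (switch-like vs gradual), and rendering to two-channel
  movies (histone + reporter) with nuclear-cycle structure, per-cycle
  doubling of nuclei, and Poisson + Gaussian noise. Ground truth is embedded.
- **`quantify`** — nuclear segmentation (Otsu on smoothed histone frames,
  watershed splitting), background-corrected field-averaged nuclear traces,
  NEF/NEB detection from the nucleus-count time series, per-cycle peak
  plateaus.
- **`kinetics`** — the converted/restored-ratio rate estimator, per-pair rate
  trajectories, exponential lifetime fits (log-linear, τ = −1/slope),
  switch/gradual schedule classification, and one-way ANOVA + Tukey HSD
  group comparison.
- **`domains`** — deletion-construct interval logic (candidate degron =
  intersection of delayed deletions minus union of normal ones) and an
  ungapped fixed-length conserved-window scan of two protein sequences.

## Worked example

```bash
python examples/pulse_chase_rates.py
```

prints (seed 42):

```
chase interval        k_hat (/min)   k_true (/min)
t =   4.5- 15.5 min         0.0085         0.0100
t =  16.0- 28.5 min         0.0091         0.0100
t =  29.0- 44.5 min         0.0093         0.0100
t =  45.0- 68.5 min         0.0370         0.0356

schedule class: switch (abruptness 3.0 vs threshold 2.0)
```

Each row is one convert/restore pulse pair: the estimated first-order
degradation rate over that chase interval next to the simulation's true mean
rate. The flat-then-jump pattern (low rate through cycle 13, ~4× jump into
cycle 14) is the switch-like schedule; the classifier fits a logistic k(t)
and labels it `switch` because the fitted transition is much sharper than
half a cycle length. The other examples cover movie synthesis
(`simulate_movie.py`), segmentation and peak extraction
(`quantify_movie.py`), lifetime fitting with ANOVA/Tukey group comparison
(`lifetime_and_groups.py`), and degron mapping (`degron_mapping.py`), e.g.:

```
candidate region: [(105, 135)] (31 residues, 1-based inclusive)
top hit: A:40 B:90 identity 1.00 window FSTIPVIRFVCR
```

A thin CLI wraps the same functions:
`pulsechase run --out OUT --seed 1`, `pulsechase simulate|quantify`,
`pulsechase kinetics rates|lifetime|compare`,
`pulsechase domains localize|scan`, `pulsechase fixtures`.

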