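# Methods

## Kinetic model

The reporter is modelled as two well-mixed pools: the fluorescent ("light")
pool L and the photoswitched ("dark") pool D. Between photoswitch events

    dL/dt = s(t) − k(t) · L
    dD/dt =       − k(t) · D

with synthesis rate `s` (concentration/min; maternal translation) and
first-order degradation rate `k(t)` (1/min). Two modelling commitments,
both required for the ratio estimator to isolate the aged pool:

- **Synthesis feeds the light pool only.** Newly made protein matures into
  the fluorescent state; it never appears dark.
- **Degradation acts equally on both pools.** Photoswitching is a
  chromophore state, not a protein modification the degradation machinery
  could read.

A 488-nm conversion pulse instantaneously moves a fraction ε_off of L into
D; a 405-nm restoration pulse moves ε_on of D back into L. Events conserve
L + D exactly.

Rate schedules are logistic,

    k(t) = k_base + (k_max − k_base) / (1 + exp(−(t − t_half)/steepness)),

which covers the two biologically relevant shapes with one parameterization:
a **switch-like** step (small `steepness`, the wild-type pattern of the
MZT-degraded paralog) and a **gradual** ramp (large `steepness`, the
checkpoint-driven pattern of the other paralog). Defaults: k_base = 0.01/min,
k_max = 0.25/min, t_half = 2 min after the final cycle's NEF, steepness
0.5 min (switch) or 15 min (gradual).

**Integration.** Intervals on which k and s are constant use the exact
exponential solution (this doubles as an internal oracle); time-varying
schedules use fixed-step RK4 with substeps ≤ 0.01 min. The simulation-level
tests verify the RK4 path against quadrature of the integrating-factor
solution to 1e−6 relative error.

## The pulse-chase estimator

With peak intensities I_preconvert (just before conversion at the cycle-i
peak), I_pre405 and I_post405 (just before/after restoration at the
cycle-i+1 peak), the surviving fraction of the marked pool is

    r = (I_post405 − I_pre405) / (ε_on · ε_off · I_preconvert),
    k̂ = −ln(r) / Δt .

Subtracting I_pre405 removes protein synthesized during the chase, so k̂ is
exactly synthesis-invariant; the nuclear enrichment factor cancels because
all three reads are taken at the same phase relative to NEF. For a
time-varying rate, k̂·Δt equals ∫k dt over the chase interval. Edge cases:
r ≥ 1 is reported as k = 0 with a `no_decay` flag; a restored increment ≤ 0
is a `no_recovery` flag with k undefined; a nonpositive converted pool is an
error.

**Pulse placement.** The nuclear peak is reached ~4 min after NEF and is
stable for 1–2 min. The simulated protocol places pulses at NEF + 4.5 min
(and staggers a conversion sharing a peak with a restoration by 0.5 min), so
the frames sampled just before and just after each pulse both sit on the
plateau. Peak extraction for the PeakSeries keeps the canonical
offset = 4 min, window = 1 min.

**Known bias.** Trace reads are frame-quantized: the "just before" read
precedes the pulse by up to one frame interval, during which L keeps
evolving. At the default 20–30 s frame interval this biases k̂ by roughly
5–10% toward zero for slowly decaying pools — visible in the worked example
(k̂ ≈ 0.009 vs k = 0.010/min) and well inside the 15% per-estimate tolerance
the recovery tests assert.

## Synthetic movies

The renderer emulates the statistical structure the analysis relies on and
nothing more:

- **Cycle plan**: gap-free alternation of interphases and mitoses; defaults
  8, 10, 13, 21 min for cycles 10–13 plus an open final cycle (no NEB),
  mitoses 3 min. Only the relative structure matters for testing.
- **Nuclei**: jittered hexagonal lattice, count doubling every cycle;
  histone channel renders Gaussian chromatin spots (σ = r/2) during
  interphase and a near-uniform dispersed signal during mitosis. The
  reporter fills a nuclear disk 1.5× the chromatin radius — nucleoplasm
  extends past the compact chromatin signal — which keeps segmentation masks
  strictly inside the region of uniform nuclear reporter, so mask-size
  fluctuations cannot bias the measured means.
- **Nuclear enrichment**: reporter nuclear/cytoplasmic ratio ramps linearly
  from 1 at NEF to 3 at NEF + 4 min, holds through the interphase, and
  collapses at NEB; cytoplasmic level is L(t) everywhere.
- **Noise**: Poisson on expected photon counts (default 20 photons per
  intensity unit) plus Gaussian read noise (σ = 3 counts), seeded; the seed
  is a required field and every stochastic output is reproducible from it.
- **Geometry**: full-frame default 1024×512 px at 0.6 µm/px, one frame per
  20 s. The demo configuration (192×256 px, 6 initial nuclei) and the
  replicated-study configuration (160×208 px, 4 initial nuclei, 30 s frames)
  are scaled-down choices that preserve the cycle structure and SNR regime
  while keeping a five-cycle movie renderable and quantifiable in a few
  seconds.

Not modelled (deliberately): 3D, nuclear movement and cytoplasmic flows,
photobleaching beyond the modelled switching, chromatin texture, Dronpa
thermal relaxation, nucleo-cytoplasmic shuttling kinetics. Passing tests
therefore demonstrate correctness of the inference chain under the stated
noise and geometry assumptions, not robustness to drift, flows or
illumination inhomogeneity in real recordings.

## Quantification

- **Segmentation**: Gaussian smoothing (σ default 2 px ≈ half the nuclear
  radius), Otsu threshold (percentile threshold available), area filter,
  and optional watershed splitting seeded at intensity maxima at least one
  nuclear radius apart. A contrast guard — (p99.9 − median)/(median − p1)
  below 2 — returns an empty mask for featureless frames (mitotic dispersal,
  blank fields) instead of thresholding noise.
- **Trace**: per frame, nuclear mean reporter intensity over all labelled
  pixels minus the median reporter intensity over the cytoplasm (complement
  of the 3-px-dilated mask union, eroded 5 px), floored at 0; frames without
  nuclei are NaN (missing, not zero). The correction is linear, so scaling
  the reporter channel scales the trace exactly.
- **Cycle detection**: NEB = first frame of a sustained (≥ 3 frames) drop of
  the nucleus count below 0.5× the preceding interphase plateau; NEF = first
  frame of the sustained recovery; indices count back from the final cycle
  (14 by default). Detection depends only on counts, hence is invariant to
  intensity scaling.
- **Peaks**: mean of the corrected trace over [NEF+4, NEF+5] min; cycles too
  short for the window are omitted with a warning.
- Traces are field-averaged (all nuclei per frame), not per-nucleus tracked;
  per-nucleus lineage tracking is out of scope.

## Lifetime fitting and classification

- **Onset rule**: the decline onset is the last maximum before ≥ 3
  consecutive decreases, detected on a 3-frame moving average so single
  noisy frames do not trigger it; the fit uses raw values.
- **Fit**: least squares of ln(I − floor) against t (floor default 0);
  τ = −1/slope with its standard error propagated from the slope; R² is
  reported even when poor. Non-declining series get τ = ∞ with a `stable`
  flag. Log-linear fitting is deterministic and closed-form; for clean
  exponentials it is exact, and the seeded recovery study (τ ∈ {3, 6, 12}
  min, 50 replicates each at default noise) keeps the median relative error
  under 10%. Near the noise floor the log transform is biased — use a
  nonzero `floor` when a background residual is expected.
- **Schedule classification**: a logistic k(t) is fitted to the rate
  estimates by grid search over (t_half, steepness) with the amplitude
  solved linearly (nonnegative). Abruptness = median cycle length / fitted
  steepness when the fitted amplitude is non-negligible, else 0; the class
  is `switch` iff abruptness ≥ 2 — i.e. the fitted transition is sharper
  than half a cycle length. All-equal rates are `gradual` with a
  `zero_amplitude` flag. The threshold separates the two simulated classes
  by a wide margin (observed abruptness ≈ 3–20 vs ≈ 0.9).
- **Group comparison**: one-way ANOVA (scipy) followed by Tukey's HSD
  (statsmodels); both are cross-checked in the tests against direct
  textbook/studentized-range formulas to 1e−9. Infinite lifetimes (stable
  traces) are excluded with a warning, never imputed; each group must retain
  ≥ 2 finite values.

## Degron mapping

Residue coordinates are 1-based inclusive everywhere; a construct named
`del60-135` deletes residues 60 through 135 inclusive (this convention is
why the canonical three-construct example yields a 31-residue interval —
[105, 135] — rather than 30). The candidate region is the intersection of
all delayed-phenotype deletions minus the union of all normal-phenotype
deletions, computed on integer residue sets and returned as contiguous
intervals; an empty result carries an `inconsistent_or_uninformative` flag.
The conserved-window scan evaluates all ungapped position pairs at fixed
window length (default 12) with exact-match identity; `X` matches nothing,
including another `X`. Similarity-matrix scoring is intentionally absent:
the scan reports conservation, not alignment score. Real paralog sequences
are user-supplied FASTA; the repository generates only synthetic,
motif-planted stand-ins.

## Reproducibility

One top-level seed per configuration; per-stage substreams are derived
deterministically via `numpy.random.SeedSequence`. Identical config + seed
give byte-identical CSV/JSON outputs (checksummed in the run report), and
the test suite asserts this end to end. Unknown configuration keys are
rejected at load time rather than silently ignored.
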