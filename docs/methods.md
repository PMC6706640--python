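# Methods

## The measurement model

A screening sample is one of three roles: the metabolite mix alone (M),
the protein alone (P), or protein plus mix (PM). Each sample is acquired
as a spin-lock triple — two short-delay (10 ms) replicates sandwiching one
long-delay spectrum (200 ms; 400 ms for proteins under 40 kDa, whose
relaxation enhancement is weaker). The two short replicates are summed,
which both averages time-dependent drift and matches the intensity scale
of the long spectrum (the long experiment accumulates twice the scans of
each short replicate; the synthetic generator renders the long spectrum
with a 2× scan factor for the same reason).

Binding is modelled as two-state fast exchange. The bound ligand fraction
p_b at total protein P, total ligand L and dissociation constant KD is the
smaller root of the binding quadratic, evaluated in the numerically stable
form 2PL / (b + sqrt(b² − 4PL)) with b = P + L + KD. The observed
relaxation rate is the population average
r_obs = (1 − p_b)·r_free + p_b·r_bound, and each peak's amplitude after a
spin lock of t seconds is A·exp(−r_obs·t). Amplitude attenuation, not
linewidth broadening, carries the effect, because the pipeline quantifies
window maxima; an explicit linewidth coupling is deliberately not
modelled.

The relaxation factor of a peak is

    ΔRF = M_long/M_short − (PM − P)_long/(PM − P)_short,

where (PM − P) denotes the protein-subtracted PM spectrum: the subtraction
is performed pointwise on the spectra *before* the window maximum is
taken. Taking maxima of PM and P separately and subtracting them
afterwards mixes intensities from different positions in the window and
leaks the protein envelope's slope into ΔRF; pointwise subtraction cancels
the envelope exactly and is what makes the noiseless pipeline agree with
the closed form ΔRF = exp(−r_free·Δt) − exp(−r_obs·Δt) (Δt = 0.19 s at the
200 ms long delay) to machine precision. M and PM spectra are always
paired at the same long delay; cross-delay comparison is refused.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| protein_conc | 15 µM | protein monomer concentration in all samples |
| metabolite_conc | 200 µM | concentration of each metabolite |
| r_free | 1 /s | spin-lock relaxation rate of a free metabolite signal |
| r_bound | 60 /s | rate while protein-bound |
| stability_max | 0.05 | max relative difference of PM short replicates |
| gain_min | −0.05 | intensity-gain floor on the M-normalised scale |
| snr_min | 2.0 | minimum S/N of the PM − P − M residual (0 disables) |
| overlap_range | 0.025 ppm | mix-design clash distance and window half-width |
| similarity_threshold | 0.5 | allosteric (below) vs competitive (at/above) |
| target_fpr | 0.05 | false-positive budget for cutoff selection |

The rates r_free = 1/s and r_bound = 60/s are configuration defaults
chosen so that KDs between 10 µM and 1 mM at the screen concentrations
span the practically relevant ΔRF range (roughly 0.05–0.5); they are not
physical claims about any real pair, and the generator's KDs must not be
read as estimates of real interactions.

## Quality filters

Three per-peak gates, each a deterministic function of stored numbers, so
their order is irrelevant:

* **Stability**: |max_a − max_b| / mean(max_a, max_b) of the two PM
  short-delay replicates must not exceed 0.05. The denominator is the
  symmetric mean — the 5% criterion is stated in the literature without a
  denominator, and the symmetric form is scale-free and direction-blind.
  A window with non-positive mean intensity is treated as infinitely
  unstable.
* **Gain**: peaks whose protein-subtracted PM intensity exceeds the
  mix-alone reference produce M − (PM − P) < 0 on the scale where the
  reference window maximum is 1; below −0.05 the peak gained intensity
  (e.g. a chemical conversion product) and is excluded. The normalisation
  scale is a package choice; −0.05 then reads as "a 5% apparent gain".
* **S/N**: the largest |PM − P − M| residual in the window, over the noise
  s.d. estimated from a signal-free region (default 10.5–11.0 ppm, linear
  baseline removed), must exceed 2. The long-delay difference spectrum is
  used; the short-delay choice is a plausible alternative, and the
  threshold is configurable for sensitivity analysis. Setting snr_min = 0
  disables the gate, which idealised noise-free data need (their residual
  is identically zero for every non-binder, which is also why noiseless
  null studies legitimately report most pairs as unquantifiable).

Peak-level ΔRF values free of all flags are averaged into one value per
pair (mean over qualifying peaks, then mean over measurement replicates;
median and max policies are available and recorded in provenance — the
aggregation rule is a package decision, as is retaining negative ΔRF
values in the matrix and letting only thresholding treat them as
non-interactions).

## Calibration of the detection cutoff

Detection is strict: ΔRF > cutoff. Pairs in the reference set are
positives, all other evaluable pairs negatives; cells without a single
qualifying peak are excluded from both classes (their count is reported),
with an option to count them as never-detected negatives instead. The ROC
is exact — candidate cutoffs are all observed ΔRF values plus {0, 0.5} — 
and a fixed grid over [0, 0.5] is available for parity with grid-swept
analyses. The operating cutoff is the smallest candidate whose FPR is at
or below the target, which maximises TPR subject to the bound since both
rates are non-increasing in the cutoff. AUC is the trapezoidal area of
the curve ordered by (FPR, TPR) and equals the probability that a random
positive outscores a random negative with ties counted half.

## Mix design

The annealer minimises the spectral-overlap penalty: every same-mix pair
of peaks from different metabolites closer than 0.025 ppm contributes 100,
scaled by the product of relative intensities when intensity scoring is
on. Moves relocate two random metabolites per step (swapping with a random
occupant when the target mix is full); acceptance follows Metropolis with
a linear schedule from T = 10,000 to 25, plus an exponential refinement
phase (50 → 25, 1,000 steps). The default desk-scale schedule shortens the
main phase to 20,000 steps with 3 restarts; the published-scale settings
(500,000 steps, 10 restarts) are available via
`AnnealSchedule.published()`. The search stops early at score zero, ties
between equal-score designs break to the lexicographically smallest
assignment in metabolite-id order, and must-separate pairs (metabolites
that could react enzymatically) and forced placements are honoured as hard
constraints, with curated post-hoc swaps supported only as forced
assignments.

Window compilation keeps a peak when its distance to every
other-metabolite peak of the mix exceeds the overlap range, and gives it a
window of one overlap range per side. Adjacent windows that would overlap
are truncated at the midpoint between their source peaks (with a 1 µppm
guard gap), keeping windows pairwise disjoint within a mix without
dropping peaks; windows narrower than 0.005 ppm after truncation are
dropped, and metabolites left without any window are reported, not
errored.

## What the synthetic generator does and does not emulate

Emulated: Lorentzian lineshapes (half-width 0.004 ppm) at catalogued
shifts; spin-lock amplitude attenuation with binding-enhanced rates; a DSS
reference line at 0 ppm (exempt from degradation); a per-sample
chemical-shift miscalibration (σ 0.004 ppm) shared by the sample's three
spectra, as drift between samples dominates drift within one acquisition;
additive Gaussian noise per point; first-order metabolite degradation
applied multiplicatively per acquisition stage (short_a → long → short_b),
so the stability filter is exercised exactly as designed; and a smooth
protein envelope (three Gaussian humps, a stable function of the protein
id) present identically in P and PM so the subtraction step is
non-trivial. All randomness derives from one seed; a study is reproducible
byte for byte, and changing only the nuisance seed changes noise and
offsets but never the truth.

Not emulated: scalar-coupling multiplets, solvent/water artifacts,
field-inhomogeneity lineshapes, linewidth broadening upon binding, phase
or baseline distortions beyond the linear detrend the noise estimator
applies. Passing tests on synthetic data therefore demonstrate the
*pipeline arithmetic and decision rules*, not robustness to every
real-spectrum pathology.

## Numerical choices

* Spectra live on a uniform descending ppm grid (default −0.5 to 11.2 ppm,
  1 mppm step, which keeps a signal-free noise region above 10.5 ppm).
  Calibration snaps the DSS maximum to 0 by an integer number of grid
  steps (zero-filled edges), so all calibrated spectra of a study share
  one axis and no interpolation error enters the ratios; the residual is
  at most half a grid step. Non-uniform grids fall back to axis shifting
  plus linear interpolation in the difference step.
* Lorentzians are rendered with a finite support of ±0.5 ppm: distant
  peaks contribute exactly zero to a window, which is what lets the
  noiseless closed-form tests demand machine precision. The truncated tail
  is below 6 × 10⁻⁵ of the peak height at the cutoff.
* Synthetic peak positions land on grid points; with zero calibration
  offset the sampled maximum equals the analytic amplitude exactly.
* ΔRF evaluation refuses non-positive denominators (the peak is marked
  unevaluable) instead of propagating NaN or infinities.
* Degenerate inputs are contracts, not crashes: empty reference sets are
  valid until the ROC needs them; metabolites without windows are reported
  conditions; a flat spectrum is a calibration error naming the cause.

## Scale of the shipped analyses

The default test-suite and acceptance studies run at desk scale: a 20 × 20
screen (62 measurements, 186 spectra) for parameter recovery, 3 × 4 to
8 × 10 studies for closed-form and pipeline checks, 20-seed annealer
convergence on a 20-metabolite library, and confusion arithmetic at the
full 29 × 55 grid. These sizes were chosen so each analysis completes in
seconds while every rate being tested (FPR at the 5% budget, TPR of
planted binders) still rests on hundreds of negative and tens of positive
pairs.

## Known limitations

* The screen quantifies binding-induced relaxation, not affinity: ΔRF is
  monotone in KD at fixed rates but confounds KD with r_bound, so no KD
  estimation is attempted.
* Chemical similarity is consumed from a precomputed table; the package
  never computes structural similarity itself, and the 0.5
  allosteric/competitive boundary is a heuristic proxy, with equality
  assigned to the competitive side.
* Only previously known interactions count as positives in calibration,
  so the true-positive rate underestimates the real recovery whenever
  genuinely novel interactions exist — an inherent property of
  benchmarking against an incomplete reference.
* The annealer is a simplified re-implementation (relocate/swap move set);
  exact parity with any specific mix-design tool is a non-goal.
* Bruker/JCAMP raw formats are out of scope; measured data enter through
  the plain two-column text export described in `t1screen.spectra`.
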