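# Methods

`breathlock` implements the statistical machinery of a paired-condition
(nasal vs oral breathing) resting-state fMRI analysis of band-limited
functional connectivity and respiration–BOLD phase-locking, together with a
synthetic cohort generator that provides ground truth for every stage. This
note describes the models, the defaults and why they were chosen, the
numerical decisions, and the limits of what the synthetic validation shows.

## The analysis band

All connectivity and phase analysis is restricted to the intermediate
frequency band 0.1–0.2 Hz (center ≈ 0.16 Hz). With breathing near 0.31 Hz,
half the respiratory rhythm (~0.155 Hz) falls inside this band, which is
the premise of the entrainment analysis. BOLD is sampled at TR = 2 s
(Nyquist 0.25 Hz), so the respiratory fundamental itself is not directly
representable on the BOLD grid — it folds to ≈ 0.19 Hz, which is why the
aliasing control (below) exists.

## Synthetic cohort generator

The generator emulates the study conditions: 20 paired subjects, 600 s
runs, TR 2 s, respiration belt at 50 Hz, breathing rate 0.31 ± 0.04 Hz
between subjects, heart rate ~69 ± 10 bpm with RMSSD 17 ± 6 ms, 133 ROIs,
and one condition-dependent hub per condition.

**Respiration.** A quasi-sinusoid whose instantaneous frequency follows an
Ornstein–Uhlenbeck process (correlation time 30 s, stationary SD 0.04 Hz —
within-run rate variability on the same scale as the between-subject
spread). Breath amplitudes carry lognormal breath-to-breath jitter (10%)
and a period-2 alternation of depth 0.8 (alternating deeper/shallower
breaths). The alternation matters: it creates a genuine subharmonic at
f0/2 ≈ 0.155 Hz, which is the component of the belt signal that survives
band-limiting to 0.1–0.2 Hz and carries respiratory phase into the
analysis band. Without some half-harmonic content the band-limited
respiration phase would be pure noise and no phase-locking analysis could
work on principle.

**Cardiac RR intervals.** AR(1) jitter (lag-1 correlation 0.3) around
60000/HR ms, with the innovation variance solved from
E[RMSSD] = √(2·var·(1−ρ)) so the sample RMSSD lands within a few percent
of the target.

**BOLD.** Background noise is an equal-power mix of 1/f (power-law
exponent 1) and white noise, scaled to `noise_sd`. A coupled ROI adds
`osc_amp · cos(φ_resp/2 + η)` with η i.i.d. von Mises(0, κ) per TR sample;
κ = 0 omits the component entirely (null construction). Optionally a
direct respiratory artifact `resp_artifact · cos(φ_resp)` is added on the
TR grid; because the fundamental exceeds the BOLD Nyquist frequency this
term is aliased by construction, exactly as respiratory artifacts are in
real acquisitions. Hemodynamic delay is not modeled: it is a constant
phase offset, and PLV is invariant to constant offsets.

**Coupling-scale calibration.** The entrainment effect size is not a
published quantity, so the scale parameters were calibrated once against
the study's reported outcomes and then frozen: `noise_sd = 0.6` with
`osc_amp = 1` and κ = 20 puts the coupled-pair %sigbins at 33.7 ± 10
(reported: 32.5 ± 9.6), and `resp_artifact = 1.15` makes the
aliasing-control paths statistically indistinguishable (reported
permutation p = 0.80/0.99). See "Aliasing control" below for why the
artifact term is load-bearing.

**Connectivity stacks.** Per-subject symmetric Fisher-Z matrices = shared
baseline (0.25 ± 0.1) + subject scalar (SD 0.1) + condition-specific
symmetric measurement noise (SD 0.15); the active condition's hub row and
column gain `effect_z` (default 0.3). The subject scalar cancels in paired
differences, as a within-subject design requires.

**Toy volumes.** 16×16×8 paired Fisher-Z maps with voxel noise SD 0.15, a
subject random effect, and a spherical ~19-voxel blob of +0.5 Z in
condition A; an integer label volume partitions the grid into four slabs.

## Phase-locking pipeline

Respiration is band-passed 0.01–0.25 Hz (zero-phase Butterworth order 4),
low-passed at 0.8× the target Nyquist (order 8) and linearly interpolated
onto the TR grid. Instantaneous phase within 0.1–0.2 Hz comes either from
the analytic signal of the band-passed trace (Hilbert) or from a Morlet
(ω₀ = 6) continuous wavelet transform evaluated in the frequency domain on
12 log-spaced scales spanning the band, with coefficients complex-averaged
across scales (energy-weighted) before taking the angle. The CWT is
computed via FFT rather than a discretized time-domain wavelet because at
TR = 2 s the band scales span only ~3–5 samples and time-domain
discretization corrupts phases. Roughly one Morlet e-folding time at the
lower band edge (1.35/0.1 Hz ≈ 13.5 s) is marked invalid at each record
end (cone of influence).

PLV uses a centered sliding window of 13 samples (four cycles of 0.16 Hz
at TR 2 s, rounded to odd). Windows touching invalid samples are invalid.

**Surrogate null.** The respiration phase's per-sample increments
(instantaneous frequency) inside the valid interior are resampled — by
IAAFT (default; preserves the IF power spectrum and value distribution,
100 iterations with a rank-convergence stop) or by plain permutation
(preserves only the distribution) — and re-integrated from the original
initial phase. Edge increments stay in place so filter transients cannot
leak into the interior. The null PLV is computed one-sided: surrogate
respiration phase against the original BOLD phase. The significance
threshold is the 95th percentile of the null, either pooled over all valid
bins (global, default) or per time bin. %sigbins is the percentage of
valid bins whose observed PLV strictly exceeds the threshold; ≥ 10% flags
a reliable effect.

**Calibration caveat (measured, not assumed).** With the global threshold
the null %sigbins is calibrated (≈ 5% over independent pairs). The per-bin
variant is anticonservative under this generator (≈ 8–9%): a pair of
independent narrowband signals can by chance co-drift in frequency for
stretches of a run, a run-level alignment that IF-resampling surrogates
cannot reproduce; the resulting pair-level offset inflates the *mean*
exceedance by convexity even when the median is calibrated. This is a
property of one-sided IF-surrogate testing on narrowband signals, not an
implementation artifact (a circular-shift null, which preserves the IF
sequence exactly, shows the same inflation). The global threshold is
therefore the default.

## Aliasing control

The control recomputes %sigbins per subject along two paths: (a) the
standard anti-aliased path, and (b) a 0.01–0.5 Hz band-pass followed by
plain decimation, which lets the respiratory fundamental fold to
0.5 − f0 ≈ 0.19 Hz inside the analysis band. A paired sign-flip
permutation test compares the paths.

A structural result worth recording: under a *pure* half-harmonic
entrainment model the two paths cannot agree. In the aliased path the
folded fundamental (full amplitude) dominates the in-band respiration
phase over the subharmonic (amplitude ~alternation/2), so the aliased
reference tracks −φ while the BOLD tracks φ/2 and locking is destroyed.
Path agreement — which the study reports — requires the BOLD itself to
carry a comparably strong aliased respiratory component, so that both
reference mixtures share both components and their phase difference
stabilizes. That is physiologically plausible (respiratory artifacts are
strongest near air cavities and the brainstem, i.e., exactly the hub
regions) and is how the generator's `resp_artifact` default was set. The
flip side is a sharp adversarial case: with the artifact present and no
genuine coupling (κ = 0), the aliased path locks strongly while the clean
path sits at chance, and the control flags the discrepancy.

## Connectivity inference

Confound regression is OLS per ROI against intercept + linear trend +
supplied confounds (e.g., six motion parameters), with a rank check that
names collinear columns. Connectivity is Pearson correlation over ≥ 10
samples, Fisher Z-transformed with |r| clamped at 1 − 10⁻¹² so degenerate
fixtures stay finite.

**Per-ROI omnibus test.** For each ROI the subjects × (R−1) matrix of
paired Fisher-Z differences is reduced to k = 2 scores per subject: score 1
is the subject's mean difference over the ROI's connections (the fixed,
uniform direction — the "overall connectivity" contrast a hub effect
moves), score 2 the leading right-singular direction of the
column-centered matrix orthogonalized against the uniform direction. A
one-sample Hotelling T² on the scores gives F = T²(n−k)/(k(n−1)) with
df (k, n−k) = (2, 18) at n = 20, BH-FDR across ROIs. The direction split
is deliberate: directions taken from the sample mean itself make the test
circular (inflated F everywhere), while purely variance-based directions
carry no power for mean shifts. With the planted-hub generator the test
recovers exactly the two hubs in ≥ 90% of cohorts at effect 0.3 and flags
nothing in ≥ 95% of null cohorts.

**Connection-level tests.** Paired t (df n−1) per connection of a
significant ROI, BH-FDR within that ROI's family, and a descriptive
post-hoc selection at uncorrected p < 0.01 with the sign giving the
direction of the condition difference.

**Paired permutation test.** Two-sided sign-flip test on the mean
difference; exact enumeration whenever 2ⁿ fits the iteration budget (then
p is the exact exceedance fraction), otherwise Monte Carlo with the
add-one correction.

## Cluster inference

Voxel-wise paired t on Fisher-Z difference volumes; two-sided
cluster-forming threshold at voxel p < 0.01; clusters by 18-neighborhood
(6/26 available), opposite signs kept separate; cluster mass = sum of
suprathreshold |t|. Cluster p-values come from a sign-flip permutation
null of the maximum cluster mass (and size) per iteration — the exact
scheme for a paired one-sample design — with add-one exceedance and
BH-FDR across observed clusters, for mass and size separately. The t
statistics under sign flips are computed vectorized from the flipped means
and the (flip-invariant) sums of squares. Permutation resolution matters:
with m observed clusters the smallest attainable FDR-adjusted p is
~m/(n_iter+1), so ≥ 1000 iterations are needed before a single cluster
among ~20 can clear q = 0.05 (the analysis default is 10,000).

## Problem sizes used in the tests and acceptance script

Simulation sizes were chosen to make the checks statistically meaningful
at interactive runtimes on one CPU: cluster calibration uses 500 null
volumes at 500 permutations each and 20 recovery runs at 1000; the
phase-locking calibration uses 200 independent pairs and 48 coupled pairs
at 200 surrogates (the analysis default is 1000); hub recovery uses 100
cohorts of 20 subjects at 133 ROIs plus 100 null cohorts; the aliasing
control uses 12-subject cohorts at 100 surrogates. The acceptance script
runs smaller replicates of the same experiments (~5 minutes total).

## What the synthetic validation does and does not show

Passing tests demonstrate that the pipeline detects the signals its own
generative model plants, at calibrated false-positive rates, and that the
implemented statistics agree with closed forms and brute-force oracles.
They do not validate the generative model against real physiology: real
belt signals have broadband in-band content beyond a period-2 subharmonic;
real BOLD noise is not exactly 1/f + white; respiratory artifacts vary
regionally rather than uniformly; and motion, scanner drift, and
preprocessing interactions are out of scope. The per-bin threshold
inflation and the artifact-dependence of the aliasing control are
genuine properties of the methods that carry over to real data.

## Known limitations

- The canonical 133-ROI label list is a synthetic stand-in (hub and
  limbic/opercular abbreviations are real; fillers are systematic names).
- The omnibus test's dimension-selection rule is a reconstruction from the
  reported degrees of freedom; k is exposed as a parameter.
- HRV regressors use the interpolated RR series before CRF convolution
  (toolbox convention); instantaneous-HR input is not offered.
- %sigbins reliability uses the fixed ≥ 10% rule; no uncertainty is
  attached to the threshold itself.
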