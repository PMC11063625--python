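# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of `emomem`.

## Data model and conventions

Time is in seconds with stimulus onset at 0 and offset at 0.5 s.  All
analysis windows are half-open `[lo, hi)` — a spike exactly at 1.5 s is
outside the stimulus window — with one exception: the artifact windows
around stimulus onset/offset are closed intervals `[t − 3 ms, t + 3 ms]`,
so boundary spikes are removed.  Default windows: baseline
`[−1.5, −0.2)` s, stimulus `[0.2, 1.5)` s, peri-stimulus `[−1.5, 2.5)` s,
dPCA `[−0.5, 2.5)` s.

Encoding outcomes are subsequent-memory labels derived from the recognition
response to the same stimulus (R → eR/nR, N → eF/nF, K → eK/nK);
recognition outcomes are RHit/KHit/Miss for old and CR/FA for new items,
per emotion.  K and FA trials are retained but flagged
`excluded_primary` rather than dropped, so K-inclusive supplementary
analyses remain runnable; the primary memory factor is R/F at encoding and
RHit/Miss/CR at recognition.

## Quality control

A unit is retained iff (a) <3% of its ISIs are under 3 ms, (b) its mean
rate exceeds 0.25 Hz, and (c) it fires on ≥50 (encoding) or ≥100
(recognition) trials.  Two details the rules leave open were fixed as
follows:

- **ISIs** are computed within trials only (spike trains concatenated in
  trial order, diffs across the multi-second inter-trial gap discarded):
  cross-trial intervals carry no information about sorting quality.
- **Mean rate** = total spikes / (n_trials × peri-stimulus window length);
  the denominator is not otherwise defined, and the recorded epoch per
  trial is exactly that window.

Spike width is peak-to-trough time of the mean waveform (global extremum of
the configured sign to the subsequent opposite extremum); monotone or flat
waveforms raise an undefined-width error.

## Event responsiveness

Baseline and stimulus windows have equal length (1.3 s), so raw counts are
compared directly.  The test statistic is mean(stimulus) − mean(baseline).
Because the two counts are paired within a trial, the default null swaps
the baseline/stimulus labels independently within each trial (a paired
sign-flip); an unpaired pooled shuffle is available behind `paired=False`
for sensitivity analysis, since the original description ("shuffling
labels") does not distinguish the two.  The p-value uses the add-one
convention p = (1 + #{|T*| ≥ |T|})/(n_perm + 1): never exactly zero,
floored at 1/(n_perm + 1), and slightly conservative (the test suite
checks super-uniformity under the null).  The test is two-sided because
both rate increases and decreases occur.

## Selectivity census

Per neuron, stimulus-window counts enter a two-way factorial ANOVA with
trials as replicates (the "repeated measures" are the trials within one
neuron; there is no within-trial factor).  p-values come from Type II
nested-model comparisons computed with pre-factorized QR designs: for each
effect, F = ((RSS_reduced − RSS_additive)/df) / (RSS_full/df_resid).
Zero-variance data yield p = 1 by convention.  The labeling rule discards
main effects whenever the interaction is significant (label X); otherwise
significant mains give E, M, or — a case the three-way labels leave
undefined — EM when both mains are significant, in which case the unit
counts toward *both* the E and the M census.

The census null re-runs the entire selection B times (default 10,000) with
each neuron's response vector permuted against its fixed factor design —
equivalent to shuffling the trial labels jointly over both factors while
preserving every condition's trial count.  p = #{null ≥ observed}/B with
floor 1/B (so an unbeaten observed count at B = 10,000 reports
p = 0.0001).  Units with any condition cell under 2 trials are unanalyzable
and excluded symmetrically from observed and null counts.  RNG: one master
seed spawns one substream per unit, so the loop can be parallelized or
reordered without changing the null distribution.

Pairwise comparisons (RHit/KHit/Miss/CR, emotions pooled) use a one-way
two-level ANOVA (equivalent to a two-sample t test) per unit and the same
census machinery; the pair-level default threshold is the conventional
printed value 0.0086, although 0.05/6 = 0.00833 — the discrepancy is
surfaced here and the threshold is configurable.  Stratified reruns
(region or patient) apply identical machinery per stratum; strata below a
configurable minimum unit count are flagged underpowered rather than
dropped.

## abs(z) population summary and mixed model

For each unit, per-trial z = (x − μ)/σ, where x is that trial's
stimulus-window rate and μ, σ are the mean and SD of the *per-trial
baseline-window rates* over all trials.  Reading x as a per-trial quantity
(rather than an across-trial mean) is required for trial-level modeling;
computing μ, σ from per-trial baseline means (not pooled bin samples)
matches "baseline from all trials" at the trial level.  If the mean z over
all trials is negative, all z are multiplied by −1 (abs(z) sign
correction), so decreasing and increasing units contribute alike.  Units
with zero baseline variance cannot be z-scored and are logged and excluded
from the model, never silently zeroed.  abs(z) is invariant to rescaling a
unit's firing rate by a positive constant.

The model is `abs_z ~ 1 + Emotion * Memory + (1 | Patient / Neuron)`:
nested random intercepts only, no random slopes.  Estimation is REML via
statsmodels `MixedLM` with a variance component for neurons within
patients.  Fixed terms are tested with omnibus Wald χ² on the sum-coded
coefficient blocks (equal to Type II/III tests in the near-balanced designs
used here); non-convergence or a boundary fit is reported in the result,
not masked.  Pairwise contrasts are estimated-marginal-mean differences
between memory levels within each emotion, with Z ratios (normal
approximation) and Benjamini–Hochberg FDR applied within the model's
contrast family (the family is per fitted model; encoding and recognition
are corrected separately).

## Demixed PCA

Marginalization is by sequential condition averaging of the per-unit
centered tensor: time term = mean over conditions; emotion/memory terms =
factor means minus the time term; interaction = residual.  The
decomposition is additive and exact (machine precision), verified on every
fit.

Per marginalization φ, decoder/encoder pairs minimize
‖X_φ − F_φ D_φ X‖² + μ‖F_φ D_φ‖².  The closed form takes
A = X_φ Xᵀ(X Xᵀ + μI)⁻¹ and the leading left singular vectors U of AX:
F = U (orthonormal within the marginalization), D = UᵀA.  With μ = 0 and a
single full marginalization this reduces exactly to PCA, which the tests
verify against an SVD oracle.  The ridge strength is expressed as a
fraction λ of total variance (μ = λ‖X‖²); `lam="cv"` selects λ from the
grid {0, 10⁻⁷ … 10⁻²} by held-out-trial reconstruction error (per fold,
one random trial per (unit, cell) forms the test average; 10 folds by
default).  λ is shared across marginalizations.

Components are pooled across marginalizations and ranked by explained
variance (2dᵀXXᵀf − dᵀXXᵀd per component, as a % of ‖X‖²); the leading
component of each marginalization is always retained so every condition
component remains available for decoding even when it carries little
variance.  20 components are computed and 15 reported by default.
Variance accounting reports per-component percentages, per-marginalization
totals, the cumulative curve, and pie-normalized shares over the first 15.

The signal-variance ceiling uses the 1/n law: the trial average of n
trials inherits 1/n of the single-trial noise variance, estimated from the
across-trial variability within condition cells; the signal fraction is
1 − (expected noise content)/(total variance), clipped to [0, 1].
Unbalanced trial counts are handled by per-cell averaging with per-cell
counts in the noise estimate; no pseudo-trial resampling enters the fit.

Decoding significance per condition component: in each of n_iter
iterations, one held-out pseudo-trial per condition (a random trial per
unit per cell) is projected on the decoder axis and classified at each
10 ms bin to the nearest training-class mean (classes: the 2 emotions, the
2–3 memory levels, or all cells for the interaction; ties go to the first
class in condition order).  The null shuffles trial-type labels within
units (preserving per-condition counts) **and refits the decoder axis on
the shuffled averages** before decoding — without the refit the null is
anticonservative, because the real decoder is optimized on the very labels
under test.  Significance marks bins where real accuracy exceeds the 97.5%
quantile of n_shuffles shuffled accuracies; 95% and 100% quantile curves
are also emitted.  A master seed drives held-out draws and shuffles through
derived substreams.  Leave-one-region-out reruns the full pipeline on the
complement and reports marginalization-variance and significance deltas;
excluding a region with no units reproduces the full model exactly.

Whether dPCA input should be raw-Hz or z-scored PSTHs is not externally
fixed; the default is raw Hz (a config switch would be a one-line wrapper,
and the tensor builder accepts any rate matrix).

## Synthetic cohorts

The generator emulates the study structure: 5 patients, ~51 units each
across HIP/AMY/EC, 120 encoding trials (40 emotional / 80 neutral,
presentation 0.5 s, ISI 3.5 s), 240 recognition trials (120 old + 120
new), pseudo-random order with no two emotional items adjacent.  The
adjacency constraint is satisfied constructively (emotional items dropped
into distinct gaps of the shuffled neutral sequence), which requires
n_emotional ≤ n_neutral; larger fractions raise a design error.

Behavior: R/K/N response probabilities per item status and emotion,
defaults (0.45/0.10/0.45 old-emotional, 0.40/0.10/0.50 old-neutral,
0.05/0.05/0.90 new) chosen to mirror the moderate performance and low K /
false-alarm counts typical of intracranial patient cohorts.

Spike trains are inhomogeneous Poisson by thinning:
λ(t) = baseline + bump(t)·(g_event + g_E·1[emotional] + g_M·1[remembered]
+ g_X·1[both]), clipped at 0, with bump a unit-peak Gaussian (latency
0.3 s, width 0.2 s — response shapes are not externally parameterized, so
a single plausible shape is used).  Refractoriness is dead-time deletion at
3 ms, matching the ISI quality criterion so simulated units cannot violate
it; renewal-process realism is out of scope.  Baselines are log-normal
(median 2 Hz, σ_log = 1.0) so a small fraction of units straddles the
0.25 Hz inclusion boundary and exercises the QC paths.  Condition gains are
expressed as multiples of baseline (default 1.5×), signed (70% increases),
with effect-class prevalences defaulting to 10% emotion, 7% memory, 5%
interaction, 30% event-only.  Each patient gets an independent design and
behavioral draw; units are simulated independently per phase (sessions a
day apart record different neurons).  All randomness flows from one seed
through spawned substreams; spike counts are platform-stable integers.

What the generator does **not** emulate: bursting and serial dependence,
non-Poisson variability, waveform shapes beyond a parametric template,
correlated noise across units, drift and nonstationarity, and any LFP
coupling.  Passing tests therefore demonstrate that the *estimators* are
calibrated and recover planted effects under Poisson assumptions — not
that real MTL data satisfy those assumptions.

## Problem sizes

The test suite and acceptance checks run on reduced sizes chosen as the
package's own desk-scale defaults: null-calibration cohorts of 5 patients
× 39 units with 120 encoding trials; 20 replicate cohorts at census
B = 500; mixed-model power at the full default size (5 × 40 × 120) over
10 replicates; decoding localization at 12 units × 60 bins with
n_iter = n_shuffles = 100.  The acceptance script uses the full B = 10,000
census on a 30-unit planted cohort.

## Known limitations

- The factorial ANOVA on counts is a Gaussian approximation to Poisson
  data; calibration is verified empirically at the default rates but will
  degrade for very sparse units.
- Wald χ² term tests and normal-approximation contrasts ignore
  small-sample df corrections (Satterthwaite/Kenward–Roger); with 5
  patients the random-effect tests are approximate.
- dPCA assumes a balanced trial-averaged tensor; units missing a condition
  cell are dropped rather than imputed.
- The decoding classifier is deliberately the component axis itself
  (1-D nearest-class-mean), not a tuned decoder; accuracies are
  interpretable as component separability, not as an upper bound on
  decodability.
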