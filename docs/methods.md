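# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `threatphys`.

## Experimental design emulated

A discriminative delay-conditioning protocol with three conditioned stimuli
presented for 4 s on a gray background: CS⁻ (never reinforced) and two CS⁺
(each reinforced on half of its trials by a 500 ms electrical pulse train
that coterminates with the CS, i.e. US onset at CS onset + 3.5 s).
Inter-trial intervals are drawn uniformly from {7, 9, 11} s. Phases:

| phase      | trials | reinforcement | probes |
|------------|--------|---------------|--------|
| acquisition| 45 (15/CS) | 50 % of CS⁺ | no |
| reminder   | 1 (CSr⁺)   | none        | no |
| retention  | 45 (15/CS) | none        | startle probe 3.5 s after every CS onset |
| relearning | 90 (30/CS) | 50 % of CS⁺ | no |

Randomization constraints: the first trial of a reinforced phase is a
reinforced CS⁺; the first six trials contain each CS exactly twice (applied
to all multi-trial phases; configurable); at most 5 identical CS in a row;
at most 4 reinforced, or 4 unreinforced, CS⁺ trials in a row, counted over
the CS⁺ subsequence only (CS⁻ trials do not interrupt a run — the
constraint concerns the reinforcement schedule; switchable). Generation is
by rejection sampling with a 10⁵-attempt cap; the first six trials are
constructed directly, which makes rejections rare. With 15 CS⁺ trials per
type, an exact 50 % split is impossible per type; the CS⁺ type shown first
receives ⌈n/2⌉ reinforced trials and the other ⌊n/2⌋, so the session-level
CS⁺ reinforcement rate is exactly 50 %.

During retention, the motoric startle response contaminates all channels
except EMG, so retention bundles carry EMG only; acquisition/relearning
bundles carry skin conductance, pupil/gaze (both eyes), and ECG.

## Canonical kernels

Fixed-shape phenomenological kernels, peak-normalized so a regression
coefficient is the peak response amplitude in channel units:

- SEBR: gamma density, mode 40 ms, support 150 ms.
- SCRF: bi-exponential (Bateman), rise 0.75 s, decay 3 s, support 20 s.
- PSRF: gamma density peaking at 2 s, support 10 s.
- HPRF: difference of gammas spanning ~12 s, peak ~4 s.

The published toolboxes' exact canonical functions are not printed in the
methods literature we follow; these parameterizations reproduce their
qualitative shape and are exposed in the configs. Correctness is claimed
through forward–inverse consistency and parameter recovery, not through
kernel-exact equivalence with any particular toolbox.

## Quantification chains and numerical choices

**SEBR.** The 3 ms smoothing time constant is implemented as a 4th-order
low-pass at 53.05 Hz (the stated equivalence). The "notch to remove 50 Hz
harmonics" is a cascade of 2nd-order IIR notches at 50·k Hz (k with
50·k < 470), Q = 35. The onset search grid is 1 ms over [0, 150] ms after
the probe; the fit criterion is minimal residual sum of squares with ties
broken toward the earliest onset; amplitudes are constrained ≥ 0 (a blink
envelope cannot be negative). The regressor kernel is passed through the
same smoothing filter as the data envelope, so the noiseless chain is an
identity. Normalization is per participant × session (whether the CS⁻ mean
should pool sessions is not specified in the protocols we follow; per
session is the conservative choice and is configurable).

**SCR.** The anticipatory input is a Gaussian bump of fixed SD 0.3 s whose
center (latency) is free in [0, 2] s; the evoked input is an impulse at US
onset + a configurable fixed delay (default 0). Model columns are built at
a 10× oversampled internal rate so the full band-pass the data went through
(including the 5 Hz leg, which lies above the 10 Hz working Nyquist) can be
applied to the regressors; because the chain is LTI, columns are time
shifts of two precomputed filtered templates, padded 40 s before and 80 s
after the input to capture the acausal undershoot of zero-phase filtering.
Estimation slides a window over trials (2 before, 1 after the target) with
inner nonnegative least squares for amplitudes and coordinate descent over
a 0.05 s latency grid — deterministic, and per coordinate a global search
over the bound. A trial's extent for the artifact-exclusion rule is CS
onset to the next CS onset. The inversion estimates an evoked amplitude on
every trial, reinforced or not (blind to reinforcement); only nonreinforced
trials are passed to analysis.

**PSR.** Gaze is handled in degrees of visual angle (70 cm screen
distance; `gaze_to_degrees` converts on-screen offsets). The exclusion rule
is exactly "< 50 % valid in the 10 s after CS onset": a trial at exactly
50 % is included. A session with > 35 % excluded trials triggers a warning,
not an error — in the data this pipeline targets that is a quality flag.
Drift regressors are constant + linear per session (kept minimal,
configurable). Down-sampling to 250 Hz is by block mean, which also
determines the (tiny) discretization error of the noiseless identity.

**HPR.** The Pan–Tompkins variant: band-pass 5–15 Hz, derivative, squaring,
150 ms moving-window integration, adaptive dual thresholds
(SPKI/NPKI, 0.125 update), 200 ms refractory period, and refinement of each
detection to the local band-passed apex. IBI bounds 400–1200 ms are treated
as valid-at-boundary ("outside 400 and 1200 ms" read as open-interval
exclusion; configurable to exclusive). The first IBI has no preceding
interval and is not placed; un-bracketed edges take the nearest value
before filtering. The conditionwise GLM optionally convolves the kernel
with a right-aligned boxcar of one mean IBI, modeling how each inter-beat
interval averages the instantaneous heart period over the beat and is
stamped at the following R spike; the pipeline passes the measured mean IBI.

**Mixed models.** Parameter estimation uses statsmodels MixedLM (REML,
random participant intercept; richer random structures are out of contract
— they are typically inestimable for these designs). The fixed-effect F
tests with Satterthwaite denominator df are computed here: the GLS
covariance of the fixed effects uses the Woodbury identity per participant
block; the df comes from the delta method with the observed REML
information (central finite differences); multi-df terms orthonormalize the
contrast rows in the metric of the covariance and combine the per-row dfs
(E = Σνᵢ/(νᵢ−2), df = 2E/(E−q)). This layer reproduces lme4 + lmerTest to
four significant figures on matched data (tested). When the intercept
variance collapses to zero or the information matrix is singular, the
residual df is used as fallback. Time (trial number) enters as a
categorical factor — trial number across CS for retention and a within-CS
counter of analyzed trials for relearning. Two CS contrasts are reported
from separate fits: pooled CS⁺ vs CS⁻ on all analyzed trials, and CSr⁺ vs
CSn⁺ on CS⁺ trials only (hence its smaller denominator df). Designs are
checked for rank; the pipeline drops the time terms with a warning when a
cohort is too small to estimate them.

**Repeated-measures ANOVA.** Mixed-design strata computed explicitly:
the group effect is tested against subject variation (df n−g); the two
1-df CS contrasts and their group interactions are tested against the
pooled within-subject error with df (n−g)(k−1) — "pooled error variance".
Type III logic with sum-to-zero contrasts: the contrast main effect uses
the unweighted mean of group means. With two conditions and one group this
reduces exactly to the squared paired t (tested), and the two contrasts
partition the omnibus within-subject sum of squares (cross-checked against
pingouin).

**Cross-validation.** Folds are equally sized up to a remainder of 1
(the general code must not assume n divisible by 3); partitionings are
redrawn until every training set contains both labels. The linear model on
a binary label reduces to training-fold group means. The statistic is
averaged over the 3 folds, then the 10 partitionings; the permutation test
shares the partitionings between observed and permuted labels, holding
partitioning noise constant (recomputing them per permutation is a
one-line change). The p value follows the literal counting rule —
the fraction of permutations with a strictly smaller statistic — with an
optional add-one correction (off by default).

**Clearance utility.** First-order kinetics, 1 − 2^(−t/t½); with a 16 h
half-life, clearance at 168 h is 99.93 % (> 99.9 %).

## The synthetic-data generator

The generator encodes the statistical structure the analysis assumes:
conditioned discrimination (CS⁺/CS⁻ amplitude multipliers per measure:
SEBR 1.5, SCR 2.0, PSR 1.6, HPR 3.0), drug modulation of the retention CS⁺
effect (×1.5), exponential habituation (0.02/trial) and extinction of the
CS⁺ differential in the unreinforced retention phase (0.05/trial), a
lognormal per-participant gain (σ = 0.4) applied multiplicatively to EMG
only — the stated motivation for CS⁻ normalization — plus blink gaps in
pupil (10/min, the better eye simulated at 0.6× that rate), step artifacts
in skin conductance (0.2/min, durations 0.5–3.5 s straddling the 2 s
interpolation threshold), and occasional gaze excursions beyond the 5° box.
The default cohort size is 39 per group (a 78-participant study); the
verification suites run scaled cohorts (20 participants for recovery, 24
for the permutation-power runs) chosen to keep the full suite in the
minutes range while leaving wide margins to the thresholds.

Channel forward models: EMG blink bursts are the canonical envelope
modulating a deterministic broadband multi-tone carrier (75/175/275/375 Hz,
off the mains-harmonic grid), pre-scaled by the measured gain of the
scoring chain so the contract "post-chain envelope = amplitude × kernel"
holds exactly; probe onsets are jittered uniformly inside the fitter's
search window. SCR uses the same dispersed-input forward model as the
inversion plus a low-passed random-walk tonic drift; US-evoked responses
are 3× the anticipatory amplitude by default (a plausible value; not
specified in the protocols we follow). ECG is generated by integrate-and-
fire over an instantaneous heart-period trace (baseline 1000 ms plus
conditionwise kernel contributions and slow variability), with a synthetic
three-lobe QRS template at each spike. Pupil area rides on a 1000 au
baseline with band-limited noise.

Noise defaults (EMG 0.02, SC 0.02 μS, pupil 4 au, ECG 0.05 of the R
amplitude) are calibrated so that recovery is comfortably above the
acceptance thresholds at 1× and degrades markedly at 10× (PSR r drops from
≈ 0.998 to ≈ 0.8; documented in the tests), since no empirical SNR figures
are available to copy. By default the generator uses the same kernel
family as the fitters; `misspecify_kernels=True` shifts peaks and
dispersions for robustness experiments, so recovery tests need not be a
tautology.

What the generator does *not* emulate: biophysical sudomotor or pupil
muscle dynamics, luminance effects (stimuli are treated as isoluminant),
beat-morphology variation or ectopy in ECG, non-stationary mains
interference, or electrode drift within a trial. Passing recovery tests
therefore demonstrates correctness of the estimation chain under the
model's own assumptions — not robustness to every artifact class of real
recordings.

## Bundles and blinding

A session bundle stores a manifest (participant, opaque group code, phase,
channel inventory), channels with validity masks, the trial event table,
and annotation intervals. On disk: a directory of TSV files with a YAML
manifest (text interchange; `%.6g` float precision), or a single HDF5 file
(lossless, used for large simulated cohorts). Trial tables export to
BIDS-style events files. The blind-code → group mapping is written to a
separate unblinding table; all quantification runs blinded and unblinding
is an explicit analysis-stage step, mirroring how a randomization code is
broken only after data checks.

## Known limitations

- The SCR inversion is windowed least squares with grid latencies, not a
  variational scheme; its contract is forward-model consistency, and
  per-trial amplitudes in dense sessions can deviate by ~20 % when an
  anticipatory and an evoked response overlap strongly (latency
  quantization interacts with their collinearity); session-level
  correlations with truth remain ≥ 0.99 at zero noise.
- Satterthwaite df relies on a finite-difference REML Hessian; at variance
  boundaries (τ² → 0) it falls back to residual df.
- The rm-ANOVA implements the standard stratification; published tables
  computed with other software can differ by a few denominator df
  depending on how the between factor is placed in the error strata.
- No foreshortening correction for pupil area; units are tracker-arbitrary
  throughout.
- Proprietary acquisition formats are out of scope; converters would write
  the bundle format.
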