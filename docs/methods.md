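# Methods

This note documents the models, parameter choices, and numerical
conventions behind `dfnckit`, and what the synthetic validation does and
does not establish.

## Pipeline overview

The unit of analysis is a scan session: a T×C matrix of ICA component
time courses (C components, T volumes at repetition time TR) plus a T×6
rigid-body motion trace. The pipeline runs:

1. **Motion QC.** Framewise displacement (FD) per volume is the sum of
   absolute backward differences of the three translations (mm) plus the
   arc length of the three rotation differences on a 50 mm sphere
   (rotations in radians); FD of the first volume is 0. A session is
   excluded iff mean FD > 0.25 mm or more than 20% of volumes have
   FD > 0.2 mm. The comparisons are strict (`>`), so a session exactly
   at a threshold is retained.
2. **Time-course cleanup**, in order: drop the first 4 volumes
   (scanner stabilization), remove a per-component least-squares line,
   despike against a running median (window 7 volumes, clip at 5
   median-absolute-deviations; the MAD is scaled by 1.4826), regress out
   the 24 motion confounds (6 base parameters, their backward-difference
   derivatives, and both sets squared; an intercept is included and the
   confounds are demeaned, so residuals are orthogonal to the raw
   columns), and low-pass filter with a fifth-order Butterworth at
   0.15 Hz applied forward–backward (zero phase; effective attenuation is
   squared relative to a single pass). Detrending is linear only — the
   0.15 Hz low-pass dominates slow-drift removal. The despiking
   algorithm and detrend order are package conventions chosen for
   determinism; disable despiking with `despike_k=None`.
3. **Windowed connectivity.** A taper — a 25-TR rectangle convolved with
   a Gaussian of width σ = 3 TR (support ±3σ), truncated to its central
   25 samples and normalized to sum 1 — slides in steps of 1 TR. Window
   offsets run 0 … T′−W−1, i.e. **T′−W windows** (171 for T′ = 196,
   W = 25), matching the window accounting of the reference tooling this
   convention reproduces (not the T′−W+1 a fencepost count would give).
   Each window's taper-weighted covariance is standardized to
   correlation scale, fitted with the graphical lasso (off-diagonal L1
   penalty on the precision), and the correlation implied by the inverse
   precision is Fisher-Z transformed. The penalty is therefore
   dimensionless; the default candidate grid is 12 log-spaced values in
   [0.01, 0.5].
4. **Penalty selection** is per session, not per window: the session's
   cleaned time course is split into 5 contiguous time blocks; each
   candidate λ is scored by the held-out Gaussian log-likelihood
   log det Θ − tr(S_test Θ) averaged over folds (training covariance
   from the remaining blocks, correlation-scaled); ties break toward the
   sparser (larger) λ. With strongly state-switching sessions the
   optimum occasionally sits at the grid maximum — a genuine feature of
   block-wise cross-validation on non-stationary series, retained as is.
5. **States.** Windows from all sessions and visits are pooled and
   clustered with k-means under correlation distance, k = 5, 500 random
   restarts. Rows are centered and unit-scaled, so d(x,c) = 1 − x̃·c̃ and
   Lloyd assignment is an argmax of a matrix product; centroids are the
   renormalized means of their members' normalized rows; empty clusters
   seize the point farthest from its centroid; the best restart by total
   within-cluster distance wins; states are relabeled by descending
   global occupancy. Constant window rows (possible when a large penalty
   zeroes a whole window) are excluded from clustering with a warning
   and assigned afterwards by Euclidean distance. An optional two-stage
   mode (off by default) restricts the restarts to per-session exemplar
   windows — local maxima of across-pair variance — and seeds one
   full-data pass from the winning exemplar centroids, for memory-scale
   cohorts.
6. **Session summaries.** Run-length encoding of the per-session state
   sequence gives mean dwell time per state (0 for unvisited states,
   flagged `visited=False`), the number of transitions (adjacent unequal
   pairs), and occupancy. Occurrence-over-scan profiles (fraction of
   sessions in each state at each window position) carry subject-level
   bootstrap envelopes and 2.5/97.5 percentile bands.
7. **Longitudinal models.** Each outcome (five MDTs, NT, and optionally
   each pair's temporal SD) is modelled with a Gaussian linear mixed
   model with a random intercept per subject and fixed effects of
   centered age (centered at the visit-1 mean) and sex. MDT outcomes are
   Box-Cox transformed first (profile likelihood on a λ grid of
   [−2, 2] in steps of 0.01; an offset of 1 − min(y) is applied when
   zeros occur, as they do when a state goes unvisited). Reported
   coefficients come from REML fits; likelihood-ratio screening of the
   age² and age×sex terms refits both models by full ML. Sex-stratified
   fits are produced when the interaction LR test passes at α = 0.05.
   FDR correction (Benjamini–Hochberg) is applied per term family across
   the six summary outcomes; the edgewise SD models form their own
   family across all pairs. Prediction bands come from resampling
   subjects with replacement (keeping both visits — the clustered
   bootstrap preserves within-subject correlation), refitting, and
   taking 2.5/97.5 percentiles of back-transformed population
   predictions; the default is 2,000 resamples.

## The synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. Defaults: C = 20 components partitioned into the seven
canonical networks (SC, AUD, SM, VIS, DMN, CC, CB), K = 5 states,
T = 200 volumes at TR = 1.76 s, a two-visit design with visit ages
N(10.1, 0.6) and N(13.9, 0.5) years, 45% retention at visit 2, and a
balanced sex ratio.

**States.** Hidden states follow a first-order Markov chain with base
self-transition probability 0.98 (mean dwell ≈ 50 TR ≈ 88 s, giving
roughly 4–6 state transitions per session — the order of magnitude such
scans show). Given the state, volumes are i.i.d. zero-mean multivariate
Gaussian draws with that state's correlation matrix; temporal smoothness
then arises from the 0.15 Hz low-pass, which is exactly the band-limit
the estimation stage faces. Four of the five default states are
block-modular: within-network correlation 0.5, between-network −0.25
(−0.2 for the "partially modularized" state 5), with each state engaging
its own subset of networks under its own ±1 polarity pattern. This
matters: states that differ only in block *strength* are nearly
collinear under correlation distance (which is scale- and
offset-invariant), so recovery would be ill-posed by construction;
engagement subsets and polarities keep pairwise pattern correlations
below 0.25 while staying within the family of configurations such
clustering recovers in practice. State 4 is "non-modularized": a few hub
components globally anti-correlated with the rest (plus one positively
coupled hub) over a weak ±0.04 random background. All state matrices are
repaired to positive definiteness by eigenvalue clipping at 1e-3
followed by renormalization to unit diagonal.

**Nuisance.** Observation noise (SD 0.2 against unit signal variance),
linear drift (0.002 per volume), sparse spikes (rate 0.002 per
volume-component, amplitude ±4), and motion as a smoothed Gaussian
random walk whose amplitude sits below the QC thresholds (so that
default cohorts pass QC; QC behavior itself is tested on constructed FD
series).

**Planted effects.** Covariate effects act on the log-odds of each
state's self-transition probability — not on dwell times directly — so
rows stay stochastic and dwell-time effects are monotone. Defaults per
year of centered age: +0.16 (state 1), +0.02, −0.04, −0.04, −0.04;
sex offsets for girls: 0, +0.20, −0.15, −0.15, +0.10; and an
age-by-sex interaction of +0.06, +0.04, 0, −0.04, +0.04 for girls.
Under the stationary distribution these produce rising state-1 dwell,
falling dwell in states 3–5, falling transition counts with a steeper
decline in girls, and girls dwelling longer in state 2 — the direction
pattern this class of developmental cohort shows. The per-session
transition matrix, the full state path, and TR-resolution dwell metrics
are recorded as ground truth.

## What validation shows (and does not)

Validation is by parameter recovery, since the motivating cohorts are
not public:

- **State stage** (100 sessions, full pipeline): every recovered
  centroid must correlate > 0.9 with its Hungarian-matched planted
  pattern, and window assignment accuracy after label matching must
  exceed 85%, where a window's true label is the taper-weighted majority
  state over its support. Windows straddling state boundaries are
  genuinely ambiguous; the majority convention scores them against the
  dominant state.
- **Longitudinal stage** (500 subjects, ground-truth metrics fed to the
  model suite): the planted positive age effect on state-1 dwell and
  negative effect on transitions must be recovered with q < 0.05; under
  a null generator the base-model age test must reject at 5% ± 2%,
  pooled over 200 replicates of 60 balanced two-visit subjects. The
  null check runs at reduced size because mixed-model fits dominate its
  cost; the balanced design is chosen for well-calibrated Wald tests.
  The longitudinal check consumes the generator's ground-truth dwell
  metrics rather than re-running window estimation for a thousand
  sessions; estimation-stage fidelity is covered by the state-stage
  check.

Passing these tests shows the pipeline correctly estimates what the
generator plants under realistic SNR. It does **not** show that real
development behaves this way: the generator has no hemodynamics, no ICA
mixing or estimation error, i.i.d.-given-state dynamics rather than true
neural nonstationarity, Gaussian marginals, and planted effects chosen
to mirror reported directions. Distributional choices are stand-ins, not
claims.

## Numerical choices and edge cases

- Graphical lasso: `sklearn.covariance.graphical_lasso`, coordinate
  descent, duality-gap tolerance 1e-3 (sufficient at C = 20 on
  correlation scale; tighten for oracle comparisons), 200 iterations.
  λ = 0 is computed by direct inversion — the exact unpenalized
  maximizer. Implied correlations are clipped to |r| ≤ 0.999999 before
  the Fisher-Z transform, so z is always finite.
- Mixed models: `statsmodels` MixedLM; optimizer falls back
  lbfgs → powell → cg on numerical failure (zero-inflated transformed
  dwell outcomes occasionally produce singular intermediate Hessians on
  the first try). Random-effect variances at the boundary are reported
  as found, with the usual Wald caveats.
- k-means ties in assignment go to the lower state label (argmax takes
  the first maximum); the identical rule applies when assigning held-out
  sessions to fixed centroids.
- Degenerate inputs raise informative errors: constant outcomes for
  Box-Cox, singular fixed-effect designs, out-of-range state labels,
  empty FD series, windows at least as long as the series, non-nested
  LR comparisons.
- The filter-attenuation contract (≥ 30 dB at 0.3 Hz vs. 0.05 Hz) is
  checked at a 1 Hz sampling rate: at TR = 1.76 s the 0.3 Hz probe lies
  above Nyquist (0.284 Hz). The filter itself is TR-agnostic and
  validates its cutoff against Nyquist.
- Full determinism under fixed seeds, including the cohort generator,
  k-means restarts, and all bootstraps; reruns produce byte-identical
  output tables.

## Problem sizes

Default validation sizes — 100 sessions for state recovery, 500 subjects
for longitudinal recovery, 200 × 60-subject null replicates, 1,000
random sequences for the run-length oracle — were chosen so the whole
validation completes comfortably on a single desktop CPU while leaving
Monte-Carlo error well inside the stated tolerances.
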