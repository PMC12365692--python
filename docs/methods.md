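# Methods

This note documents the models, estimators, and numerical choices behind
`fcreliab`, and what its synthetic cohorts do and do not emulate.

## Reliability estimands

A subject's functional connectome is the node × node matrix of Fisher-z
Pearson correlations computed over post-censored volumes. Reliability is
quantified two ways:

**FC-TRC** (whole-connectome test–retest correlation): the Pearson
correlation between the upper-triangle edge vectors of two connectomes built
from independent splits of a subject's data. It measures multivariate
pattern stability within a subject.

**ICC(2,1)**: for each feature (edge, block mean, or parcel), the n × 2 table
of subjects' split-half values is decomposed by two-way ANOVA into
between-subject (MSR), between-measurement (MSC), and residual (MSE) mean
squares, and

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)),   k = 2.

This is the absolute-agreement, single-measure form: systematic split
differences count against reliability. Negative values are kept in matrices
(informative when averaging) and floored only at categorisation. The
category bins are made contiguous — poor (≤ 0.4, including negatives), fair
(0.4, 0.6), good [0.6, 0.75), excellent ≥ 0.75 — because the conventional
printed bins leave (0.59, 0.6) unmapped; this closure is the minimal repair
and is checked by a property test covering [−1, 1].

## The two TRC estimators and when they agree

The split-session estimator correlates two halves each truncated to their
first T post-censored minutes: TRC_split(T) ≈ rel(T), the per-half edge
reliability at duration T. The iterative estimator correlates a fixed
R-minute reference against T minutes of residual chunks:
TRC_iter(T) ≈ √(rel(R) · rel(T)). The two therefore coincide in expectation
only where rel varies little over the compared range — near T = R, or
anywhere once reliability is close to its asymptote. The method-agreement
test compares group means at durations bracketing the reference length
(8/10/12 minutes around a 10-minute reference) on temporally independent
data with no session effects, the regime where both estimators target the
same quantity; at short durations with high edge noise the geometric-mean
structure of the iterative estimator makes it sit above the split-session
curve, which is a property of the estimators, not an implementation
discrepancy. With within-session autocorrelation the iterative estimator is
additionally inflated because reference and residual chunks interleave in
time; the generator draws volumes independently, so this inflation is absent
by construction.

Edge vectors are Fisher-z transformed before correlating; correlations of
magnitude exactly 1 (possible only on tiny toy inputs) are clipped to
1 − 1e−7 with a warning rather than raised, so small examples run.
Time-to-threshold interpolates linearly between the bracketing grid points;
a curve that never reaches the threshold returns an infinite sentinel rather
than raising.

## Motion, censoring, and bookkeeping

FD follows the Power convention (sum of absolute backward differences,
rotations converted to arc length on a 50 mm sphere, FD₁ = 0). The censoring
rule is strict: FD > 0.15 mm is dropped, FD = 0.15 mm retained. The optional
motion-parameter filter is a 4th-order zero-phase Butterworth low-pass at
0.1 Hz applied by default to the anterior–posterior translation only (the
phase-encoding axis in an AP acquisition, where respiratory pseudo-motion
concentrates); axes and cutoff are configurable, and censoring can be
computed on filtered or raw FD. Acquisition-time planning walks the
concatenated censor masks in order and reports the scanned minutes at which
the cumulative retained count first reaches the target.

## Motion-group classification

Retained-volume counts are summarised per age group by a normal density
(mean, SD of the group's counts — a two-parameter family is the minimal
choice that makes "intersection" well-defined from summary statistics); the
classification threshold is the unique density crossing between the two
group means, obtained in closed form from the log-density quadratic (the
midpoint when SDs are equal). Counts *below* the threshold are high-motion —
heavier censoring means more movement — and ties go to low motion. An
optional pre-filter excludes subjects retaining less than a minimum (e.g. 40
minutes) before classification.

## Synthetic cohort: what it emulates

The generator reproduces the geometry and motion heterogeneity of a
dense-sampling family study: 24 parent–child pairs, 4 sessions, 3 viewing
conditions × 2 runs × 205 volumes at TR = 2 s (41 acquisition minutes per
session, 1,640 volumes per condition across sessions).

- **Latent connectomes.** A block-structured group template (within-network
  r = 0.45, between r = 0.05 over 12 canonical networks) is perturbed per
  subject by symmetric Gaussian noise on the Fisher-z scale
  (`subject_deviation_scale`, default 0.12) plus a network-block-shared
  offset (`block_deviation_scale`, default 0.05) that makes individual
  differences coherent within networks, as they are in real cortex; the
  result is projected to the nearest correlation matrix by eigenvalue
  clipping. Setting the deviation to zero returns the template exactly.
- **Runs.** i.i.d. multivariate normal volumes with covariance equal to the
  latent connectome (scaled by per-condition SD multipliers; the low-demand
  condition gets 1.08, reflecting slightly higher temporal SD under calmer
  viewing), plus independent observation noise (SD 0.5 against unit signal
  SD) and motion contamination.
- **Motion.** Per volume, FD = |N(baseline, jitter)| plus, with probability
  `burst_prob`, a lognormal burst (median 0.35 mm, log-SD 0.8). The burst
  indicator is u < p with u drawn once per volume, so raising p under a
  fixed seed strictly grows the censored set — this common-random-number
  coupling is what makes "more bursts ⇒ more scan time needed" exact per
  subject, not just on average. Contamination adds zero-mean signal noise
  with SD proportional to the local FD maximum over a ±1-volume window
  (spin-history-like carryover): the burst volume itself is censored, but
  its retained neighbours carry degraded signal, so motion hurts reliability
  even after scrubbing. Group defaults: adults baseline 0.06 mm / p = 0.02,
  low-motion children 0.08 mm / p = 0.02, high-motion children (half the
  child sample) 0.11 mm / p = 0.25; per-subject lognormal spread (log-SD 0.4
  on p, 0.15 on baseline) gives each group a realistic within-group range of
  motion propensity instead of a binomially tight cluster.

These defaults were set so the cohort reproduces the qualitative regime of a
dense-sampling pediatric comparison: adults reach whole-connectome TRC ≥ 0.8
near 15 post-censored minutes and need ~30 acquisition minutes for 30 usable
minutes, while high-motion children need roughly 1.5× the post-censored time
and ~47 acquisition minutes, with retention differences of ~25–30 percentage
points. The generator does **not** model hemodynamics, temporal
autocorrelation, session-state drift (available but off by default),
scanner drift, spatial dropout gradients, or respiration physics; passing
tests therefore certify estimator correctness and directionality of motion
and duration effects, not quantitative transfer to any particular scanner or
sample.

## Problem sizes

Tests and the acceptance script run on scaled-down cohorts — typically 4–20
subjects and 40–100 nodes rather than 48 subjects and 1,000 parcels — sizes
chosen so the full suite completes in about a minute while keeping every
Monte-Carlo check comfortably powered. Edge-level ICC is vectorised across
all N(N−1)/2 edges at once, so larger node counts scale quadratically but
remain tractable.

## Numerical choices and degenerate inputs

- Sample (n − 1) SD for temporal SD; Pearson correlations clipped to
  [−1, 1] before any transform.
- Zero-variance nodes make correlation undefined: the error names the
  offending nodes instead of propagating NaNs.
- Template matching: Pearson correlation between a node's connectivity row
  (self-connection excluded) and each binary membership vector; eta² is
  available as an alternative metric. Ties break to the first template in
  canonical order with a warning; a node with no scorable template is
  unassigned unless only one template exists.
- Iterative chunking tiles 1-minute chunks from the start of the censored
  concatenated series and drops the final partial chunk; chunks may span run
  boundaries (the data are concatenated), and sampling is without
  replacement within an iteration.
- Split-session halves take the *earliest* retained volumes
  ("first T minutes"), matching what a truncated acquisition would have
  collected.
- All randomness flows through `numpy.random.Generator` streams spawned from
  a single seed; identical config + seed reproduces byte-identical outputs,
  including the pipeline's JSON report (which deliberately contains no
  timestamps).

## Known limitations

- The normal-density motion cutoff is sensitive to group-variance estimates
  in small cohorts; a kernel-density variant is not implemented.
- Linear mixed-effects modelling of time-to-threshold, ANOVAs, and post hoc
  tests are out of scope; the pipeline exports the per-subject tables
  (subject, group, mean FD, time-to-threshold) for external modelling tools.
- Multivariate reliability measures (discriminability, I2C2) and ICC
  confidence intervals are not provided.
- Vertex-level surface analysis is replaced by parcel-level analysis
  throughout; this is a resolution change, not a method change.
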