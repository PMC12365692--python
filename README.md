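# fcreliab

Test–retest reliability of functional connectomes as a function of scan
duration, head motion, and viewing condition — with a synthetic multi-session
BOLD cohort generator so every estimator can be validated against known ground
truth.

## The problem

Precision fMRI studies collect large amounts of data per person to obtain
reliable individual-level connectomes. How much data is enough? The answer
depends on head motion (censored volumes do not count toward usable scan
time, and residual sub-threshold motion degrades what remains), on age (young
children move more and show intrinsically noisier connectivity), and on what
participants watch in the scanner. This package implements the analysis
machinery needed to answer that question for a dense-sampling family design
— parent–child pairs, 4 sessions, 3 passive-viewing conditions × 2 runs × 205
volumes at TR = 2 s — starting from parcellated, denoised BOLD time series.

It is written for developmental and precision-fMRI researchers planning scan
budgets, and for methodologists studying reliability estimators.

## What it computes

- **Censoring and retention.** Power-style framewise displacement
  FD_t = Σ|Δd| + r·Σ|Δθ| (r = 50 mm), optional zero-phase low-pass filtering
  of motion parameters (> 0.1 Hz respiratory band, phase-encoding axis),
  censoring at FD > 0.15 mm, retention percentages, and the acquisition time
  needed to bank a target amount of post-censored data.
- **FC test–retest correlation (FC-TRC).** Fisher-z Pearson connectomes from
  censored, concatenated runs; TRC is the Pearson correlation between the
  flattened upper-triangle edge vectors of two connectomes built from
  independent data splits. Two estimators: *split-session* (session halves,
  e.g. 1+4 vs 2+3, truncated to the first T post-censored minutes, averaged
  over the three balanced splits) and *iterative* (random 1-minute chunks
  forming a fixed "true" reference vs residual subsets, averaged over
  iterations). Time-to-threshold (TRC ≥ 0.8, linearly interpolated), Cohen's
  d between motion groups, and per-step incremental benefit.
- **ICC(2,1).** Two-way random-effects, absolute-agreement, single-measure
  intraclass correlation across subjects' split-half connectomes:
  ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)),
  computed per edge, averaged within network blocks either before or after
  the variance decomposition, per parcel, and swept over split-half durations;
  values binned poor / fair / good / excellent.
- **Motion grouping.** Normal densities over post-censored volume counts per
  age group; the density intersection between the group means is the
  low/high-motion cutoff (fewer retained volumes ⇒ high motion).
- **Template matching.** Node-to-network assignment by correlating each
  node's connectivity profile with binary network templates; group consensus
  maps at 66%/75% agreement; analysis filter dropping unlabeled nodes and
  networks with fewer than two members.
- **Survey scoring.** Attention (percent correct recall) and drowsiness
  (0–3 coded per run, summed over the two runs per condition).
- **Synthetic cohorts.** Subject-specific latent connectomes perturbed around
  a block-structured group template (Fisher-z Gaussian deviations plus
  network-coherent offsets, projected back to a valid correlation matrix);
  runs drawn as multivariate normal signals that converge to the latent
  connectome, plus observation noise and FD-scaled contamination; two-state
  motion model (baseline jitter + lognormal bursts with spin-history-like
  carryover to neighbouring volumes).

## Worked example

```python
import fcreliab as f

cfg = f.SyntheticCohortConfig(n_pairs=2, n_nodes=60, seed=42)
cohort = f.generate_cohort(cfg)
subject = "child001"                      # a high-motion child
runs = cohort.subject_runs(subject)
masks = [f.censor(r.fd, threshold_mm=0.15) for r in runs]

retained = sum(m.n_retained for m in masks)
total = sum(r.n_volumes for r in runs)
print(f"{subject}: retained {retained}/{total} volumes ({100*retained/total:.1f}%)")

pre = f.pre_censored_time_to_reach(masks, target_minutes=30, tr_seconds=2.0)
print(f"acquisition needed for 30 usable minutes: {pre:.1f} min")

curve = f.split_session_trc(
    runs, f.default_split_scheme(4), f.duration_grid(5, 40, 5), masks=masks)
print(f"time to TRC >= 0.8: {f.time_to_threshold(curve, 0.8):.2f} min")
```

prints

```
child001: retained 2693/4920 volumes (54.7%)
acquisition needed for 30 usable minutes: 55.0 min
time to TRC >= 0.8: 31.31 min
```

This child loses almost half of the acquired volumes to censoring, needs 55
minutes in the scanner to bank 30 usable minutes, and the split-session
reliability curve crosses 0.8 only after ~31 post-censored minutes — roughly
twice the time a low-motion adult in the same cohort needs.

The same stages are available from the shell:

```bash
fcreliab simulate --out data/ --seed 1
fcreliab censor --in data/ --out censored/ --fd-threshold 0.15
fcreliab trc --in data/ --out trc.csv --method split --grid 5:40:5
fcreliab all --out results/   # full pipeline + report.json
```

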