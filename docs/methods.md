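# Methods

This note documents the models, statistical procedures, and numerical
choices implemented in `subneuro`, and what the synthetic-data tests do and
do not demonstrate about real intraoperative recordings.

## Task model and synthetic behavior

A trial is: a 300-ms auditory go cue, a 500-ms delay, a 2-s stimulation
window inside which a 100-ms vibrotactile stimulus occurs at a uniformly
random time (except on catch trials, exactly `round(0.2 · n_trials)` per
session, randomly placed), and a respond cue 0.5–1 s after the window
closes. Sessions default to 71 trials. A 2-s inter-trial interval holds the
verbal response and the next trial's 500-ms pre-cue baseline. All times are
stored in seconds from session start; analysis grids are in milliseconds.

The simulated observer is a logistic psychometric function of
log-amplitude,

    p(yes | a) = γ + (1 − γ − λ) · expit(k · log(a / θ)),

with false-alarm floor γ (default 0.24, matching the false-alarm rate such
patients produce), lapse λ = 0.02, slope k = 8 and threshold θ. Catch
trials are answered "yes" with probability γ. The 1-up/1-down staircase
multiplies the amplitude by 0.95 after a hit and 1.05 after a miss
(multiplicative rather than additive steps — "5% steps" is honored and
amplitudes stay positive for free) and leaves it unchanged on catch trials;
it converges onto the amplitude where p(yes) = 0.5, so the long-run hit
rate is 50% regardless of θ. An optional nonstationary failure mode
(`dropout_prob`, `dropout_len`) starts blocks of forced misses, emulating
the attention lapses seen after anesthesia; cohorts by default give 25% of
sessions a severe version (probability 0.2 per trial of a 30-trial block),
which the behavioral filter then rejects at a rate comparable to clinical
practice (roughly a quarter of sessions discarded).

## Synthetic spike trains

Each neuron's rate function is `baseline × (product of active gains) +
drift`, where the cue gain is active for a configurable window after cue
offset, the task gain throughout the stimulation window, the sensory gain
from `latency` to `latency + duration` after every stimulus, and the
perception gain likewise but on hit trials only. Gains below 1 encode
suppression — the dominant direction in these structures. Drift is a linear
within-trial ramp anchored at cue onset (Hz/s), i.e. exactly the kind of
slow trend the catch-trial correction is designed to remove. Spikes are
drawn by thinning a homogeneous Poisson stream at the envelope maximum
(1-ms envelope resolution) and then imposing a hard refractory floor
(default 2 ms). A negative envelope anywhere raises an error rather than
being clipped.

Randomness is organized as named substreams of one master seed
(`SeedSequence.spawn`): behavior, artifacts, and each neuron are
independent, so the same trial table is reproduced no matter how many
neurons are simulated.

Artifact epochs (vocal-response cross-talk in the real recordings) are a
Poisson process (default 0.02 /s) of 0.2–1-s blanks; any trial whose
analysis epoch overlaps one is excluded from that analysis, with the
exclusion reason recorded.

What the generator does **not** emulate: spike waveforms and sorting
errors, bursting/oscillatory (e.g. beta-band) structure, rate
nonstationarities other than the linear ramp, covariation between behavior
and excitability, and amplitude-dependent response scaling. Passing
parameter-recovery tests therefore demonstrates correctness of the
analysis chain under the stated generative assumptions, not robustness to
every pathology of intraoperative data.

## Behavioral quality control

Outcomes partition as hit / miss (stimulus present, report yes/no) and
false alarm / correct rejection (catch, report yes/no). The trial-wise hit
rate is a centered 11-trial moving average over **stimulus trials only**
(catch trials carry no hit/miss information); the first and last five
positions use mirror reflection without repeating the edge element. Trials
with local hit rate outside the open interval (0.25, 0.75) are removed
from hit-vs-miss analyses; a session is discarded when fewer than 10 hits
or 10 misses survive. The trace is computed once, on the original
ordering; the filter is therefore idempotent by construction. Cue, task,
and sensory analyses use all artifact-free trials — the filter exists to
balance the perception contrast, not to censor the neural data.

Hit-vs-miss covariate checks (stimulus amplitude, stimulus onset) use a
permutation test on the difference of group means; two-sided p-values are
primary and both one-sided p-values are reported. Group comparisons of
per-participant rates use the Wilcoxon rank-sum test (exact for small
samples).

## Firing-rate estimation

Rates are sums of unit-mass Gaussian kernels (σ = 40 ms) centered on spike
times, evaluated on a 1-ms grid in Hz. Kernels are truncated at ±4σ and
renormalized by the truncated mass, so the integral of any trace over its
spikes' support equals the spike count to numerical precision (the test
suite enforces 1e-3). Epochs are padded by 4σ of raw spikes before
evaluation, so in-window estimates carry no edge bias; there is no edge
renormalization. Windows are half-open `[start, end)` throughout.

Bootstrap SEM is the standard deviation (ddof = 1) of trial-resampled mean
traces, 1000 resamples by default.

Drift correction subtracts the pointwise mean cue-locked catch-trial trace
from each cue-locked stimulus-present trial, then re-samples each residual
onto a stimulus-locked grid by integer-millisecond shifting. It removes
*exactly* any rate component common to catch and stimulus trials in
cue-locked time; corrected values are residuals and may be negative. All
artifact-free catch trials are used however few; below 5 a warning is
raised (typical sessions have ~9).

## Selectivity analyses

All analyses gate on ≥ 20 usable trials per condition; the perception
analysis additionally requires a behaviorally kept session and ≥ 10 hits
and ≥ 10 misses after QC. Ineligible neurons carry a machine-readable
reason and are excluded from population denominators.

- **Cue**: exact two-tailed sign test on per-trial spike counts (500 ms
  after cue offset vs 500 ms before cue onset); zero differences dropped.
- **Task**: paired sign-flip permutation test on per-trial mean rates in
  Hz (2-s stimulation window vs 500-ms baseline). Rates, not raw counts,
  keep the unequal window durations comparable.
- **Sensory**: drift-corrected stimulus-locked rates, scanned against each
  trial's scalar mean over the 300-ms pre-stimulus baseline with a paired
  signed-rank test at every 1-ms step of the first 400 ms. (The scalar
  baseline reading is implemented; a pointwise-baseline variant would be a
  one-line change in the scan call.)
- **Perception**: unpaired rank-sum scan of hit vs miss rates over the
  same window. No drift correction is needed — a common drift cancels in
  the contrast.

A neuron is selective when a maximal run of pointwise significance
(α = 0.05, two-sided) is strictly longer than 80 ms — twice the kernel SD,
read strictly: ≥ 81 samples on the 1-ms grid. Of several qualifying runs
only the longest is kept; ties go to the earliest. Effect latency and
duration are the surviving cluster's start and length; cohort summaries
are reported mean ± SEM.

### Pointwise tests, vectorized

Population nulls re-run the full scan a thousand times per neuron, so the
signed-rank and rank-sum tests are computed column-wise with the normal
approximation using exact moments of the realized tie-averaged ranks:
under random signs `W⁺ = Σ rᵢbᵢ` has mean `Σr/2` and variance `Σr²/4`
exactly; under random group assignment the group rank sum has the
finite-population moments of a without-replacement sample of the pooled
ranks. No continuity correction is applied. Because |differences| are
invariant under sign flips and pooled ranks under label shuffles, each
permutation reduces to one matrix product. The suite verifies agreement
with `scipy.stats.wilcoxon` / `mannwhitneyu` column-by-column. The normal
approximation is accurate from ~15 trials per condition; the 20-trial gate
keeps every scan above that.

### Permutation nulls

Population inference counts selective neurons and compares the count to a
null built by sign-flipping each neuron's per-trial differences (cue,
task, sensory) or shuffling its hit/miss labels (perception) and re-running
the complete decision rule — including the inner permutation test for task
and the full cluster scan for sensory/perception. Monte-Carlo p-values use
the add-one correction `p = (1 + #{null ≥ obs}) / (1 + n_perm)`, so they
are bounded below by 1/1001 and never zero. Whenever the joint permutation
space has ≤ 2¹⁰ elements, each neuron's space is enumerated exhaustively
and — since neurons permute independently — the exact null of the count is
the Poisson-binomial convolution of per-neuron flag probabilities; exact
p-values are plain proportions. The same exact/Monte-Carlo switch applies
to the covariate, task, region-proportion, and overlap tests.

### Calibration, measured

On 200 flat-Poisson neurons (20 Hz, 40 stimulus trials) the suite measures
per-analysis null flag rates of about 0.04 (cue), 0.04 (task), 0.08
(sensory) and 0.06 (perception). Cue and task sit at or below nominal
α = 0.05 (the exact sign test is conservative at discrete counts). The
scan-based analyses can exceed nominal α per neuron: 40-ms smoothing makes
neighboring 1-ms tests strongly dependent, and in the sensory analysis the
subtracted catch mean (estimated from ~10 trials) adds noise *common to
all stimulus trials*, which a paired test sees coherently. Both mechanisms
are inherited by the sign-flip/label-shuffle population nulls, so
population-level p-values remain calibrated even where the per-neuron
effective α is inflated — this is precisely why the population null
re-runs the full pipeline rather than assuming a per-neuron α.

Injected-effect recovery, measured at the generator's study-scale
conditions (suppression to 40% of a 25-Hz baseline, 150-ms latency, 120-ms
duration, 20 hits + 20 misses): the perception scan flags the effect in
~82% of simulations, and in ~74% the cluster onset lands within one kernel
SD (40 ms) of the true latency. The limiting factor is not pointwise power
(~95% at the effect center) but the requirement of an unbroken 81-ms
significant run when the high-power span is only ~120 ms wide; longer or
stronger effects are recovered essentially always. Latency estimates are
biased slightly early (smoothing spreads the effect backward) with a
spread of ~20 ms.

## Latency mixture

For each of the sensory and perception analyses, the count of neurons
whose cluster covers each millisecond of 0–400 ms forms a significance
trace (1-ms bins; the bin width is a parameter). An amplitude-weighted sum
of two Gaussian curves is fit to the trace by least squares — curve
fitting to counts, deliberately not a probability-density EM fit, since
the quantity of interest is the shape of the trace. Constraints: means in
[0, 400] ms, SDs in [10, 200] ms, weights ≥ 0. The optimizer is
box-constrained L-BFGS-B; each fit takes the best of 20 restarts drawn
uniformly inside the constraint boxes from a named substream. (An
interior-point optimizer, `trust-constr`, recovers constructed traces to
the same precision but ~8× slower; L-BFGS-B was chosen on speed alone.)
The best single-Gaussian fit uses the same protocol, and bimodality is
declared when `MSE(1 component) / MSE(2 components) > 4`. Components are
always reported early-mean first. On exact two-Gaussian traces the means
are recovered to < 1 ms; at cohort scale (8 neurons, ~100-ms clusters) to
within ~15 ms.

## Degenerate inputs and tie-breaks

- Sign test / signed-rank: zero differences dropped; columns with < 2
  nonzero differences get p = 1.
- Cluster-length tie: earliest cluster retained.
- Median split for covariate controls: stable argsort, lower half gets the
  extra trial on odd counts.
- All-zero significance trace: mixture fit refuses (validation error)
  rather than returning a meaningless fit.
- Sessions with zero artifact-free catch trials: sensory analysis marked
  ineligible ("drift correction unavailable") rather than silently
  uncorrected.

## Problem sizes

The test suite and the acceptance script run at deliberately chosen sizes:
cohorts of 48 sessions / 50 neurons with 71 trials (the study scale for
cohort-level quantities), 200 neurons for null calibration, 100 simulations
for recovery rates, 10,000 trials for staircase convergence, and 1000
permutations for all Monte-Carlo nulls — the same permutation count used
for the real analyses.

## Known limitations

- The per-neuron effective α of the scan analyses depends on the number of
  catch trials and the kernel width; it is measured, not nominal. Cross-
  study comparisons of *counts* of selective neurons should rely on the
  population permutation p-values, which inherit the correct null.
- Latency estimates from cluster onsets are biased early by smoothing and
  censored at the 0/400-ms window edges; the mixture means partially
  average this out but inherit the censoring.
- The interchange format stores spike times, not waveforms; unit grading
  (single vs multi) is metadata supplied by the upstream sorter.
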