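# Methods

## Model

The subject's affective trajectory is modeled as a discrete-time,
discrete-space Markov chain over the four circumplex quadrants
A = stress (high arousal, negative valence), B = engagement (high, positive),
C = boredom (low, negative), D = relaxation (low, positive). The chain is
not fitted to observed state sequences; instead, its transition matrix is
*measured physiologically*: the short-term heart-rate variability elicited
around each induced transition is taken as the propensity of that
transition, and row-normalization turns propensities into probabilities
(P_ij = Δ_ij / Σ_k Δ_ik, self cell included in the denominator). The key
assumptions are therefore

1. the stimulus protocol actually induces the labeled affective states in
   block order;
2. vagally mediated variability (RMSSD) in the 30 s around a boundary
   indexes the subject's physiological reactivity to that specific
   transition; and
3. reactivities on a row are comparable, so their relative sizes are
   meaningful as probabilities.

The Markov property itself (next state depends only on the current state)
is a modeling convention inherited from the one-boundary-at-a-time design,
not something the data can falsify here: each directed transition is
observed exactly once per run.

## Protocol machinery

The block order is an Eulerian circuit of the complete directed graph K4*
(12 edges, in-degree = out-degree = 3 everywhere, so a circuit always
exists), generated by a seeded randomized Hierholzer traversal; any valid
circuit is equally acceptable and different seeds sample different
circuits. Stimuli are classified by strict SAM thresholds (> 6 high, < 4
low; values on or between the cuts are excluded) and drawn without
replacement, 12 per block, 156 per run. Analysis windows are half-open
[start, end): 30 s at each boundary (120k ± 15 s relative to
first-stimulus onset) and 30 s centered at 60 s into each state's *first*
block for the self cells. An interval belongs to a window iff its
terminating beat time falls inside it; half-openness prevents a beat on a
shared edge from counting twice. Baselines (120 s before and after) carry
no windows.

## Signal processing

RMSSD is computed exactly as the root mean square of successive
differences over the intervals in a window; windows with fewer than 3
intervals (configurable `min_intervals`) are an error rather than a
numerically legal but meaningless value.

Artifact correction is automatic and reproducible: an interval is flagged
when it deviates from the median of its 11-beat neighborhood (itself
excluded) by more than a named threshold level — very_low 450 ms, low 350,
medium 250 (default), strong 150, very_strong 50. Two refinements matter in
practice:

- **Decontaminated detection.** A burst of adjacent artifacts drags its own
  local median toward the artifact values; the median is therefore
  re-estimated over currently-unflagged neighbors until the flag set
  stabilizes, which recovers whole bursts.
- **Duration-preserving repair.** The underlying ECG time base is fixed, so
  repair must not move the beats that follow. Each maximal flagged run's
  exact time span is re-divided into the number of beats the surrounding
  rhythm implies, with values interpolated linearly between the nearest
  unflagged neighbors: an ectopic split (short+short) merges back into one
  normal interval, a missed beat (one double interval) splits into two, and
  every unflagged interval — and the recording's total duration — is
  preserved bit-identically. Count-preserving value interpolation was
  rejected because it shifts all subsequent beat times (~0.8 s per
  corrected split), which mis-aligns every later analysis window.
  Flag-and-repair iterates to a fixed point, making correction idempotent.

## Steady states and rounded matrices

Two routes to the stationary distribution are implemented: power iteration
(π₀·Pⁿ, default n = 10 from the uniform π₀) and the left eigenvector of P
for eigenvalue 1 (requiring irreducibility and aperiodicity, checked on the
sparsity pattern via strong connectivity and aperiodicity of the transition
digraph; reducible or periodic chains are an error, not a silent answer).
On strictly positive matrices the two agree to ≤ 1e−6 per entry (tested on
200 random chains).

Matrices re-keyed from publications rounded to two decimals have row sums
of only ~0.99–1.00; `TransitionMatrix.from_rounded` accepts ±0.02.
Renormalization is deliberately *optional and off by default* — iterating
the printed values verbatim is what reproduces the published steady state
(state A rounds to 0.18 raw but 0.19 after renormalizing), and the
`renormalize` flags on ingestion and on `steady_state_power` let users pick
either convention explicitly. Probabilities are kept at full precision
internally; rendering (summary, DOT labels) rounds to two decimals.

## Synthetic data generator

`simulate_rr` draws independent Gaussian RR levels: RR_i = clip(μ + e_i),
e_i ~ N(0, σ(t)²/2), with σ(t) the target RMSSD of the window containing
the beat's expected time and the baseline RMSSD (default 30 ms) elsewhere;
for independent levels the successive-difference variance is σ², so the
expected windowed RMSSD equals the target. Defaults: mean RR 800 ms
(75 bpm), clip bounds 300–2000 ms (clipping bias is negligible for
σ ≤ 100 ms at these means), recording spans the full 1560 s stimulus
timeline (~1950 beats). Artifact injection preserves total duration
exactly: ectopic_split replaces RR with (0.4·RR, 0.6·RR); missed_merge sums
two adjacent intervals.

This generator is a test scaffold, not cardiac physiology: it omits
respiratory sinus arrhythmia, autocorrelation, trends and non-Gaussian
tails. Passing recovery tests therefore demonstrates that the pipeline's
windowing, correction and normalization are unbiased and correctly aligned
— not that RMSSD differences in real recordings will be as cleanly
separable.

`recovery_experiment` (50 seeds by default in the acceptance suite;
problem size ~1950 beats × 50 runs, a few seconds of compute) simulates,
corrects, windows and Markovizes, reporting per-cell median absolute and
relative error against the profile-implied target matrix. With targets
proportional to the built-in published single-case matrix, the maximum
per-cell median absolute error is ≈ 0.03 (30 s windows hold ~37 beats, so
a single window's RMSSD has ~12 % sampling error; row-normalization over
four cells averages much of it out). With 2 % injected ectopic splits and
medium correction the error inflates by a factor ≈ 1.02.

## Numerical choices and degenerate inputs

- Row-stochasticity is enforced at 1e−9 on computed matrices.
- A zero-sum RMSSD row (possible only for an identically constant window
  row) is an error naming the state, since its probabilities are undefined.
- Empty files, non-positive intervals and out-of-range SAM ratings fail
  with stage-tagged exceptions; the CLI maps stages to distinct exit codes.
- All randomness is explicit: `seed` arguments everywhere, no global state;
  identical inputs give byte-identical JSON reports.

## Known limitations

- Single-subject, single-run design: one 30 s window per matrix cell, so no
  within-run uncertainty estimate for P_ij is possible; the recovery
  experiment quantifies sampling error only under the synthetic generator.
- The artifact thresholds are a reproducible convention, not an estimate of
  any specific device's error process.
- Self-transition cells measure within-state variability of the first
  block only; repeat blocks of a state contribute nothing to the diagonal.
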