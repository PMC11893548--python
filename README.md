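# affectdyn

Affect dynamics from heart-rate variability: quantify how a person moves
between the four circumplex affective states — **stress (A)**, **engagement
(B)**, **boredom (C)** and **relaxation (D)** — during a block-design
emotional-picture protocol, using windowed ultra-short-term RMSSD and a
discrete-time, discrete-space Markov chain.

It is aimed at psychophysiology researchers and clinicians who want a
patient-centered, single-subject index of emotional flexibility: which
transitions between affective states the body reacts to, which states the
person tends to stay in, and where the dynamics settle in the long run.

## The method

**Protocol.** Stimulus images are classified into circumplex quadrants by
their normative SAM ratings (arousal/valence on 1–9; high > 6, low < 4,
anything in between excluded). 13 blocks of 120 s (12 images × 10 s) are
ordered so that the 12 block boundaries realize each of the 12 directed
transitions between the four states exactly once — an Eulerian circuit on
the complete directed graph over {A, B, C, D}.

**Signal.** From the RR-interval series (artifact-corrected with a
threshold-vs-local-median rule), RMSSD

```
RMSSD = sqrt( 1/(N−1) · Σ_{i=1}^{N−1} (RR_{i+1} − RR_i)² )    [ms]
```

is computed in 16 thirty-second windows: one straddling each block boundary
(120k ± 15 s, the 12 *transition* windows) and one in the middle of each
state's first block (60 ± 15 s from block start, the 4 *self-transition*
windows).

**Markovization.** The 16 RMSSD values fill a 4×4 matrix Δ; dividing every
row by its sum gives a row-stochastic transition matrix, P_ij = Δ_ij / Σ_k Δ_ik,
interpreted as the probability of moving from state i to state j.
Descriptive indexes group the entries by geometry on the circumplex —
vertical (AC, CA, BD, DB: arousal flips), horizontal (AB, BA, CD, DC:
valence flips), oblique (AD, DA, BC, CB: both flip) and self (AA…DD) — and
the predictive index is the steady state π ≈ π₀·Pⁿ from the uniform
π₀ = (0.25, 0.25, 0.25, 0.25) (10 power steps by default, cross-checked
against the left eigenvector of P for eigenvalue 1).

A seeded synthetic-data module generates RR recordings whose expected
windowed RMSSD equals any chosen 16-cell target profile, so the entire
pipeline is testable end-to-end by parameter recovery without any recorded
data.

## Worked example

```python
import affectdyn as ad

sched = ad.generate_schedule(seed=7)          # 13 blocks, all 12 transitions
ws    = ad.place_windows(sched)               # the 16 analysis windows
prof  = ad.VariabilityProfile.from_matrix(ad.example_patient_matrix())
rr    = ad.simulate_rr(sched, ws, prof, ad.SimulationConfig(seed=21))

res = ad.AffectDynamics(rr, sched).fit()
print(res.summary())
```

prints (abridged):

```
Beats analyzed:   1949    Artifacts corrected: 0 (level=medium)

Windowed RMSSD (ms)            Transition probabilities
            A      B      C      D                A      B      C      D
  A      24.3   21.1   25.2   28.4      A      0.25   0.21   0.26   0.29
  B      27.1   20.9   22.8   29.2      B      0.27   0.21   0.23   0.29
  C      10.2   48.8    8.8   14.5      C      0.12   0.59   0.11   0.18
  D      18.6   22.7   37.2   18.3      D      0.19   0.23   0.38   0.19

Steady state (probability of each state after many transitions)
  power  A=0.21  B=0.31  C=0.24  D=0.24   (converged=True, 10 steps)
  eigen  A=0.21  B=0.31  C=0.24  D=0.24   (converged=True)
```

Row C reads: coming out of boredom, this (simulated) subject's short-term
vagal variability concentrates on the move to engagement (P_CB = 0.59) —
the recording was simulated from targets proportional to a published
single-case matrix with P_CB = 0.58, and one run of the pipeline recovers
each probability to within a few hundredths. The steady state says that
after many transitions the subject is most likely found in engagement
(B ≈ 0.31).

The same analysis is available from a shell:

```bash
affectdyn schedule --seed 7 --out schedule.json
affectdyn simulate --schedule schedule.json --seed 21 --out rr.txt
affectdyn analyze  --rr rr.txt --schedule schedule.json --out-dir results/
affectdyn graph    --matrix results/transition_matrix.csv --out grapho.dot
```

`analyze` writes `report.json`, both matrices as CSV and the color-coded
transition graph (`transitions.dot`, Graphviz DOT: vertical green,
horizontal yellow, oblique orange, self gray).

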