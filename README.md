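# tempocat

An attractor-network model of **temporal categorization**: how a brain
circuit decides whether an elapsed interval was "short" or "long", holds
that decision across a memory delay, and turns it into a reaching
movement whose kinematics carry signatures of the decision process.

## The scientific problem

In the interval-categorization (temporal bisection) task a subject
watches a visual stimulus whose duration is drawn from a set of eight
intervals between 450 and 920 ms, waits through a delay, and then reaches
with a joystick-driven cursor to one of two response circles — one
meaning "short", one "long". The implicit category boundary sits at
687.5 ms. The behavioural signatures are robust: a sigmoidal psychometric
curve with errors concentrated at the intervals flanking the boundary; a
reaction time (RT) that is an inverted U over intervals (hard decisions
are slow) and grows with the angular separation of the two response
circles; a movement time (MT) that decreases with that separation; and
slower RTs on error trials at the easy extreme intervals.

This package implements a mechanistic model that reproduces those
signatures: two mutually inhibiting rate units accumulate the interval
(winner-take-all dynamics with a 155 ms time constant), a second, slower
pair (500 ms) holds a parametric memory trace across the delay, and
downstream *reading areas* average each category's accumulation and
memory activity. RT and MT are threshold crossings of the winning
reading area's normalized distance to its attractor. The model is
complemented by a random-walk (diffusion) baseline that provably cannot
produce a sigmoidal psychometric (its choice curve is exactly affine), a
psychometric-fitting toolbox, a reach-kinematics pipeline (smoothing,
movement bounds, submovement and change-of-mind detection), and a
synthetic-behaviour generator with fully controllable ground truth.

## Worked example

```python
import tempocat as tc

# 1. Simulate the full model: 1,000 trials per interval, all angles
params = tc.AttractorParams()          # shipped calibration, tau = 155 ms
summary = tc.simulate_experiment(params, n_per_interval=1000, seed=42)

# 2. Fit the psychometric curve
fit = tc.fit_psychometric(summary.psychometric)
print(f"PSE {fit.pse_ms:.1f} ms, threshold "
      f"{fit.difference_threshold_ms:.1f} ms")   # PSE ~ 687.5 ms

# 3. Reaction / movement times by target separation (correct trials)
cc = summary.cells[summary.cells.outcome == "correct"]
print(cc.groupby("angle_deg")[["rt_mean", "mt_mean"]].mean())

# 4. A single trial with recorded traces
trial = tc.simulate_trial(709.0, angle=90, params=params, seed=7,
                          record_traces=True)
print(trial.choice, trial.rt_ms, trial.mt_ms)

# 5. Synthetic joystick data with ground truth, then recover it
design = tc.build_session(seed=1)                 # 24 training + 160 testing
data = tc.synth_session(design, seed=2)
measures = [tc.analyze_trajectory(t) for t in data["trajectories"][:5]]
```

The same workflows are available from the command line:

```sh
tempocat simulate --n 1000 --seed 42 --out results/
tempocat ablate   --n 1000 --seed 42 --out reduced/      # no-memory model
tempocat predict  --delays 0,1000,3000 --out predictions/
tempocat synth    --seed 3 --out synthetic/
tempocat analyze  synthetic/trajectories.csv --out kinematics.csv
tempocat compare  --model results/psychometric.csv \
                  --reference reduced/psychometric.csv
```

Every output CSV carries a provenance header (package version, seed,
parameter hash) and is never overwritten without `--overwrite`.

## Layout

- `src/tempocat/task_design.py` — session/trial structure (8 response
  positions, 20 admissible target pairs, 8 intervals).
- `src/tempocat/attractor.py` — the mutual-inhibition network, readout,
  calibration and generalization predictions.
- `src/tempocat/diffusion.py` — random-walk baseline (gambler's-ruin
  closed form + Monte-Carlo).
- `src/tempocat/psychometrics.py` — logistic psychometric fits and
  model-vs-data comparison statistics.
- `src/tempocat/kinematics.py` — trajectory smoothing, movement bounds,
  submovements, curvature, change-of-mind detection.
- `src/tempocat/synth.py` — minimum-jerk synthetic trajectories and
  whole sessions with ground truth.
- `src/tempocat/cli.py`, `io.py` — command line and provenance-stamped
  file I/O.
- `docs/methods.md` — model assumptions, parameters and numerical
  choices.
- `examples/` — narrative scripts.
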