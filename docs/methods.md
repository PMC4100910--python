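# Methods

## Network model

Four rate units in two uncoupled winner-take-all pairs. Each unit obeys

    tau_i * dx/dt = -x + f(E_x - w * x_opp) + noise,
    f(u) = M / (1 + exp(-beta * u)),

with sigmoid ceiling `M = 10`, slope `beta = 1`, mutual-inhibition
weight `w = 1`, and additive white noise (SD `noise_sd = 0.015` per
unit, Euler–Maruyama scaled by `sqrt(dt)`). Activities are clipped to
`[0, M]`. The *accumulation* pair (units L and S, `tau = 155 ms`) makes
the category decision; the *memory* pair (M_L, M_S, `tau_mem = 500 ms`)
holds a parametric trace of the interval across the delay. Only the
excitatory drives `E` change between task phases; the connectivity never
does.

### Phases

- **Stimulus** (duration = the interval): asymmetric drives
  `E_L = E0 + a`, `E_S = E0 - a` with `E0 = 3`. The network starts in
  the mirror image of the stimulus-phase attractor (the short-category
  prototype) and drifts through a saddle-node bottleneck toward the
  long-category state. The moment its trajectory crosses the L = S
  diagonal is the implicit category boundary.
- **Delay** (default 1000 ms): weak symmetric drive `E = -1.2` for all
  units; both pairs leak toward a common symmetric state, the memory
  pair much more slowly (a correlate of forgetting). Performance
  therefore degrades monotonically with delay length.
- **Response** (cap 3000 ms): the accumulation pair is driven into a
  strongly bistable regime (`E = 5`) and falls into the attractor on its
  side of the diagonal; the memory pair keeps its delay drive.

### Readout

Two downstream reading areas average a node with its memory partner:
`DRA_L = (L + M_L) / (2M)`, similarly for S, both in [0, 1]. The winner
is the reading area leading at the end of the response window. Its
distance to its attractor value, normalized to 1 at response onset, is
the decision variable: RT is its first crossing of an angle-specific
threshold ({45°: 0.61, 90°: 0.59, 135°: 0.56, 180°: 0.54} — wider
target separations need less of the distance covered before movement
can start), and MT the further time until it falls below 0.04. An
optional affine map converts simulated to behavioural milliseconds
(identity by default). Because the target angle only moves thresholds,
RT/MT for every angle are read from the same simulated trace.

Error anatomy: near-boundary intervals leave the network close to the
unstable symmetric state at response onset, so both error rates and
RTs peak there, and error trials at the easy extremes are slow because
noise must carry the state across the diagonal.

### Reduced (ablated) model

`simulate_reduced` removes the memory pair and reading areas: the
thresholds act on the winning accumulation node's own normalized
distance. It still produces a sigmoidal psychometric curve but a much
flatter MT-vs-interval profile — quantified as the range (max − min)
of the correct-trial MT across intervals, which is less than 70% of the
full model's in the shipped configuration.

## Calibration

`calibrate` fixes the stimulus-phase asymmetries so the category
boundary lands at 687.5 ms:

1. **Deterministic stage**: bisect each pair's asymmetry until the
   zero-noise diagonal-crossing time equals the target boundary
   (crossing time is monotonically decreasing in the asymmetry above
   the saddle-node, so plain bisection applies).
2. **Stochastic refinement** (optional, `n_refine > 0`): secant
   iteration of the accumulation asymmetry against the *simulated* PSE
   at the default noise level. This matters because noise interacts
   with the bottleneck: the finite-noise PSE sits ~20 ms away from the
   zero-noise crossing.
3. **Ordering check** (optional): verifies RT increases and MT
   decreases over angles on a fresh simulation; violations raise
   `CalibrationError` naming the constraint.

The shipped constants (`a_acc = 1.88996..., a_mem = 3.24081...`) were
produced by `calibrate(params, n_refine=2000, seed=11)` and verified on
held-out seeds (PSE 686.7–691.8 ms at 2,000 trials/interval against the
687.5 ± 15 ms criterion).

## Diffusion baseline

Evidence accumulates during the stimulus with constant drift and
diffusion, is held through the delay, and after target onset drifts
freely (zero drift by default) between absorbing bounds; absorption at
the lower bound means "short". With zero post-onset drift the hitting
probability is the gambler's-ruin linear form, so the predicted
psychometric is *exactly affine* in the interval — the analytic reason
this baseline cannot reproduce the sigmoidal choice curve. Monte-Carlo
validation uses discrete 1 ms Gaussian walks; note that discrete walks
overshoot the bounds by O(sigma·sqrt(dt)) per absorption, so closed-form
comparisons are made at step sizes small relative to the bound span.

## Psychometrics

`fit_psychometric` is a maximum-likelihood binomial logistic
(location/scale, no lapse parameter) via iteratively reweighted least
squares. Reported indices: PSE = −b0/b1, difference threshold =
ln(3)/|b1| (half the 25–75% spread), constant error = PSE − boundary.
Degenerate data are flagged rather than regularised: all-identical
responses yield NaN; perfectly separating (step) data fall back to
linear interpolation of the raw proportions for the PSE, with the
threshold reported as 0.

## Kinematics

Processing chain per trial: rotate the path so the chosen target lies at
0° → zero-phase 4th-order Butterworth low-pass (20 Hz) → constant-
velocity Kalman filter with Rauch–Tung–Striebel smoothing. The Kalman
stage's measurement noise is estimated from the Butterworth residual and
its process noise is set so the smoother's characteristic frequency is
~10 Hz; this second stage matters because jerk (third derivative)
amplifies residual noise as frequency cubed.

- **Movement bounds**: crossings of 10% of peak speed around the global
  speed peak. For a minimum-jerk reach these sit at fixed fractions
  0.0863 / 0.9137 of the movement duration (roots of
  `30 s²(1−s)² = 0.1875`), which gives analytic expectations for the
  measured RT and MT.
- **Submovements**: local maxima of jerk magnitude inside the movement
  window above a prominence floor; a single smooth movement contributes
  one peak, so submovements = max(peaks − 1, 0). The floor is the larger
  of 5% of the window's peak jerk and 2× the largest pre-target-onset
  jerk (the hold period contains only measurement noise, pinning the
  scale below which jerk structure is indistinguishable from noise).
- **Curvature**: the movement-window path is resampled to 100
  arc-length-equidistant points; reported are the area between path and
  chord and the polar angle of the maximum perpendicular deviation.
  Deviations below 1% of the chord length count as straight (angle 0).
- **Decision change**: maximum-deviation angle exceeding half the
  inter-target angle (45/90/135°); for opposite targets (180°) the sign
  of the first five post-onset samples along the chosen-target axis.

## Synthetic data

Trajectories compose a quintic minimum-jerk profile (peak speed
1.875·d/T) with, optionally: a change of mind (an initial minimum-jerk
segment toward the non-chosen target blended at 30% of the movement into
a corrective quintic with matched position/velocity/acceleration);
out-and-back pulses along the chord whose peak jerk is 40× the base
movement's interior jerk peak (detectable through smoothing, while the
speed dip stays far above the 10% bound threshold); and additive
Gaussian position noise. Ground truth records both the number of
*inserted pulses* and the *ideal measurement* (the analysis pipeline run
on the noise-free path) — a compact velocity perturbation necessarily
contributes several jerk lobes, so the two differ by a
construction-dependent factor, and recovery of submovement activity is
scored as the binary presence/absence of extra peaks. Analytic
expected-RT/MT/vmax values are provided for plain trials only (changes
of mind and pulses reshape the speed profile, so no closed form exists).

Sessions draw choices from a logistic psychometric centred on the
boundary and RT/MT from interval- and angle-dependent means shaped like
the empirical pattern (inverted-U RT with a separation increase, MT
decreasing with separation).

## Numerical choices and limitations

- Integration: explicit Euler–Maruyama at `dt = 1 ms` with simultaneous
  updates of all four units; against an adaptive ODE oracle the
  zero-noise endpoint error over 500 ms is ~4×10⁻⁴ (norm-relative).
  Response-phase traces are recorded in float32 to bound memory at
  large batch sizes.
- Per-interval batches use independent substreams (`seed + 7919·i`), so
  results are invariant to which intervals are simulated together.
- The model is a rate (mean-field) abstraction: no spiking, no
  within-pair heterogeneity, no learning; the delay forgetting is pure
  leak. The affine RT/MT map is identity by default, so simulated
  times are in network milliseconds, not literal behavioural ones —
  orderings and shapes, not absolute values, are the modelled claims.
- The kinematic pipeline assumes uniformly sampled, 2-D, single-reach
  trajectories with a recorded pre-target hold; heavily occluded or
  multi-reach data are out of scope.
- Synthetic sessions model one fixed operating point (no per-subject
  parameter distributions) and are intended for pipeline validation,
  not for fitting individual differences.
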