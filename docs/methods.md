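# Methods

## Model

A lumped two-state ODE describes a volume of subchondral bone at the
lateral condyle of the equine third metacarpus. Bone volume fraction
`f_BM ∈ (0, 1]` changes by surface remodelling: osteoblast and osteoclast
activities (`A_OBL`, `A_OCL`, mm/day — bone thickness formed/resorbed per
unit surface per day) act on the specific surface `S_v(f_BM)` (1/mm), of
which a fraction `α` is available for remodelling. The mechanical signal is
the strain energy density `ψ = σ²/2E` under a uniaxial compressive joint
pressure `σ`, with tissue stiffness `E = E₀ ε̇^γE f_BM³` increasing in both
density and strain rate. Formation follows an increasing Hill function of
`ψ`; resorption a decreasing one (intense loading inhibits osteoclasts), so
resting bone remodels faster than training bone.

Damage `D* ∈ [0, 1]` is a fatigue life fraction. Each loading cycle at
pressure `σ` consumes `1/N_f*(σ)` of the life, where
`N_f* = 10^(−(σ−σ₀)/σ₁) · E/E_nom` is a compressive S–N power law scaled by
stiffness relative to the reference `E_nom` (stiffer bone resists fatigue
longer). Remodelling repairs damage at rate
`[A_OBL + (F_s − 1) A_OCL] α S_v D*/f_BM`: formation dilutes cracks over new
matrix, and resorption removes cracks to the extent (`F_s − 1`) that it
targets them beyond chance. `D* = 1` is local failure of the bone pocket
(clinically palmar osteochondral disease rather than gross fracture) and
terminates a simulation.

Assumptions inherited from the model family: homogeneous material (no
spatial heterogeneity or focal remodelling), stiffness independent of
accumulated damage, remodelling activation independent of `D*`, no
biochemical signalling delays, compression-only loading (tensile `σ` is
rejected rather than extrapolated, since the fatigue law was fitted in
compression). Cycles per day influence damage but not adaptation: formation
saturates above ~36 cycles/day and all modelled workloads exceed that.

## Parameters

Defaults are the `fitted` preset; `pre-fit` keeps the pre-fit
literature values `A_OBL,max = 0.0127`, `A_OCL,max = 0.011` mm/day,
`σ₀ = 134.2` MPa (the four-fold rest:training resorption tuning predates
the fit and is only reproduced under this preset).

| symbol | field | default | units | meaning |
|---|---|---|---|---|
| a, b | `a`, `b` | 11.42, −0.02 | 1/mm, — | specific-surface law |
| α | `alpha` | 0.19 | — | surface fraction available to remodelling |
| E₀, γE | `E0`, `gammaE` | 2500, 0.06 | MPa, — | stiffness law |
| A_OBL,min/max | `AOBL_min/max` | 0.001094 / 0.00603 | mm/day | formation bounds (max fitted) |
| δ_B, γB | `deltaB`, `gammaB` | 7, 1 | MPa, — | formation Hill curve |
| A_OCL,min/max | `AOCL_min/max` | 0.001 / 0.00358 | mm/day | resorption bounds (max fitted) |
| δ_C, γC | `deltaC`, `gammaC` | 1, 2 | MPa, — | resorption Hill curve |
| σ₀, σ₁ | `sigma0`, `sigma1` | 139.0 (fitted), 14.1 | MPa | fatigue-life power law |
| E_nom | `Enom` | 1714.1 | MPa | fatigue-law reference stiffness (`E` at f_BM = 0.9, ε̇ = 0.36/s) |
| F_s | `Fs` | 5 | — | repair specificity (1 = untargeted) |

Reference loading conditions: training `σ = 81.1` MPa, `ε̇ = 0.2974` 1/s,
`v_n = 43.7`/day (a 14 m/s gallop, 8000 m per 30 days); racing/high
workload `σ = 90` MPa, otherwise as training; rest `σ = 30` MPa with no
damage-relevant cycles. The rest strain rate is not observable and is
back-calculated (≈ 0.0225 1/s) so that the rest signal is `ψ = 0.31` MPa on
race-adapted bone (`f_BM = 0.9`), the anchor used to tune the resorption
curve together with the racing value `ψ = 2.36` MPa.

## Numerics

* Integration: `scipy.integrate.solve_ivp` (LSODA), rtol 1e−8, atol 1e−10,
  restarted at every segment boundary of a piecewise-constant loading
  schedule so discontinuities never sit inside a solver step. Rates span
  ~1e−4–1e−2 per day and failure must be located sharply.
* Failure: terminal event on `D* − 1` (event root-finding, well inside the
  0.1-day reporting precision), not grid inspection. `D*` is never clipped
  below 1 — integration stops at the event. `f_BM` is clipped to
  `[1e−9, 1 − 1e−9]` inside the right-hand side so `S_v` and `E` stay
  defined at the `f_BM → 1` boundary, where `√(1 − f_BM)` is non-Lipschitz;
  clipping is flagged on the result.
* Hill terms evaluate `ψ^γ/(δ^γ + ψ^γ)` with the convention `0 ↦ 0`, so
  sigmoidicities below 1 remain defined at `ψ = 0`.
* Steady state: `|df_BM/dt| < 1e−7`/day sustained for 50 consecutive days;
  the reported time-to-steady-state is the first day of that sustained
  window. The criterion is a package convention (used consistently
  everywhere, including the de-adaptation timescale) since "steady state"
  admits many operational definitions. Degenerate loading (formation ≡
  resorption for every signal, so every `f_BM` is stationary) and
  boundary-type steady states (`f_BM → 1`, vanishing remodelling surface)
  are detected and flagged.
* Damage plateau: `time_to_failure` reports a plateau when `dD*/dt` falls
  below 1e−3/day with `D* < 1`. At that rate damage needs over 1000 days —
  several racing campaigns — to traverse the unit interval, an order of
  magnitude below training-intensity formation rates (~3e−3–1.5e−2/day), so
  it is stationary on every timescale the model addresses. Under the
  training workload damage plateaus near 0.5 (repair balances formation);
  under the racing workload it never does and the bone fails.
* Batch evaluation (sensitivity analysis): a fixed-step classical
  Runge–Kutta integrator (dt = 0.05 day) vectorised across samples, with
  failure crossings located by linear interpolation within the step. Its
  agreement with the adaptive reference integrator is itself under test
  (~1e−9 at defaults).

## Calibration

Three parameters are re-estimated: `A_OBL,max`, `A_OCL,max`, `σ₀`. Data are
cross-sectional bone volume fractions (one observation per limb against
days in training or rest) and a right-skewed set of fracture times whose
median anchors the fatigue law — the median, not the mean, because times to
fracture are strongly skewed.

Arm conventions (all config-overridable; each traces to a printed anchor):
training arm simulated from `f_BM = 0.85` under the training condition;
rest arm from `f_BM = 0.93` under rest; fracture condition is the 90 MPa
high workload from `(f_BM, D*) = (0.9, 0)`. The loss is

    SSE(training) + SSE(rest) + w · ((TTF − median)/median)²

with `w = 1` by default: the relative form of the fracture term makes both
contributions order one at the initial guess without data-dependent
weighting (237 observations at noise sd 0.05 give an SSE near 0.6; the
relative TTF error is O(1) at the pre-fit values). A simulation failure
inside the loss (e.g. no failure within the horizon at extreme trial
values) returns a large finite penalty and is logged. Optimization is
bounded derivative-free Powell — three parameters, a smooth loss, and no
gradients through the event-terminated ODE — started from the pre-fit
literature values with seeded uniform multi-starts inside the sampling
ranges; every start is reported and the best successful one wins.

Identifiability: damage does not feed back on `f_BM`, so the two arms
identify the activity maxima independently of `σ₀`, which is pinned by the
fracture-time term alone. Noise-free synthetic data are recovered to
optimizer tolerance; at noise sd 0.05 and the study sample sizes the median
recovery error across replicate fits stays below 15 % per parameter.

## Sensitivity analysis

Outputs are `f_BM` and `D*` after 70 days (10 weeks) from unadapted bone
(`f_BM = 0.7`, `D* = 0`) under constant loading. All 20 parameters —
including the three loading quantities — are sampled within their stated
ranges, plus a `dummy` variable with no effect on the model to expose
spurious correlations. Runs that fail before 70 days contribute `D* = 1`:
failed bone is maximal damage, and discarding those runs would bias the
measures.

PRCC uses the linear-residual definition: rank-transform every column
(average ranks on ties), regress each parameter's ranks and the output
ranks on all other parameters' ranks, and correlate the residuals. Being
rank-based it is invariant to monotone output transforms. Default n = 1000
Latin-hypercube rows (scipy's LHS engine; one point per equal-probability
stratum per dimension), at least 10 per dimension required.

Sobol indices use Saltelli's scheme (scrambled Sobol' base sequence;
`n_base (2k + 2)` model runs) with the standard estimators for first-order
(`mean(f_B (f_ABi − f_A))/V`), total (`½ mean((f_A − f_ABi)²)/V`) and
closed second-order indices, and percentile bootstrap confidence intervals
over sample rows. Small negative estimates are reported as-is with their
intervals — they are estimator noise and clipping would hide it. Default
base 512 with second-order sampling enabled. Estimators are verified
against closed-form variance shares of additive and pure-interaction test
functions and against an independent first/total-order implementation.

## Training programmes

A programme is a list of phases (rest, pre-training, progressive,
race-fit), each with daily or weekly workouts at a speed and distance. The
speed→load map interpolates linearly between three printed anchors — 30 MPa
at rest, 81.1 MPa / 0.2974 1/s at 14 m/s, 90 MPa at 16 m/s — and the stride
length passes through the one derivable anchor (6.103 m at 14 m/s, which
makes 8000 m per 30 days exactly 43.7 cycles/day); every entry is explicit
configuration, and speeds outside the anchored range are an error, never an
extrapolation. Stride lengths away from that anchor (walk ~1 m, canter
~5.5 m, racing ~6.9 m) are plausible values, overridable like the rest.

Each day collapses to one ODE loading condition: the highest-speed
workout's pressure and strain rate, with cycles aggregated across the day's
workouts. Damage attribution, by contrast, is additive per cycle: each
workout contributes `cycles/N_f*(σ_workout, E(t))` with its own pressure
and the stiffness taken from the simulation's own trace (midday
interpolation), so attribution never recomputes physics. Because the single
daily condition charges every cycle at the fastest workout's pressure,
weekly fast workouts replace that day's routine daily work by default
(fast-work days are exclusive, as in practice); on single-speed days the
attributed damage integrates to the trajectory's own formation term within
quadrature tolerance.

The shipped demonstration programme (four preparations: 7 weeks rest, 4
weeks pre-training at slow canter, 9 weeks progressive and 8 weeks race-fit
with two weekly fast-work days) is a plausible reconstruction for
demonstration, clearly labelled as such — it is not a surveyed programme,
and reproducing any published programme's exact distances is out of scope.

## Synthetic data

The generator emulates the *shape* of the calibration data: cross-sectional
observations (one per synthetic limb; day uniform on the arm's window,
defaults 0–150 days training / 0–120 days rest; value = model trajectory
plus truncated-Gaussian noise confined to (0, 1), sd 0.05 by default) and
log-normal fracture times (log-sd 0.4, visibly right-skewed) rescaled so
the sample median exactly equals a target — by default the generating
model's own time to failure, making round-trip parameter recovery a
well-posed check. Defaults mirror the study sample sizes: 213 training
limbs, 24 resting limbs, 16 fractures.

What it does not emulate: horse-level covariates (age, sex, surface,
trainer), per-horse parameter heterogeneity, repeated measures within
horses, and any real observation-day distribution. Passing recovery tests
therefore shows the pipeline is self-consistent under the stated noise
model, not that field data of this size would constrain the parameters
equally well.

## Problem sizes

Test and analysis runs use: 100-day arm simulations and 30-day integrator
comparisons (Euler oracle at dt ≤ 1e−3 day); PRCC at n = 1000; Sobol at
base 512 (22 528 model runs); calibration recovery with 10 replicate noisy
fits at full sample sizes with single-start Powell; 4000-day horizons for
steady-state searches. These sizes give stable estimates for every check
performed while keeping the full suite fast.

## Known limitations

* The rest strain rate, the calibration arm initial conditions, the
  speed→load/stride tables away from their printed anchors and the
  demonstration programme are reconstructions; all are explicit
  configuration, and conclusions that depend on them (notably the absolute
  size of the rest de-adaptation) inherit that uncertainty.
* The model is lumped: no spatial stress field, focal damage or
  site-specific remodelling.
* Damage does not degrade stiffness and does not trigger remodelling, so
  near-failure mechanics are optimistic.
* Under sustained training-intensity loading `f_BM` creeps toward 1 over
  thousands of days, where the remodelling surface — and with it repair —
  vanishes; the damage "plateau" is quasi-steady, not a true equilibrium.
* PRCC signs are stable at n = 1000, but Sobol second-order estimates at
  base 512 carry wide bootstrap intervals; rankings among small
  interactions should not be over-read.
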