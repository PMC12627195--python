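# Methods

## Scope and data model

The package analyzes serial dependence in continuous color reports: on each
trial a target hue on a 360° wheel is reported by a mouse click, and the
signed report error is modeled as a function of the previous trial's target
color relative to the current one, `x = wrap(prev − current) ∈ (−180°, 180°]`
(positive = previous target clockwise of the current one; the boundary maps
to +180° by convention so binning is deterministic). Three report types are
distinguished: *perceptual* (target visible during the response), WM
*consolidation* (immediately after mask offset), and WM *retrieval* (after a
retention delay). Relative colors step through −144°:36°:+144°; a uniformly
drawn "random" target appears about every tenth trial and is excluded, as
are trials immediately following it (their `x` is off the 36° grid and
cannot enter a step bin without distortion) and the first trial of a block.
Circular mean errors per participant × report type × bin are the fitting
unit; the −144° and +144° bin means are averaged into a synthesized ±180°
bin (ten conditions total). A sign-respecting variant of the edge synthesis,
`(e(+144) − e(−144))/2`, and a global sign-convention flip are available as
switches for sensitivity checks.

## The DoG bias curve

`y(x) = α·w·x·c·e^(−(wx)²) + β` with `c = √2/e^(−1/2)`, so the extremum over
`x` equals `α` exactly (at `x = 1/(w√2)`). `α` carries the sign of the bias
(attraction positive); `w` is constrained positive so the sign lives in `α`
alone. The deterministic reference fitter profiles out the linear parameters
`(α, β)` in closed form and searches `w` on a log grid followed by bounded
scalar refinement; it is exact on noiseless data and serves as the
independent oracle for the Bayesian back-end in the tests.

## Hierarchical model

Bin means are modeled as Gaussian around the DoG prediction:

    y_ijb ~ Normal( α_ij·k(x_b; w_ij) + β_ij , σ_j² )
    α_ij ~ Normal( α_i + α_j , δ² )
    log w_ij ~ Normal( log w_j , τ_w² ),   β_ij ~ Normal( β_j , τ_b² )

Participants `i` are random effects, report types `j` fixed effects, and
`δ²` is the participant-by-condition interaction variance. The four-level
variant indexes columns by report type × movement time point (20 nodes at
5% steps); the code treats both cases uniformly as a row × column cell grid.
The model is fit to condition-level means, not trials: the condition mean is
the quantity the DoG is defined on, and it keeps the likelihood Gaussian.

The residual scale is per column (`σ_j`), not shared. A visible-target
matching task and a delayed memory report differ in trial noise by a factor
of ~3, and trajectory deviations grow with radius over movement time; a
single shared σ both inflates the precise columns' uncertainty and deflates
the noisy ones'.

### Priors

Defaults (degrees; for pixel-valued trajectory statistics all
amplitude-like scales are multiplied by 5 via `Priors.scaled`):

| parameter | prior | default |
|---|---|---|
| α_i, α_j | Normal(0, s²) | s = 10° |
| β_j | Normal(0, s²) | s = 5° |
| δ, σ_j, τ_b | HalfNormal(s) | s = 5°, 5°, 2° |
| log w_j | Normal(log 0.02, 0.3²), support w ∈ [0.005, 0.04] | |
| log w_ij | Normal(log w_j, τ_w²), τ_w ~ HalfNormal(0.2) | |

The width prior is deliberately informative. With a diffuse width prior the
posterior acquires a spurious "narrow-spike" mode: for large `w` the kernel
`k(x; w)` is nearly zero at every 36°-spaced bin, the amplitude becomes
unidentified, `δ` inflates to absorb it, and the Occam factor of the
marginal likelihood then *favors* the inert kernel — a self-reinforcing
ratchet that we observed capturing entire chains and destroying the
amplitude estimates. The hard support keeps the curve's peak between 17.7°
and 141°, i.e. resolvable by a design that samples `x` every 36° over ±180°;
curves outside that range are not distinguishable from noise in this design
regardless of the prior.

### Sampler

The model is conditionally linear-Gaussian, which the sampler exploits
(blocked Gibbs with Metropolis and slice components; chains independent and
seeded):

1. **Widths**: random-walk Metropolis on `log w_ij` with `(α_ij, β_ij)`
   integrated out analytically (2×2 Woodbury identity), plus a column-level
   group move that shifts a column's widths and their mean jointly. The
   collapse makes the width update immune to the amplitude funnel; the group
   move lets the column level mix directly.
2. **Amplitudes/intercepts**: exact joint bivariate-Gaussian draw per cell,
   followed by conjugate draws of `α_i`, `α_j`, `β_j`, an exact recentering
   draw along the flat `α_i + α_j` direction, and column-translation
   Metropolis moves (cells + fixed effect together) so that small-`δ`
   regimes mix at the data's precision rather than by O(δ) increments.
3. **Scales**: univariate slice sampling of `σ_j`, `δ`, `τ_w`, `τ_b` on the
   log scale, plus an interweaving (non-centered rescaling) Metropolis move
   for `δ` to break the centered parameterization's funnel.

Proposal steps adapt toward 44% acceptance during warm-up only. The default
sizes are 12,000 warm-up / 12,000 retained draws for the three-level model
and 2,000/2,000 for the four-level one; both totals are split evenly over 4
chains and pooled for summaries. Convergence is monitored with split-R̂
(classic between/within formula, each chain halved) on every
population-level parameter; R̂ > 1.05 triggers a warning but still returns
results, keeping failed fits inspectable. The sorted-window HDI and the
split-R̂ implementations are cross-checked against arviz in the test suite.
The headline per-report amplitude is the participant-marginalized mean of
the `α_ij` draws — the population-level posterior matrix (draws ×
participants × report types, × time points for the four-level model) is
exposed directly, with xarray export for named dimensions.

## Trajectory statistics

Movement onset is the first sample strictly more than 10 px from the start;
paths that never cross the threshold are excluded from trajectory analyses
(their trials remain in the error analyses). The path is linearly
interpolated onto a 101-point grid over [onset, click] (the 5%-step nodes
are embedded exactly), rotated rigidly so the target direction points up,
and the rotated x-coordinate `h` (positive = clockwise of target, matching
the error sign) is re-anchored so `h(0) = 0` at the onset point.

AUC is the trapezoid integral of `h` over normalized time on [0, 1],
reported in px·(unit normalized time) (a configurable scale factor converts
to other time conventions). The endpoint-excluded variant integrates
`h(t) − t·h(1)` — the unique linear detrend that zeroes the endpoint while
preserving `h(0) = 0` — so `AUC_with − AUC_without = h(1)/2` holds exactly
for every trajectory, a relation asserted in the tests. Deviation profiles
take `h` at the 20 nodes 5%…100%; cell means feed the four-level model. The
movement-onset median split is per participant × report type; trials at or
below the median go to the early set (deterministic tie-break), and cells
without both halves are flagged.

## Synthetic data generator

The generator emulates the full study design: 20 participants, 150
perceptual trials and 400 WM trials each (consolidation + retrieval reports
per WM trial sharing one target sequence), 36°-step relative-color
manipulation in shuffled balanced blocks, one random-condition trial per
ten-trial window, von Mises report errors whose mean follows the DoG of
`x`, log-normal movement-onset latencies (median 300 ms, σ = 0.4), and
cursor paths that move radially outward while their angular bias follows a
time-varying DoG amplitude before homing linearly onto the trial's recorded
response (so click = response by construction).

Generating truth: α = (−0.8°, +1.6°, +6.2°) for (perceptual, consolidation,
retrieval), w = 0.02/°, β = 0. Report noise is von Mises with per-report
concentrations κ = (250, 40, 20), i.e. circular SDs ≈ (3.6°, 9.1°, 12.8°):
a visible-target matching response is limited mainly by click precision,
and memory reports degrade with consolidation and retention demands. These
concentrations put the population-level posterior precision of α in the
regime the analyses are designed for (HDI widths of order 1°at n = 20).

Within-movement bias profiles are two scaled logistic ramps (a decaying
early component and a rising late component whose asymptote equals the
report-level α, so path and click are mutually consistent):

* perceptual — early −4.0°, late −0.8°: repulsion throughout, stronger
  early, giving a negative path-only AUC;
* consolidation — early −3.0°, late +1.6°: the repulsion-to-attraction
  crossover, and hence the endpoint dissociation (endpoint-included AUC
  positive, endpoint-excluded negative);
* retrieval — early +9.0°, late +6.2°: strong attraction with an early
  mnemonic overshoot, giving positive AUCs in both variants.

Consolidation movements that start after the median onset latency use a
profile whose attraction engages from the start (no early repulsion),
producing the crossover only in the early-onset half of the median split.
Motor noise is white 2-px jitter on intermediate samples.

What the generator does **not** emulate, and what passing tests therefore do
not show about real data: no guess/swap mixture in report errors
(single-item displays; extension point in `simulate_errors`), no categorical
color-space structure, no true between-participant variability in α — all
participants share the generating amplitudes, so cross-report correlations
of posterior-mean amplitudes on synthetic data reflect hierarchical
shrinkage through the shared participant effect, not individual
differences; they are reported for pipeline completeness, not as a recovery
check — and no velocity structure or submovement corrections in the cursor
paths.

## Numerical choices

* Signed offsets live in (−180°, +180°]; exactly opposite colors map to
  +180°. Zero-resultant circular means raise instead of returning an
  arbitrary angle.
* Non-random trials whose `x` is more than 1° off the 36° grid raise a
  data-integrity error rather than being silently re-binned.
* Empty condition cells raise with an explicit cell list; they are never
  silently dropped.
* The LS fitter's width search is log-spaced on [0.002, 0.2]/° with 200
  nodes plus bounded refinement; deterministic given inputs.
* Pipeline outputs are byte-identical across reruns with the same seed and
  configuration (the provenance hash excludes the output directory).

## Problem sizes used in the checks

The test suite runs reduced-scale fits (2 chains, a few hundred to ~1,200
retained draws; 4–8 participants) for speed, plus one full-scale
three-level fit on the default 20-participant simulation to verify R̂ ≤ 1.05
at the standard sampler sizes. Parameter-recovery calibration uses 20
simulate→fit repetitions at 8 participants. `scripts/acceptance.py` runs
the complete pipeline once at full scale (20 participants, default draw
counts).

## Known limitations

* The hierarchical fit operates on condition means with Gaussian residuals;
  trial-level (von Mises) likelihoods and mixture components are out of
  scope.
* Alignment of the bias to the previous *response* rather than the previous
  stimulus is not implemented (extension point in `assign_condition`).
* The four-level model shares one interaction variance `δ²` across all
  report × time columns; with strongly heteroscedastic cells a few
  column-level parameters can sit marginally above R̂ = 1.05 at the default
  (short) four-level chain lengths — raise `n_warmup`/`n_samples` when that
  matters.
* Time normalization is linear in clock time between onset and click;
  velocity-based renormalization is not attempted.
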