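# serialbias

Analysis tools for **serial dependence** in continuous color reports and
mouse-cursor trajectories: how the color reported on the current trial is
biased toward (attraction) or away from (repulsion) the color shown on the
previous trial, and how that bias evolves across perception, working-memory
(WM) consolidation, and retrieval — down to the moment-by-moment path of the
response movement.

The package is written for visual-psychophysics and working-memory
researchers running continuous-report ("delayed estimation") color tasks
with mouse responses. It provides

* circular statistics on the 360° color wheel (signed wrapping, circular
  means, condition binning with the ±180° edge synthesis),
* the derivative-of-Gaussian (DoG) serial-bias curve and a deterministic
  least-squares fitter,
* a hierarchical Bayesian DoG model (participants as random effects, report
  types — and optionally movement time points — as fixed effects), sampled
  with an in-package blocked Gibbs/Metropolis MCMC with split-R̂ and HDI
  diagnostics,
* mouse-trajectory preprocessing (movement-onset detection, time
  normalization, rotation to the target axis) and the trajectory bias
  statistics: AUC with/without endpoint bias and time-resolved horizontal
  deviation profiles with a movement-onset median split,
* a synthetic-experiment generator with known ground truth, so the whole
  pipeline is testable offline,
* a CLI (`serialbias simulate | fit-errors | fit-trajectories | run-all |
  report`) and an end-to-end pipeline runner.

## The model

The response error `y` (reported minus true color, degrees, positive =
clockwise) as a function of the previous trial's relative color `x`
(previous minus current target, degrees) is modeled by the first derivative
of a Gaussian:

```
y(x) = α · w·x · c · exp(−(w·x)²) + β,     c = √2 / e^(−1/2)
```

`α` (degrees) is the signed peak bias — positive values mean attraction
toward the previous color, negative repulsion away from it; `w`
(1/degrees) scales the curve's width (peak at `x = 1/(w√2)`); `β` absorbs
any condition-independent bias; `c` normalizes the curve so its extremum
equals `α` exactly.

Circular mean errors are computed per participant × report type on the nine
relative-color conditions −144°:36°:+144°, the two edges are averaged into a
synthesized ±180° bin (ten conditions total), and the bin means are fit
hierarchically:

```
y_ijb ~ Normal( α_ij·k(x_b; w_ij) + β_ij , σ_j² )
α_ij  ~ Normal( α_i + α_j , δ² )
```

with participant effects `α_i`, report-type effects `α_j`, and
participant-by-condition interaction variance `δ²`. The same model fits
trajectory AUCs, and a four-level variant adds 20 movement time points
(every 5% from movement onset to the click). Headline amplitudes are the
participant-marginalized posterior means with 95% highest-density intervals.

## Worked example

```python
import serialbias as sb

cfg = sb.SimConfig(n_participants=8, include_trajectories=False, seed=7)
dataset = sb.simulate_experiment(cfg)
summaries = sb.prepare_condition_summaries(dataset.trials)
spec = sb.HierarchicalSpec(levels=3, n_chains=2, n_warmup=1000,
                           n_samples=1000, seed=7)
posterior, diagnostics = sb.fit_hbm3(summaries, spec)
print(sb.posterior_summary(posterior, diagnostics).round(3).to_string(index=False))
```

prints

```
  report_type   mean  hdi_low  hdi_high           verdict  rhat
   perceptual -0.743   -1.514    -0.093 credibly negative 1.015
consolidation  1.835    0.761     3.019 credibly positive 1.032
    retrieval  6.169    5.106     7.056 credibly positive 1.000
```

The generator's true amplitudes were −0.8° (perceptual), +1.6°
(consolidation), and +6.2° (retrieval): a repulsive perceptual bias whose
95% HDI excludes zero, and attractive WM biases that grow from consolidation
to retrieval — each recovered within its credible interval. The same
estimator fits trajectory AUCs (`fit_hbm3(..., value_col="auc_with")`) and
time-resolved deviation profiles (`fit_hbm4`), where consolidation reports
show the signature dissociation: attraction at the endpoint but repulsion
along the movement path early on.

The equivalent shell command is `serialbias run-all --outdir results/ --fast`.

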