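# stroopdmc

Simulation, fitting, and inference tools for conflict-task diffusion
modelling of Stroop experiments:

- **dmc_core** — the diffusion model for conflict tasks: a constant
  controlled drift superimposed with a gamma-shaped automatic drift
  (amplitude ζ, shape α, scale τ, peak at `t_max = (α−1)τ`), absorbing
  boundaries at ±a, and a Normal(Ter, sr) residual time. Euler simulation
  (dt = 1 ms, σ = 4) with a continuity-corrected boundary so the ζ = 0 case
  matches the analytic constant-drift first-passage law.
- **gof_fit** — reduction of RT/accuracy data to quantile-bin multinomials,
  the G² goodness-of-fit statistic, and multi-restart Nelder-Mead fitting
  with common random numbers (paper-scale settings: 50,000 simulated
  observations per congruency per evaluation, 250 iterations, 30 restarts;
  desk-scale defaults: 5,000 / 100 / 5).
- **behavior** — session CSV loading and validation, congruency-sequence
  annotation, error/post-error exclusions, Stroop / Gratton effect tables,
  and sham-vs-active effect deltas.
- **stats_tests** — paired Fisher-Pitman Monte-Carlo permutation test,
  maxT-adjusted multivariate Kruskal-Wallis permutation test, and
  Bonferroni-Holm correction.
- **synthetic_data** — a complete synthetic Stroop session generator
  (balanced two-button stimulus sequences, chi-squared ISIs on
  [0.3, 0.7] s with mean 0.5 s, adaptive practice phase, configurable
  conflict-adaptation and stimulation effects).
- **recovery** — parameter-recovery studies (simulate at known parameters,
  refit, grade per-parameter recoverability).
- **cli** — the `stroopdmc` command-line pipeline.

## Quick start

```python
import stroopdmc as sd

params = sd.DMCParams(a=85, mu_c=0.5, zeta=20, alpha=2, tau=50, ter=300, sr=30)
res = sd.simulate_decisions(params, "incongruent", sd.SimConfig(n_trials=10_000, seed=1))
print(res.rt.mean(), res.correct.mean())

session = sd.synthetic_data.simulate_session(params, "sham", seed=1)
data = sd.ObservedSummary.from_trials(session[session["phase"] == "main"])
fit = sd.fit_dataset(data, sd.FitConfig(), seed=1)
print(fit.best_params, fit.g2)
```

## Command line

```sh
stroopdmc generate --subjects 12 --conditions sham,6hz --seed 1 --out data/
stroopdmc effects  --input data/sessions.csv --out effects.csv
stroopdmc fit      --input data/sessions.csv --n-sim 5000 --restarts 5 --seed 1 --out fits
stroopdmc permtest --input fits_params.csv --design paired2 --n-perm 10000 --seed 1 --out tests.csv
stroopdmc recover  --datasets 20 --trials 300 --seed 1 --out recovery/
stroopdmc run      --config pipeline.yaml --seed 1 --out out/
```

`--paper-scale` switches `fit`, `recover`, and `run` to the published
fitting settings (50,000 / 250 / 30); expect long runtimes.

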