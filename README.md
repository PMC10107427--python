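# camprox

Temporal-proximity analysis of predator–prey interactions from camera-trap
records.

Camera traps watch fixed points in space and record time-stamped passages of
every larger terrestrial animal — an Eulerian alternative to GPS collars for
studying whether **prey avoid places a predator has just visited** and
whether **predators seek out places prey have just visited**. `camprox`
implements that analysis as a tested, reusable pipeline:

1. **Intervals.** For each passage of an *initiator* (predator for the
   avoidance hypothesis, prey for the tracking hypothesis), measure the time
   until the next passage of the *event* species at the same camera.
   Intervals interrupted by a nontarget species (or a second initiator) are
   right-censored as competing events; intervals cut off by camera failure or
   pickup are right-censored at the deployment end; intervals longer than a
   cutoff (default 3 days) are omitted.
2. **Survival model.** The interval durations t with censoring indicators are
   fitted by maximum likelihood to a Weibull model, S(t) = exp(−(t/λ)ᵏ),
   with shape k and scale λ in hours. The scalar test statistic is the
   *constant hazard rate* 1/λ (the exponential-equivalent per-hour rate), and
   the median λ·(ln 2)^(1/k) is reported for interpretation.
3. **Permutation null.** Within each camera location, calendar dates are
   shuffled among observations while every record keeps its own species and
   time of day — preserving local abundance, seasonality and diel activity
   while destroying fine-scale temporal association. Each of the (default
   999) permuted datasets is pushed through the same interval construction
   and Weibull fit; the empirical p-value is
   p = (1 + #{null hazards at least as extreme}) / (1 + n), one-sided:
   avoidance predicts a hazard *below* the null, tracking a hazard *above* it.
4. **Diel activity.** Circular (von Mises) kernel densities of times-of-day
   with bootstrap envelopes verify that predator and prey activity overlap
   enough for the question to be meaningful.

Because the motivating field dataset is not publicly archived, the package
ships a first-class synthetic community generator: an inhomogeneous marked
Poisson process with species-specific diel activity, camera sessions and
failures, and *plantable* ground-truth avoidance/tracking effects (a
multiplicative rate modifier θ active for a window w after each trigger
passage), simulated exactly by chronological thinning. Every downstream
stage is validated against it.

## Worked example

```python
from camprox import TemporalProximity, AnalysisSpec
from camprox.simulate import bci_like_config, default_interactions, simulate_community

cfg = bci_like_config(seed=1, interactions=default_interactions())
obs, dep, truth = simulate_community(cfg)          # 30 cameras, ~9 months
res = TemporalProximity(obs, dep, AnalysisSpec.predator_avoidance()).fit(
    n_reps=199, seed=1
)
print(res.summary())
```

```
Temporal proximity analysis
================================================================
analysis:            avoidance
initiator -> event:  predator -> prey
competing roles:     ['nontarget', 'predator']
ignored roles:       -
interval cutoff:     72 h
----------------------------------------------------------------
initiator passages:  480
intervals stored:    479  (events 460, competing-censored 16, camera-censored 3)
omitted:             1 over cutoff, 0 zero-duration
----------------------------------------------------------------
Weibull fit (right-censored MLE)
  shape k:           1.2734
  scale lambda:      13.5949 h
  constant hazard:   0.073557 / h  (= 1/lambda)
  median time:       10.1948 h
  log likelihood:    -1612.866
  converged:         True
----------------------------------------------------------------
Permutation null (199 reps, seed 1, 0 failed)
  null hazard:       0.113695 / h (sd 0.005094)
  null median:       6.2775 h +/- 0.0222 (MC error)
  direction:         less (one-sided, hazard)
  empirical p:       0.0050
  p (median stat):   0.0050
```

The simulated community plants a halving of prey intensity for 12 h after
each predator passage (θ = 0.5). The analysis recovers it: the observed
median predator→prey interval (10.19 h) is well above the permutation-null
median (6.28 h), and the observed constant hazard falls below all 199 null
hazards (p = 0.005, one-sided "less") — the avoidance signature. With
`AnalysisSpec.prey_tracking()` the same data yield the tracking signature
(observed median below the null, small p in direction "greater") for the
planted predator attraction. `res.plot_survival()` and
`res.plot_null_hazards()` draw the observed survival curve over the spray of
null curves and the null hazard histogram with the observed value marked.

The full pipeline — six preset robustness variants (3-day vs 7-day cutoff,
prey-tracking with/without prey–prey competing events, expanded predator
set), the diel-overlap gate and a machine-readable report — runs from a
single config:

```bash
camprox simulate --seed 1 --out data/          # synthetic tables + truth record
camprox run --config run.yaml --out results/   # report.json + per-variant sidecars
camprox report --in results/                   # re-render the summary
```

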