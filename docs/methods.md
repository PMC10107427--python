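# Methods

## The model

`camprox` treats each passage of an animal past a fixed camera as a point on
a per-location timeline and asks a time-to-event question in both directions:
after a predator passes, how long until the next prey (predator avoidance —
prey should take *longer* than chance); after a prey passes, how long until
the next predator (prey tracking — predators should arrive *sooner* than
chance).

### Interval construction and censoring

An analysis is specified by four role sets: the *initiator* opens an
interval, the *event* role closes it as an observed event, *competing* roles
close it as right-censored (a nontarget animal walking through plausibly
disrupts the interaction being timed), and *ignored* roles are skipped
entirely. Scanning is strictly forward within one deployment session:
intervals never span a camera pickup/redeploy boundary, and an interval
still open when the session ends is right-censored at the session's
effective end (for failed cameras, the last 12-h time-lapse mark, which is
how failure times are inferred in the field). Intervals longer than the
cutoff (72 h by default; 168 h as a robustness variant) are omitted and
counted, on the argument that animals three days apart are not interacting;
zero-length intervals from simultaneous triggers are omitted and counted
separately because the Weibull likelihood degenerates at t = 0. Every
initiator passage therefore maps to exactly one of {stored interval, omitted
over cutoff, omitted zero-duration} — an accounting identity asserted at run
time.

Two deliberate rule choices, both exposed as configuration:

- **Avoidance** (initiator predator → event prey): a second predator before
  any prey *censors* the open interval, i.e. same-role repeats are treated
  as interruptions like nontargets.
- **Tracking, headline variant** (initiator prey → event predator):
  intervening prey neither close nor censor, so every prey passage opens an
  interval and one predator may close several overlapping intervals. This
  makes intervals positively correlated (they share a closing event), which
  the permutation test absorbs — the null is built by re-running the
  identical construction on permuted data — but a naive analytic SE would
  not. The alternative rule (prey–prey passages as competing events) is one
  flag away (`compete_prey=True`) and is one of the preset variants.
  Whether the analysis should open an interval at every prey passage or
  only at the last prey before each predator is genuinely open; we implement
  the former as the default and regard the choice as part of the test
  statistic's definition — the permutation null uses the same choice, so the
  p-value remains valid either way.

### The Weibull fit and the "constant hazard rate"

Durations (hours) with right-censoring indicators are fitted to
S(t) = exp(−(t/λ)ᵏ) by maximum likelihood. Both censoring causes (competing
event, camera end) enter identically as right censoring; competing risks are
*not* modelled as a multi-state likelihood — the censored-interval question
("at least this long with no event") is exactly what the survival term
encodes.

Optimization is on (log λ, log k) with the analytic gradient: damped Newton
(finite-difference Hessian with backtracking) from the moment estimator of
the uncensored log durations — sd(log T) = π/(k√6), E[log T] = log λ − γ/k —
resolves virtually every fit in a handful of iterations; a BFGS multi-start
fallback (k ∈ {0.5, 1, 2}) handles the remainder. Convergence means gradient
norm < 1e-8 on the log scale, and non-convergence is flagged, never silent.
With the shape fixed, the scale has the closed-form profile solution
λᵏ = Σtᵢᵏ/d; at k = 1 this is the censored exponential (hazard = events /
exposure), which serves as an independent oracle in the tests.

The permutation statistic is the **constant hazard rate, defined as 1/λ**.
A Weibull hazard is constant only at k = 1, and no unique "constant hazard"
exists for k ≠ 1; 1/λ is the exponential-equivalent rate (exp(−intercept)
in the accelerated-failure-time parameterization) and is the scale-free
summary the fit provides. For any fixed shape it orders datasets exactly
oppositely to the median λ(ln 2)^(1/k), so the one-sided permutation
p-value is insensitive to the choice; the Results object reports a
median-statistic p alongside the hazard-statistic p as a standing check.

### The permutation null

Within each location, calendar dates are shuffled among observations; each
record keeps its own (species, time-of-day) pair. This preserves, exactly:
the per-location date multiset (local + seasonal abundance), per-location
species composition, and every record's diel timing — and destroys only the
fine-scale temporal order between species. Deployments, and hence the
camera-censoring boundaries, are never permuted. Each replicate re-runs the
full interval construction and Weibull fit; replicates that cannot be fitted
(no events, non-convergence) are counted, and a result with ≥ 5% failed
replicates is flagged unusable.

A reassigned (date, time-of-day) pair can fall outside deployment coverage
when a coverage boundary cuts through a day (a camera that died at noon):
the offending location — and only it — is re-shuffled, up to 1000 attempts,
after which the replicate counts as failed. Because the shuffle is
independent across locations, per-location rejection sampling draws from the
same conditional distribution as re-drawing the whole replicate, at far
lower cost. A location with many observations on a partial-coverage day can
have an accept rate of a few percent, which is why the bound is generous.

The empirical p-value uses the add-one rule p = (1 + b)/(1 + n), where b
counts null statistics at least as extreme in the pre-registered direction
(ties count against significance). This is a valid p-value under
exchangeability, is never zero, and coincides with the raw percentile at
reported precision in the extreme (b = 0, n = 999 gives p = 0.001). Default
n = 999; one-sided directions are fixed per hypothesis (avoidance: hazard
below null, "less"; tracking: above, "greater").

### Diel activity and the overlap gate

Times-of-day are smoothed on the 24-h circle with a von Mises kernel.
Kernel concentration comes from Taylor's rule of thumb,
ν = (3n κ̂² I₂(2κ̂) / (4√π I₀(κ̂)²))^(2/5), with κ̂ the ML von Mises
concentration of the sample; a fixed override exists. Densities are per
hour (uniform = 1/24) and renormalised to integrate to 1 over the cycle.
Envelopes are pointwise 2.5/97.5% percentile bootstrap (default 250
resamples) with the concentration held at the full-sample value, clipped to
contain the point estimate. For speed the empirical distribution is binned
at 3 minutes and convolved by FFT — far finer than any plug-in bandwidth.
The predator-vs-pooled-prey overlap coefficient ∫min(f₁, f₂) gates the
pipeline at a default threshold of 0.25; the threshold is a pipeline sanity
gate of our choosing, not an estimate of anything, and prey are pooled by
record (so common species dominate, matching how the interval analysis
weights passages).

## The synthetic community

Each species at each camera is an independent inhomogeneous Poisson stream
with per-hour intensity

λ_s(t) = base_rate_s/24 × diel_s(tod(t)) × Π modifier_i(t),

where diel_s is a von Mises mixture normalised to mean 1 over the cycle and
each interaction modifier multiplies the responder role's intensity by θ
while t is within w hours of the *most recent* trigger-role passage (step
decay; an exponential decay 1 + (θ−1)e^(−Δt/w) is also available). Using
only the most recent trigger keeps θ interpretable and matches the renewal
logic of the interval analysis. Simulation is exact chronological thinning
of the marked process against the dominating rate base × max-diel ×
max(θ, 1), so mutual interactions (prey avoiding predators while predators
track prey) need no approximation. Sessions run back-to-back per location;
with probability `failure_prob` a session fails at a uniform time and its
recorded end snaps to the preceding 12-h time-lapse mark, with observations
truncated there.

The shipped "bci-like" scenario (also in `camprox/data/bci_like.yaml`):
30 locations, three 90-day sessions, failure probability 0.1 per session,
one mostly nocturnal predator at 0.03 passages/camera/day, five mostly
diurnal prey at 2.0/0.5/0.25/0.1/0.05 per day, one nontarget at 0.005 per
day. This echoes the rank-abundance shape of a Neotropical moist-forest
camera grid — a predator roughly 100× rarer than the prey pool, one
dominant diurnal rodent — at desk scale; it is not a numeric match to any
census. Default planted effects: avoidance θ = 0.5 for w = 12 h
(predator→prey), tracking θ = 4 for w = 6 h (prey→predator). The tracking
window is deliberately shorter than the typical gap between prey passages
(~8 h at these rates): a window much longer than that gap would keep the
responder inside a window almost always, raising its overall rate without
creating the temporal structure the test detects.

What the simulator does *not* emulate: spatial structure and home ranges
(locations are independent), individual identity and behavioural
heterogeneity, double-triggers from lingering animals, seasonal rate trends,
and clock drift. Passing tests therefore demonstrate correctness of the
machinery and calibration of the test under the stated generative
assumptions — not that real communities satisfy those assumptions.

## Operating characteristics (recomputed by the test suite and
`scripts/acceptance.py`, never asserted from memory)

- Closed-form agreement of the fixed-shape fit with events/exposure.
- Parameter recovery on 5,000 censored Weibull draws (bias < 3%).
- Record-for-record agreement of the interval builder with an independent
  brute-force scan on 1,000 random streams.
- Conservation laws of the permutation under 100 random datasets.
- Type-I error of both one-sided tests on 200 null communities × 199
  permutations (nominal 5%, accepted band 2–10%).
- Directional power against planted effects and monotonicity of the
  rejection rate in θ across {0.25, 0.5, 1, 2, 4}.
- Byte-identical reports for identical configuration + seed.

The calibration harness uses a smaller community (10 cameras, 60 days,
predator at 0.2/day) than the headline scenario so that hundreds of
independent replicates are affordable; the predator is made less rare purely
to keep ~120 avoidance intervals per replicate, a regime where every
permutation refit is stable.

## Numerical and engineering choices

- Timestamps are stored to 1 s; statistics use fractional hours; no
  rounding of durations.
- Simultaneous triggers are ordered by input order (camera clock resolution
  is not assumed); a closer at the identical timestamp yields a
  zero-duration interval, which is omitted and counted.
- Observations outside every deployment at their location are a hard error,
  not a silent drop: the simulator cannot produce them, so in real data they
  indicate a metadata bug.
- An optional independence filter (drop same-species records at one camera
  within m minutes, default off, m = 1) approximates the manual removal of
  double observations from lingering animals; it is mechanical and not
  claimed equivalent to expert vetting.
- Per-variant permutation seeds are derived from SHA-256 of (master seed,
  variant name), so adding a variant never changes another's numbers.
- The report body contains no timestamps and serialises with sorted keys,
  making byte-level reproducibility a testable contract.
- n_reps defaults to 999; large von Mises concentrations use exponentially
  scaled Bessel functions throughout to avoid overflow.

## Known limitations

- The tracking variant without prey–prey competing events produces
  correlated intervals (shared closing predator); only permutation-based
  inference is offered for it, by design.
- The planted-effect self-check (`planted_effect_summary`) estimates θ
  without confounding only for flat-diel responders; with diel structure the
  inside/outside-window rate ratio mixes the interaction with time-of-day.
- The permutation preserves date multisets, not within-day order; data in
  which interactions operate at multi-day scales would need a coarser
  (e.g. block) permutation, which is out of scope.
- Covariates (season, habitat), frailty terms and non-Weibull duration
  families are out of scope; the exponential is available only as an oracle.
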