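# Methods

## Task geometry and the path-length cost

The workspace is a 106 × 200 mm rectangle; movements go from a start point at
the origin to a checkpoint at (0, 140) mm, past a 30 mm wide × 10 mm high
obstacle centred vertically at 70 mm. Obstacle centres occupy 29 equally
spaced horizontal positions spanning −34.2 … +34.2 mm (spacing 68.4/28 ≈
2.443 mm); for the statistical models positions are linearly re-coded so the
extremes map to ±0.9.

The cost of passing on a given side is derived from the shortest parabola
through both endpoints that clears the obstacle on that side. The family is
fixed to x(y) = a·y·(y − 140): endpoints pinned, axis horizontal, arc length
strictly increasing in |a|. Over the obstacle's vertical band [65, 75] mm the
magnitude of x is smallest at the band's corner rows, so corner clearance is
the binding constraint and the minimal |a| has a closed form; when the
straight line already passes on the requested side (obstacle edge at or
beyond x = 0, ties counting as passable) the path is the 140 mm line itself.
Clearance is evaluated against the full rectangle (not its centre line), with
non-strict inequality for the idealized point path. Arc length is computed by
adaptive quadrature at 1e−9 relative tolerance, and the normalized cost is
c = 140 / path length ∈ (0, 1], so longer detours give lower valuation. An
independent brute-force check (dense scan plus bisection over the
coefficient, numerical arc length) agrees with the closed-form pipeline to
better than 1e−6 relative across all 29 positions × 2 sides.

Out of scope: the checkpoint-to-target leg, cursor/stylus contact radii, and
alternative cost functionals (jerk, torque, endpoint variance); these co-vary
with path length here and would not change the emergence of hysteresis.

## Generative choice model

Action values combine scaled cost and scaled accumulated bias,
V_i = s_c·c_i + s_b·b_i; the left action is chosen with softmax probability
p_L = e^{V_L}/(e^{V_L}+e^{V_R}) (computed max-subtracted for overflow
safety). After each trial the biases move by a delta rule with rate
r ∈ [0, 1]: toward 1 for a selected successful action, toward 0 in every
other case (unselected action, failed trial, or trial failed before any
selection). Biases start at zero and therefore remain in [0, 1].

Failure injection: each simulated trial fails outright with a per-position
probability before any side is sampled, in which case no side is recorded and
both biases decay. Bias trajectories run continuously across the three
experimental blocks (participants experience them as one uninterrupted run);
a per-block reset mode exists but is off by default. Example, practice and
baseline trials are simulated from the same value rule but excluded from bias
accumulation by default (configurable), and excluded from the likelihood.

## Synthetic cohorts

One session = 4 example + 6 practice + 9 baseline trials (obstacle central)
followed by 87 experimental trials: three 29-trial blocks (rightwards
ascending sweep, leftwards descending sweep, random shuffle), block order
randomized per participant — 106 trials in all. Default cohorts share one
parameter set per experiment, matching the fitting model; optional Gaussian
between-participant jitter exists for robustness checks only. The default
generating parameters are the fitted posterior means per experiment:
(39.26, 2.69, 0.32), (41.96, 1.09, 0.43) and (37.63, 1.87, 0.35) for
(cost scaler, bias scaler, bias rate). The study's empirical per-position
error probabilities are not published, so the default error table is a flat
5% per trial (with an optional U-shaped component toward the screen edges);
this is a placeholder for the real per-position profile.

Stylus traces for the kinematic pipeline hold at the start for a lognormal
reaction time (median 400 ms, σ = 0.25 — chosen to sit at the observed
~400 ms scale), then traverse the minimal parabola with a minimum-jerk time
course reaching the checkpoint in 400 ms, sampled at 100 Hz with additive
Gaussian position noise (default SD 0.3 mm). The delayed-release variant adds
its 1.5 s enforced hold before the reaction-time clock. The recorded
ground-truth onset is the first time the noiseless tangential speed exceeds
the 50 mm/s detection criterion. What the generator does *not* emulate:
condition-dependent RT effects (no RT model is part of the generative
account), target-phase behaviour, memory/colour errors beyond the aggregate
failure rate, and any drift in parameters over the session. Tests passing on
these cohorts therefore validate the machinery and the emergent choice
phenomena, not RT predictions.

## Likelihood and Bayesian inference

For each participant the bias pair is propagated deterministically through
the observed sequence of choices and outcomes (it depends only on the data
and r), and every trial with an observed side contributes the Bernoulli
log-probability of that side; no-passage trials contribute nothing but still
decay the biases. The implementation is vectorized across participants and
verified against a scalar step-by-step oracle to 1e−10.

Priors: s_c, s_b ~ Normal(0, sd 25) — scale-matched to a cost scaler near 40;
widening them does not move the posteriors — and r ~ Normal(0.5, 0.2)
truncated to [0, 1] (enforced by rejection at the posterior bound, no
transform). Sampling uses the affine-invariant ensemble sampler (emcee):
walkers double as chains for the Gelman–Rubin statistic and effective sample
size (arviz), initialized in a small ball around a Nelder–Mead MAP estimate.
A fit is flagged non-converged when any R-hat reaches 1.1; a collapsed
acceptance fraction raises an error rather than returning silently. One
parameter set is fitted per experiment (the experiments are fitted
separately), with per-participant bias trajectories. The default profile is
16 walkers × (600–800 warm-up + 700–800 retained) draws, sized for synthetic
cohorts of ~16–40 participants on one CPU; the study-scale profile
(8 × 5000 + 5000) is available via `FitConfig.full_scale()`.

HDIs use the sorted-window algorithm (narrowest window of ⌈0.95 n⌉ order
statistics), cross-checked against an exhaustive window scan.
Between-experiment contrasts subtract draw sets elementwise after truncation
to a common length (or resampling with replacement when a generator is
supplied).

Posterior-predictive ribbons: for each sampled posterior draw a full dataset
is simulated over per-participant designs with the error table, summarized by
a pooled logistic fit of P(right) on coded position per condition (or per
prime condition in the random block), evaluated at the 29 positions; the
ribbon is the pointwise min/max over draws. Requests beyond the available
draws sample with replacement. The logistic fits use a large-C (1e6) L2
penalty — effectively maximum likelihood, with the small ridge keeping
estimates finite under complete separation; single-class cells saturate to
0/1. Observed data are summarized by the same logistic fit before coverage
comparisons, mirroring how the empirical curves are drawn.

## Behavioral statistics

Choice preprocessing removes trials without a detected passage, attaches
coded positions, and computes within-block prime (previous trial's side;
undefined on block-initial trials and after no-passage trials) and
switch/repeat flags.

The hysteresis model is a mixed-effect logistic regression of going right on
zero-centred position × condition (reference: random) × experiment
(reference: 1) with a participant random intercept. No frequentist GLMM
exists in the installed Python stack, so marginal maximum likelihood is
implemented directly with adaptive Gauss–Hermite quadrature (15 nodes,
integrand re-centred at its Newton mode and curvature-scaled per group),
optimized by L-BFGS-B over (β, log σ) with Wald covariance from a
finite-difference observed-information matrix. It is validated against a
dense non-adaptive quadrature oracle (1e−3) and collapses to ordinary
logistic regression as σ → 0. Post hoc condition comparisons are linear
combinations of coefficients at coded position 0, with Wald 95% intervals and
Bonferroni–Holm step-down correction (monotonicity enforced, capped at 1).
The prime analysis fits position × prime with a participant intercept on
random-block trials; the reported effect is the LO difference at the central
position.

RT preprocessing: traces are low-pass filtered with a dual-pass second-order
Butterworth at 10 Hz (zero phase; the digital realization attenuates a 30 Hz
component below the analog squared-magnitude bound of ~1.2%), speed is taken
by central differences, onset is the strict upward 50 mm/s crossing nearest
the logged start-point exit, and RT is onset minus the stimulus onset
(standard and reduced-demand tasks) or the hold release (delayed task). The
exclusion cascade applies four rules sequentially, each on the survivors of
the previous: missing RT, RT < 100 ms, trial outside 2 SD of the
participant-condition mean, and participant-condition mean outside 2 SD of
the group mean of participant-condition means (the closest reading of the
group-level rule). RT models are linear mixed models on inverse RT (1/s),
with trial number centred on the middle trial, fitted by REML
(statsmodels MixedLM) with a participant intercept and condition (or switch)
random slopes; estimated marginal means at the middle trial are
back-transformed to ms (interval endpoints swap under the reciprocal).

## Design choices and numerical notes

- Interchange format is headered CSV (positions mm, times ms), with a
  column-mapping adapter for foreign exports; summaries are JSON; all
  randomness derives from one root seed through named SHA-256 substreams.
- Softmax ties at equal values give exactly 0.5; obstacle-edge/path ties
  count as passable; Holm ties are handled by the step-down cumulative
  maximum.
- Mixed-model estimates will not bit-match other tooling (lme4, Stan);
  comparisons elsewhere are made at interval, not bit, precision.
- Scaled-down problem sizes are used throughout the tests and the acceptance
  script (cohorts of 16–40 participants, 16 walkers, hundreds of draws,
  200-draw ribbons); they were chosen so every qualitative result is
  detectable with comfortable margins on one CPU.

## Known limitations

- The error-rate table is a placeholder (flat 5%) where the study used
  empirical per-position rates.
- The synthetic generator produces no condition-dependent RT structure, so RT
  analyses on synthetic data demonstrate the pipeline, not the RT findings.
- The GLMM supports a single random intercept (plus the RT models' condition
  slopes via MixedLM); forward random-structure selection and marginal /
  conditional R² are out of scope.
- Fitting assumes one parameter set per experiment; hierarchical
  per-participant extensions are out of scope.
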