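# motorhyst

Choice hysteresis — the tendency to repeat a recently used action even when an
alternative has become cheaper — as an *emergent* property of a decision system
that learns from the outcomes of its own actions. `motorhyst` implements the
complete analysis pipeline for an obstacle-avoidance reaching task in which
participants move a stylus from a start point to a checkpoint 140 mm away,
passing a 30 × 10 mm obstacle on the left or the right. Across three
experiments (a standard task with 152 participants, a delayed-release variant
and a reduced-demand variant with 20 each) the obstacle steps across 29
horizontal positions either sequentially (rightwards / leftwards) or in
shuffled order (random).

The package is for computational cognition / sensorimotor-control researchers
who want to simulate the task, fit the generative choice model, and run the
behavioral statistics end to end on synthetic or deposited trial tables.

## The model

Each action $i \in \{L, R\}$ has value

$$V_i = s_c\,c_i + s_b\,b_i$$

where $c_i \in (0,1]$ is the normalized path cost — 140 mm divided by the arc
length of the shortest parabola from start to checkpoint that clears the
obstacle on side $i$ — and $b_i \in [0,1]$ is a bias accumulated over trials.
The left action is selected with softmax probability

$$p_L = \frac{e^{V_L}}{e^{V_L} + e^{V_R}},$$

and after each trial the biases update by a delta rule with bias rate $r$:

$$b_i \leftarrow b_i + r\,(1 - b_i)$$ if $i$ was selected and succeeded, and
$b_i \leftarrow b_i + r\,(0 - b_i)$ otherwise (unselected action, failed
trial, or no selection). Biases start at 0, so they stay in $[0,1]$ for
$r \in [0,1]$. Sequential obstacle motion lets one side's bias build up, and
at the central position — where both costs are equal — that bias alone tips
the choice: hysteresis emerges without any dedicated "hysteresis mechanism".

The three parameters $(s_c, s_b, r)$ are estimated by MCMC with priors
$s_c, s_b \sim \mathcal N(0, 25)$ and $r \sim \mathcal N(0.5, 0.2)$ truncated
to $[0,1]$, summarized by posterior means and 95% highest-density intervals.
Hysteresis in the data is quantified by mixed-effect logistic regression as
the increase in log odds (LO) of passing right at the central position in the
rightwards versus the leftwards condition.

## Worked example

Simulate scaled cohorts at the fitted mean parameters, fit the model, and run
the choice statistics:

```bash
python analysis/01_simulate_cohorts.py --scale 0.2 --seed 0
python analysis/02_fit_choice_model.py --seed 0 --warmup 400 --draws 500
python analysis/04_choice_statistics.py
```

which prints (experiment 1, 30 simulated participants):

```
experiment 1:
  cost_scaler   38.518  95% HDI [ 34.103,  42.566]  R-hat 1.112
  bias_scaler    2.724  95% HDI [  2.384,   3.084]  R-hat 1.091
  bias_rate      0.293  95% HDI [  0.223,   0.362]  R-hat 1.100
...
central-position log-odds contrasts (Holm-corrected):
  exp1: rightwards - random           LO =   3.34 [  2.53,   4.15]  p = 1.04e-15
  exp1: leftwards - random            LO =  -2.31 [ -2.93,  -1.68]  p = 5.78e-13
  exp1: rightwards - leftwards        LO =   5.64 [  4.68,   6.61]  p = 3.34e-30
prime effect (random block): LO = 1.73 [1.03, 2.43]
```

The fitted posterior means recover the generating parameters (cost scaler
39.26, bias scaler 2.69, bias rate 0.32) within their HDIs; the positive
rightwards − leftwards contrast is the hysteresis effect, and the positive
prime effect shows the trial-level bias in the random block. Scripts
`03_posterior_predictive.py` and `05_rt_pipeline.py` add the
posterior-predictive ribbons and the reaction-time pipeline (Butterworth
filtering, 50 mm/s onset detection, four-rule exclusion cascade, inverse-RT
mixed models). A `motorhyst` console command exposes the same stages
(`simulate | fit | ppc | stats | rt | recover`).

## Layout

- `src/motorhyst/` — library: `geometry`, `choice_model`, `synthetic_data`,
  `inference`, `glmm`, `kinematics`, `behavior_stats`, `pipeline_io`, `cli`
- `analysis/` — numbered narrative drivers writing tables under `results/`
- `tests/` — unit, property and end-to-end suites
- `docs/methods.md` — modelling and statistical methods in detail
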