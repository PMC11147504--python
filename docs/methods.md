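# Methods

## The behavioural model being analysed

Each session is one uninterrupted run of water-jet shots by one fish.  The
shot error is the signed distance (mm) between target centre and jet
centre, projected on the airflow axis with positive = the direction the
airflow pushes the jet.  Sessions follow a schedule of phases: baseline
(no airflow), perturbation (airflow on), optionally a reversed-perturbation
phase (the fish is rotated 180° while the airflow stays fixed), and washout
(airflow off).  Phase block lengths are drawn uniformly within the design's
bounds — exp1: 5–10 / 10–15 / 5–10 trials; exp2: 5–10 / 8–12 / 15–20 / 5–10 —
so the fish cannot anticipate transitions.

## Epochs

Statistical contrasts are defined on epochs, contiguous trial groups
anchored at the perturbation events (six for exp1, nine for exp2; see
`shotadapt.epochs`).  The two-trial boundary epochs (2, 4, 5, and 7, 8 for
exp2) isolate the transient response at each transition; the "middle"
epochs (3, 6, 9) absorb the remaining trials and may be empty — a
four-trial perturbation block is entirely epochs 2 and 4, which is legal
and handled throughout (the model keeps the full epoch count with an empty
cell).  Epoch assignment requires each perturbation phase to have at least
4 trials so the boundary epochs cannot overlap; violations raise rather
than silently mislabel.

## Synthetic-data generator

The generator produces the statistical structure the analysis assumes — a
jump–decay error trajectory — not the biomechanics of the jet.  During
perturbation the mean error is `m_t = shift · (1 − λ)^t` (t = 0 on the
first perturbed trial); the internal compensation is `c_t = shift − m_t`.
Washout starts at `−α · c_last` and decays at the same rate λ.  At an exp2
reversal the next mean is `shift + c_last` (egocentric: the carried-over
correction adds to the new effect, ≈ 2× the onset jump when adaptation is
complete) or `shift − c_last` (allocentric: it cancels).  Gaussian noise is
added per trial, and each fish receives a Normal(0, `fish_effect_sd`) mean
offset shared by all its sessions, mirroring the subject term of the model.

Defaults (units mm unless noted): `perturbation_shift = 5`,
`learning_rate λ = 0.2` /trial, `baseline_sd = trial_noise_sd = 3.2`,
`aftereffect_fraction α = 0.7`, `fish_effect_sd = 1`.  They are a
calibration, not ground truth: chosen once so the simulated epoch contrasts
land in the ranges the analysis is built to resolve — onset contrast
`shift·(2−λ)/2 = 4.5` (inside 4.28–5.52), onset Cohen's d `4.5/3.2 ≈ 1.4`,
aftereffect contrast ≈ 3.3 (inside 2.65–3.99), egocentric reversal ≈ 2× the
onset.  The default cohorts mirror the study: exp1, 7 fish completing
15/15/8/7/7/2/1 sessions; exp2, 3 fish completing 15/4/8.

Randomness is counter-split: stream `(seed, fish, session)` per session and
a separate per-fish stream for offsets, so enlarging the cohort never
changes earlier fish's data, and output CSVs are byte-identical for a given
(params, seed).

What the generator does *not* emulate: session-to-session learning
("savings"), drifting baselines, outlier shots, autocorrelated noise, or
2-D error fields.  Passing tests therefore demonstrate that the estimation
machinery is correct and calibrated under the assumed generative structure,
not that real archerfish data satisfy that structure.

## Hierarchical Bayesian model

Per-trial likelihood
`error ~ N(a_baseline + a_epoch[e] + a_subject[s] + a_es[e,s], σ²)` with a
second level in which each coefficient group is normal around its own
hyper-mean and hyper-variance.  Priors: hyper-means N(0, 1000² mm²);
group precisions Gamma(0.001, 0.001); σ uniform on (0, 100) mm.  "Broad" is
deliberately vague in this tradition; these constants dominate nothing at
the millimetre scale of the data, and `prior_scale` rescales the normal SD
and the σ bound by ×10 / ×0.1 for sensitivity checks.

Sampling is a systematic-scan Gibbs sampler: every full conditional is
conjugate (normal–normal for coefficients and hyper-means, gamma for the
group precisions); the uniform-on-SD prior makes the σ conditional a
Gamma((n−1)/2, SS/2) on the precision truncated at 1/100², drawn by
rejection with an inverse-CDF fallback.  Degenerate sizes are handled
explicitly (n = 0 draws σ from its prior; group precisions that underflow
to zero are floored so variances stay finite).  Defaults: 3 chains ×
10,000 retained draws after 2,000 burn-in, no thinning; chains are
initialized overdispersed around the data moments and seeded via spawned
`SeedSequence`s, so runs are exactly reproducible.

No sum-to-zero constraints are imposed, so the individual `a` terms are
unidentified and their chains may mix arbitrarily slowly; this is expected
and visible in the diagnostics.  All inference uses the identifiable cell
means `m[e,s] = a_baseline + a_epoch[e] + a_subject[s] + a_es[e,s]` and
their contrasts, whose chains converge rapidly.  `convergence_diagnostics`
reports rank-normalized split-R̂ and ESS (via arviz) for every monitored
scalar, including the pooled per-epoch cell means; constant chains get an
explicit `zero_variance` flag instead of NaN, and R̂ > 1.01 flags a
parameter without aborting the pipeline.

Correctness is pinned by three oracles in the test suite: a collapsed
one-subject/two-epoch case with fixed variances, where the model is jointly
Gaussian and the contrast posterior has a closed form; a prior-recovery run
on empty data; and seeded parameter-recovery/coverage simulations at the
study's cohort shape.

## HDI, ROPE and effect size

`hdi` returns the shortest contiguous window of `ceil(mass·n)` order
statistics; ties go to the smallest lower endpoint, and the implementation
is required (by test) to agree exactly with an exhaustive window search.
Multimodal samples still get one contiguous interval by definition.

The ROPE rule compares the 95% HDI of a contrast with `[−h, +h]`:
credibly different if disjoint, practically equivalent if contained,
undecided otherwise.  "5% around zero" is ambiguous between a relative and
an absolute reading, so both are exposed: the default takes `h` as 5% of
the posterior-mean absolute value of the contrast under test; an absolute
halfwidth in mm can be passed instead.  Neither is asserted to be the
original rule.

Cohen's d is computed per posterior draw as the contrast divided by that
draw's residual σ — the model-consistent pooled SD, since the hierarchical
model has a single residual variance — and summarized by its own HDI.
Draws with non-positive SD are excluded and counted, never propagated as
NaN.  An empirical two-group pooled-SD variant is available for comparison
with the frequentist convention.  Contrasts are available pooled (cell-mean
difference averaged over fish) and per fish; both are reported because the
original summaries could be read either way.

## Frequentist cross-check

`error ~ C(epoch)` with a fish random intercept, REML via statsmodels
MixedLM.  The epoch factor is tested with the joint Wald statistic divided
by its degrees of freedom, referred to an F distribution with the residual
df.  η² is classical (between-epoch SS over total SS); a partial variant is
a flag, matching the two conventions in the literature.  Post hoc pairwise
comparisons run two-sample t tests on observations adjusted for the fitted
fish intercepts, Bonferroni-multiplied by the family size (the number of
declared pairs: 3 for exp1, 5 for exp2), with empirical pooled-SD Cohen's
d.  A boundary (zero-variance) or non-converged fit is flagged `singular`
with estimates still returned.  Session-within-fish nesting is deliberately
not modelled by default — the random structure follows the stated design —
and the test suite checks that Bayesian cell-mean contrasts and mixed-model
fixed-effect contrasts agree within 2 SE on shared data.

## Problem sizes and numerical choices

The replicate studies in the test suite run at reduced but honest sizes
chosen as standard practice for simulation studies of this kind: coverage
and ROPE calibration use 100 full cohorts at 3 × 2,000 retained draws
(500 burn-in) — enough that the Monte-Carlo error of a 95% coverage
estimate is ~2 points; null calibration uses 500 single-session cohorts at
3 × 800 draws; the sampler-correctness check runs the full 3 × 10,000.
The acceptance script uses 3 × 2,000 draws per cohort.  HDI inputs are
validated (≥ 2 finite samples); empty epochs yield flagged rows rather than
silent drops; all estimators validate index ranges and finiteness up front.

## Known limitations

- The generator's single-rate exponential is the simplest trajectory
  consistent with jump, plateau and aftereffect; real adaptation may be
  multi-rate, and the washout fraction α is phenomenological.
- Classical η² on mixed-model data attributes fish variance to the total;
  values are therefore conservative relative to a partial η².
- The Wald-F epoch test relies on asymptotics; at very small cohorts its
  null calibration is approximate (verified at the sizes used here).
- The relative-ROPE default makes the decision scale-free but data
  dependent; for strict preregistration use the absolute-mm mode.
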