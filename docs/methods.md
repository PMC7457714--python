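# Methods

This note documents the models, estimators and numerical choices behind
`cautionmeta`, what its synthetic-data generator does and does not
emulate, and the problem sizes its validation experiments use.

## Decision models

Both simulators describe a single accumulator X(t) between absorbing
boundaries at 0 (error) and *a* (correct), started at z = zr·a
(zr = 0.5 unless stated), with diffusion coefficient σ.  RT = decision
time + non-decision time Ter.

* **Standard diffusion**: dX = v·dt + σ·dW.  Optional trial-to-trial
  variabilities (normal drift sv, uniform Ter range st, uniform start
  range szr) are implemented but **off by default**, and the fitting path
  does not estimate them: which variabilities the original conflict-model
  fits freed is not documented in the material this package works from,
  so the simplest identifiable configuration is the default and both
  configurations are exposed.
* **Conflict model**: dX = μ(t)·dt + σ·dW with
  μ(t) = μ_c + s·dE[A(t)]/dt, s = +1/−1/0 for congruent / incongruent /
  neutral.  E[A(t)] = ζ·e^{−t/τ}·(t·e/((α−1)τ))^{α−1} is a rescaled gamma
  density: zero at t = 0 (α > 1), peak ζ at t = (α−1)τ.  With ζ = 0 the
  model is distributionally identical to the standard diffusion with
  v = μ_c (a property the tests check by KS distance).

**Units.**  Seconds, σ = 0.1, one convention everywhere; the conflict-
model literature's ms / σ = 4 / symmetric-boundary convention is accepted
through `from_dmc_convention`, which rescales evidence by
0.1/(σ·√1000) and time by 1000 (exact process equivalence; note the
boundary *separation* is twice the symmetric half-boundary).  Classic
literature values (b = 75, μ_c = 0.5/ms, ζ = 20, τ = 30 ms) map to
a ≈ 0.119, μ_c ≈ 0.40, ζ ≈ 0.016, τ = 0.03 s, which anchors the
package's defaults and random-start bounds.

**Integration.**  Euler–Maruyama, default dt = 1 ms, hard decision-time
ceiling 5 s (censored trials flagged and, where binned, classified by
which boundary the final state is nearer).  Naive discrete-time
absorption overestimates first-passage times by O(√dt); the simulators
therefore shrink both boundaries inward by the Broadie–Glasserman–Kou
continuity correction 0.5826·σ·√dt (on by default), after which the
remaining bias is O(dt) and simulated choice probabilities and mean
decision times agree with the closed-form constant-drift expressions
within Monte-Carlo error at dt = 0.5–1 ms.  The conflict model's
time-varying drift is evaluated at step midpoints, which also avoids the
t = 0 singularity of dE/dt for 1 < α < 2.

**Closed-form oracle.**  For constant drift without variabilities,
P(upper) = (1 − e^{−2vz/σ²})/(1 − e^{−2va/σ²}) and
E[T] = (a/v)·P(upper) − z/v (v = 0: P = zr, E[T] = z(a−z)/σ²).  This is
used only as a test oracle, never inside the estimator.

## Fitting procedure

Each participant × task is fit independently; sessions are pooled before
binning (two-session data are concatenated, matching how multi-session
studies are usually collapsed for model fitting).  Per design cell
(congruency × instruction block):

* correct RTs are binned at their own empirical quantiles
  [.1, .3, .5, .7, .9] (six bins);
* errors use the same cuts when the cell has ≥ 11 errors, the sparser
  cuts [.3, .5, .7] with 5–10 errors, and below 5 errors only the error
  count and the median error RT are scored.  The sparse cut list defines
  four inter-quantile intervals; a `literal_three_bins` switch ([.3, .7])
  is provided for the alternative three-interval reading, since the
  verbal description ("three bins") and the printed cut list disagree.

The objective is the multinomial deviance
G² = 2·Σ Oᵢ·ln(Oᵢ/(N·pᵢ)) over all cells, with model proportions pᵢ
estimated from `n_sim` simulated trials (default 20 000 per cell) and
clipped below at 1/(2·n_sim) so the deviance stays finite under finite
simulation.  In median mode the error side enters as a single multinomial
cell for the error count — algebraically the binomial deviance on the
error count given the correct-bin cells — plus a penalty
λ·N·((m_obs − m_pred)/m_obs)² on the median error RT (λ = 1 default,
capped at λ·N when the model produces no errors at all).

**Optimisation.**  5000 uniform random starts in a documented box
(boundary 0.05–0.25, drift 0.05–0.7, ζ 0–0.05, Ter 0.1–0.6 s on the
σ = 0.1 scale) are screened; the best 15 (ties broken by lowest index)
are refined by Nelder–Mead (bounded, `maxfev` 200 per run by default),
each restarted 3 times by re-initialising the simplex at the incumbent
optimum.  The final deviance can never exceed the best screening
deviance (enforced, and asserted in tests).  Free parameters: boundaries
(one per sharing group: single, per congruency block, or per instruction
block), a shared drift (μ_c for the conflict model, with ζ also free and
τ, α fixed at 0.03 s / 2.0 unless `fit_tau` is set), and Ter.

**Common random numbers.**  One Gaussian increment pool (2²² values) is
drawn per fit; every objective evaluation reads it with a fixed stride
per trial and a fixed offset per cell.  This makes the objective
deterministic given the fit seed, much smoother in the parameters than
fresh-noise simulation, and roughly an order of magnitude faster.  The
whole fit is reproducible: identical (data, options, seed) give an
identical `FitResult`.

## Questionnaire scoring

Responses are integers 1–4 (1 = Agree strongly .. 4 = Disagree strongly)
on 59 items in five subscales (negative urgency 12, premeditation 11,
perseverance 10, sensation seeking 12, positive urgency 14 items).
Reverse-coded items map r → 5 − r; subscale scores are item totals
(a monotone transform of the item mean, so rank-based correlations are
unaffected by the sum-vs-mean choice), oriented so high = more impulsive;
two-session scores are averaged.  The default key is *generic*: correct
subscale sizes with urgency/sensation-seeking items flagged reversed; the
instrument's exact item-level key is deliberately not reproduced and can
be supplied as a CSV (`item_id, subscale, reversed`).  Missing items
default to strict (subscale NaN), with a mean-imputation switch.

## Meta-analysis

Effects: Spearman ρ per (dataset, task × boundary-group, subscale),
z = atanh(ρ), var = 1/(n−3).  The three-level model's marginal covariance
is block-diagonal by dataset: V_d = diag(vᵢ + τ²_w) + τ²_b·J.  REML
estimates (τ²_w, τ²_b) by bounded quasi-Newton from a 4 × 4 grid of
starts plus a Nelder–Mead polish (tolerance 1e-8; negative components
truncated at 0); block inverses and determinants use the
Sherman–Morrison identity, so the likelihood is exact.  The pooled mean
is the GLS average; CIs are Wald on z (Knapp–Hartung optional, off by
default) and back-transformed by tanh.  Note var = 1/(n−3) is the
Pearson-z variance; for Spearman correlations it is mildly
anticonservative (the exact factor is ≈ 1.06), which the null-calibration
experiment shows still yields near-nominal CI coverage.

Heterogeneity: multilevel I² per level =
100·τ²_level/(τ²_w + τ²_b + ṽ), with the Higgins–Thompson typical
sampling variance ṽ = (k−1)Σw/((Σw)² − Σw²); Cochran's Q against the
fixed-effect mean with χ²(k−1) reference.  With one effect per dataset
only τ²_w + τ²_b is identified (the likelihood depends on the sum); the
tests therefore compare the sum, pooled mean and SE against an
independent two-level REML oracle.

**Sensitivity power analysis** (closed form, the default; a Monte-Carlo
mode cross-checks it): ṽ = 1/(n̄−3), τ² = ṽ·I²/(1−I²),
SE = √((ṽ+τ²)/k), detectable z = (z_{1−α/2} + z_power)·SE, reported as
tanh(z) rounded to two decimals.  Heterogeneity anchors: I² = 25/50/75%
for small/moderate/large — the conventional benchmarks, and the
calibration under which a 19-effect, n̄ = 68 design detects
ρ = 0.09/0.11/0.16 at 80% power.

## Synthetic-data generator

The generator defines the study conditions the pipeline is validated
under.  Defaults reproduce the five-dataset battery: N = 50/103/102/43/69;
intermixed three-condition conflict tasks (336 and 480 trials per
condition, the latter over two sessions), a blocked/intermixed Simon pair
(288 per condition, separate congruent/incongruent boundaries in the
blocked task), two speed/accuracy-instructed datasets (576 and 192 trials
per condition across 3 instruction × 3 congruency cells) and a dot-motion
task (240 per condition, 2 motion directions × 3 instruction blocks, fit
with the standard diffusion model — directions are statistically
mirrored, so one drift magnitude describes both).  Boundary groups sum to
19, the design's effect count per subscale.  Trials-per-condition are
totals, split evenly across sessions; behavioural sessions share
generating parameters exactly.

Per subject: latent (caution, 5 impulsivity traits) ~ MVN with unit
variances, per-subscale caution–impulsivity correlation `true_corr`
(default 0) and impulsivity inter-trait correlation 0.3 (PSD validated).
log a = log 0.11 + instruction offset (−0.25 / 0 / +0.25 for
speed/both/accuracy) + 0.18·caution + N(0, 0.09²), giving a boundary CV
of ≈ 20% around a mean of 0.11 — a plausible between-subject spread for
these tasks, and positivity by construction.  Other generating
parameters: μ_c ~ N(0.40, 0.08), ζ ~ N(0.016, 0.004) (truncated ≥ 0),
τ = 0.03 s, α = 2, Ter ~ N(0.30, 0.03).  Questionnaire items are graded
thresholds (−1, 0, 1) on (session trait + N(0,1) item noise), where the
session trait mixes the stable trait with session noise to give a
test-retest correlation of 0.8; reversed items are inverted.  Seeding is
hierarchical (one master seed, counter-based sub-streams per
dataset/subject/stage), so partial re-runs reproduce exactly.

What it does **not** emulate: contaminant/outlier RT processes, fatigue
or practice effects, response biases, missing data beyond simple
missing-item handling, or item-level psychometric structure beyond one
trait per subscale.  Passing recovery and calibration tests therefore
show the estimator chain is correct under the assumed generative
process, not that real data meet those assumptions.

## Validation problem sizes

Chosen as the package's own desk-scale experiments:

* simulator vs closed form: 50 000 trials at dt = 0.5 ms, 3 MC SEs;
* conflict-model reduction: KS distance on 10 000-trial samples below
  the 1% two-sample critical value (≈ 0.023);
* REML vs brute force: 6 effects in 2 datasets, two-stage grid to
  2·10⁻⁴ resolution, agreement to 3 decimals;
* boundary recovery: 30 participants × 480 trials, boundaries
  log-normal(log 0.11, 0.18), reduced budget (200 starts, best 5
  refined, 2 restarts, 10 000 simulated trials per evaluation,
  Nelder–Mead `maxfev` 60 per run) — Spearman(true, estimated) ≥ 0.7
  (observed ≈ 0.9);
* null calibration: 100 replicate studies (2 datasets × 30 subjects,
  true_corr = 0, truth boundaries) — pooled 95% CIs cover zero at
  90–98% of checks.

## Known limitations

* The quantile-deviance estimator is simulation-based; its objective is
  exactly reproducible per seed but still a noisy estimate of the ideal
  deviance — very small `n_sim` biases parameter estimates.
* The Wald CI with REML variance components ignores uncertainty in τ²;
  with few datasets the between-dataset component is weakly identified
  (use Knapp–Hartung for conservative inference).
* No analytic first-passage densities, hierarchical/Bayesian estimation,
  publication-bias diagnostics or meta-regression — out of scope by
  design.
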