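# cautionmeta

Does trait impulsivity, as people report it about themselves, predict how
cautiously they make speeded decisions?  `cautionmeta` is a tested Python
pipeline for answering that question the way individual-differences
researchers do: it extracts **response caution** — the boundary-separation
parameter *a* of evidence-accumulation models — from trial-level choice-RT
data, scores the 59-item **UPPS-P** impulsivity questionnaire, correlates
the two, and pools the correlations across tasks and datasets with a
**three-level random-effects meta-analysis**.

It is aimed at cognitive researchers who have (or want to simulate)
multi-dataset batteries of conflict tasks (flanker, Simon, Stroop) and
perceptual-decision tasks, and need the full chain from raw trials to a
pooled effect size with heterogeneity diagnostics and a sensitivity power
analysis.

## What it computes

**Decision models.**  Two forward simulators (seconds / σ = 0.1 scale,
Euler–Maruyama with a continuity-corrected absorbing boundary):

* standard drift-diffusion model: evidence *X* accumulates with drift *v*
  and diffusion σ between boundaries 0 and *a*; *a* is response caution;
* diffusion model for conflict tasks: the drift is
  μ(t) = μ_c ± dE[A(t)]/dt, where
  E[A(t)] = ζ·e^{−t/τ}·(t·e/((α−1)τ))^{α−1}
  is a gamma-shaped automatic activation with peak amplitude ζ at
  t = (α−1)τ, added toward the correct response on congruent trials and
  toward the error on incongruent trials.

**Fitting.**  Observed RTs per design cell are split into quantile bins
([.1, .3, .5, .7, .9] for corrects; sparser rules when errors are scarce:
cuts [.3, .5, .7] below 11 errors, error count + median error RT below 5),
and parameters minimise the multinomial deviance
G² = 2·Σ Oᵢ ln(Oᵢ/(N·pᵢ)) against model-simulated bin proportions — 5000
uniform random starts, the best 15 refined by Nelder–Mead restarted 3
times (budgets configurable).  Boundary parameters can be shared or split
per congruency block or per speed/accuracy instruction block.

**Meta-analysis.**  Spearman correlations ρ between each boundary estimate
and each UPPS-P subscale are Fisher-z transformed (var = 1/(n−3)) and
pooled by REML under a three-level model: sampling error (level 1),
heterogeneity of effects within a dataset (τ²_within, level 2), and
across datasets (τ²_between, level 3).  Reported alongside: multilevel I²
(Higgins–Thompson typical sampling variance), Cochran's Q, Wald or
Knapp–Hartung CIs, and a closed-form sensitivity power analysis
(detectable ρ at given k, n̄, α, power, and I² anchors 25/50/75%).

**Synthetic studies.**  A generator emulates a five-dataset battery
(N = 50/103/102/43/69; intermixed and blocked congruency; speed/accuracy
instruction blocks; two-session designs; 19 boundary estimates in total)
with a configurable latent correlation between a caution trait (driving
log-boundary) and impulsivity traits (driving graded Likert responses), so
the whole pipeline can be validated by parameter recovery and null
calibration.

## Worked example

```python
from cautionmeta import (DDMParams, FitOptions, simulate_ddm,
                         fit_participant_task, power_table)

true = DDMParams(boundary_a=0.13, drift_v=0.35, nondecision_ter=0.30)
trials = simulate_ddm(true, 480, seed=42)
print(trials["correct"].mean(), trials["rt"].mean())
# 0.988 0.487   <- high accuracy, ~490 ms mean RT: a cautious responder

opts = FitOptions(n_starts=200, n_refine=5, n_restarts=2, n_sim=10_000,
                  nm_maxfev=60)
res = fit_participant_task(trials, model="ddm", options=opts, seed=7)
print(res.best_params, res.deviance)
# boundary 0.131, drift 0.349, Ter 0.301, deviance 5.58
# -> the generating caution level (a = 0.13) is recovered from 480 trials
```

The sensitivity power analysis for a 19-effect pool with average n = 68:

```python
print(power_table(k=19, n_bar=68, alpha=0.05, power=0.80))
# heterogeneity  i2_percent  detectable_rho
#         small        25.0            0.09
#      moderate        50.0            0.11
#         large        75.0            0.16
```

i.e. with that design the meta-analysis has 80% power to detect pooled
correlations of ρ ≥ 0.09–0.16 depending on assumed heterogeneity, so a
null result is informative about anything but very small effects.

The same stages are available from the shell:

```bash
cautionmeta simulate --out study/ --seed 1          # synthetic study CSVs
cautionmeta fit --trials study/trials_ds1.csv --out fits.csv
cautionmeta meta --boundaries fits.csv --questionnaire study/questionnaire.csv --out meta/
cautionmeta power --k 19 --n-bar 68
```

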