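"""Three-level random-effects meta-analysis of caution-impulsivity
correlations.

Each effect is a Spearman correlation between one boundary-separation
estimate (a task x boundary-group "measure") and one questionnaire
subscale, computed within one dataset.  Correlations are pooled on the
Fisher-z scale with sampling variance 1/(n-3).  The three-level model
places sampling error at level 1, heterogeneity of effects within a
dataset at level 2 (tau2_within) and heterogeneity across datasets at
level 3 (tau2_between); variance components are estimated by REML and the
pooled mean is the generalised-least-squares average under the implied
block covariance.  Heterogeneity is summarised by a multilevel I^2
decomposition (using the Higgins-Thompson typical sampling variance) and
Cochran's Q.

A closed-form sensitivity power analysis reports the smallest correlation
detectable at a target power for a given number of effects, average sample
size and assumed heterogeneity (I^2 anchors 25/50/75% for
small/moderate/large).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

logger = logging.getLogger("cautionmeta")

HETEROGENEITY_ANCHORS = {"none": 0.0, "small": 0.25, "moderate": 0.50, "large": 0.75}


class UndefinedCorrelationError(ValueError):
    """Spearman's rho is undefined (a constant input vector)."""


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectSize:
    """One Spearman correlation with its Fisher-z transform."""

    rho: float
    n: int
    dataset_id: str
    measure_id: str
    subscale: str
    z: float = field(init=False)
    var_z: float = field(init=False)

    def __post_init__(self):
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if abs(self.rho) == 1.0:
            raise ValueError("|rho| = 1 has infinite Fisher z")
        if self.n < 4:
            raise ValueError("need n >= 4 for var_z = 1/(n-3)")
        object.__setattr__(self, "z", math.atanh(self.rho))
        object.__setattr__(self, "var_z", 1.0 / (self.n - 3))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def to_fisher_z(rho: float, n: int) -> tuple[float, float]:
    """Fisher z = atanh(rho) and its sampling variance 1/(n-3)."""
    if abs(rho) >= 1.0:
        raise ValueError("|rho| must be < 1 for a finite Fisher z")
    if n < 4:
        raise ValueError("need n >= 4")
    return math.atanh(rho), 1.0 / (n - 3)


# ---------------------------------------------------------------------------
# Three-level REML
# ---------------------------------------------------------------------------


@dataclass
class MetaResult:
    """Pooled three-level meta-analysis result (z and rho scales)."""

    pooled_z: float
    pooled_rho: float
    se_z: float
    ci95_z: tuple
    ci95_rho: tuple
    tau2_within: float
    tau2_between: float
    i2_within: float
    i2_between: float
    i2_total: float
    q_stat: float
    q_df: int
    q_pvalue: float
    k: int
    n_datasets: int
    reml_loglik: float = float("nan")
    ci_method: str = "wald"


def _blocks(effects):
    z = np.array([e.z for e in effects])
    v = np.array([e.var_z for e in effects])
    ds = [e.dataset_id for e in effects]
    groups = {}
    for i, d in enumerate(ds):
        groups.setdefault(d, []).append(i)
    return z, v, list(groups.values())


def reml_loglik(tau2_within: float, tau2_between: float, effects) -> float:
    """Restricted log-likelihood of the three-level model (intercept-only).

    Block covariance per dataset: diag(v_i + tau2_within) + tau2_between
    (shared between all effects of a dataset); inverses via
    Sherman-Morrison, so the computation is exact and fast.
    """
    z, v, blocks = _blocks(effects)
    tw, tb = max(tau2_within, 0.0), max(tau2_between, 0.0)
    logdet = 0.0
    s_wz = 0.0
    s_w = 0.0
    s_wzz = 0.0
    for idx in blocks:
        d = v[np.array(idx)] + tw
        zi = z[np.array(idx)]
        dinv = 1.0 / d
        c = 1.0 + tb * dinv.sum()
        logdet += np.sum(np.log(d)) + math.log(c)
        # V^-1 x = D^-1 x - tb * D^-1 1 (1' D^-1 x) / c
        s1x = float(np.sum(dinv * zi))
        s11 = float(np.sum(dinv))
        s_wz += s1x - tb * s11 * s1x / c
        s_w += s11 - tb * s11 * s11 / c
        s_wzz += float(np.sum(dinv * zi * zi)) - tb * s1x * s1x / c
    beta = s_wz / s_w
    rss = s_wzz - 2.0 * beta * s_wz + beta * beta * s_w
    k = len(z)
    return -0.5 * (logdet + math.log(s_w) + rss + (k - 1) * math.log(2.0 * math.pi))


def _gls_mean(tau2_within, tau2_between, effects):
    z, v, blocks = _blocks(effects)
    tw, tb = max(tau2_within, 0.0), max(tau2_between, 0.0)
    s_wz = 0.0
    s_w = 0.0
    for idx in blocks:
        d = v[np.array(idx)] + tw
        zi = z[np.array(idx)]
        dinv = 1.0 / d
        c = 1.0 + tb * dinv.sum()
        s1x = float(np.sum(dinv * zi))
        s11 = float(np.sum(dinv))
        s_wz += s1x - tb * s11 * s1x / c
        s_w += s11 - tb * s11 * s11 / c
    return s_wz / s_w, 1.0 / math.sqrt(s_w)


def typical_sampling_variance(effects) -> float:
    """Higgins-Thompson typical within-study variance
    v~ = (k-1) * sum(w) / ((sum w)^2 - sum w^2), w = 1/var_z."""
    w = np.array([1.0 / e.var_z for e in effects])
    k = len(w)
    if k < 2:
        return float(np.mean(1.0 / w)) if k else float("nan")
    return float((k - 1) * w.sum() / (w.sum() ** 2 - np.sum(w ** 2)))


def multilevel_i2(tau2_within: float, tau2_between: float, effects):
    """Percentage of total variance at each heterogeneity level relative to
    tau2_within + tau2_between + typical sampling variance."""
    vt = typical_sampling_variance(effects)
    denom = tau2_within + tau2_between + vt
    if denom <= 0:
        return 0.0, 0.0, 0.0
    i2w = 100.0 * tau2_within / denom
    i2b = 100.0 * tau2_between / denom
    return i2w, i2b, i2w + i2b


def cochran_q(effects):
    """Cochran's Q against the fixed-effect mean; chi-square df = k - 1."""
    if len(effects) < 2:
        raise ValueError("need at least two effects")
    z = np.array([e.z for e in effects])
    w = np.array([1.0 / e.var_z for e in effects])
    zbar = np.sum(w * z) / np.sum(w)
    q = float(np.sum(w * (z - zbar) ** 2))
    df = len(z) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def fit_three_level(effects, ci_method: str = "wald", tol: float = 1e-8) -> MetaResult:
    """REML fit of the three-level random-effects model.

    Variance components are maximised over [0, inf) with multiple bounded
    L-BFGS-B starts followed by a Nelder-Mead polish; negative estimates
    are truncated at zero.  The 95% CI is Wald on the z scale (optionally
    Knapp-Hartung: ``ci_method="knapp_hartung"``) and back-transformed to
    rho via tanh.
    """
    effects = list(effects)
    k = len(effects)
    datasets = {e.dataset_id for e in effects}
    if k == 0:
        raise ValueError("no effects to pool")
    if k == 1:
        e = effects[0]
        se = math.sqrt(e.var_z)
        lo, hi = e.z - 1.959963984540054 * se, e.z + 1.959963984540054 * se
        return MetaResult(e.z, math.tanh(e.z), se, (lo, hi), (math.tanh(lo), math.tanh(hi)),
                          0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0, 1.0, 1, 1)

    z = np.array([e.z for e in effects])
    v = np.array([e.var_z for e in effects])
    scale = max(float(np.var(z)), float(np.mean(v)), 1e-4)

    def nll(theta):
        return -reml_loglik(theta[0], theta[1], effects)

    best = None
    for s0 in (0.0, 0.1, 1.0, 4.0):
        for s1 in (0.0, 0.1, 1.0, 4.0):
            res = minimize(nll, x0=np.array([s0 * scale, s1 * scale]),
                           method="L-BFGS-B", bounds=[(0.0, None), (0.0, None)],
                           options={"ftol": tol, "gtol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
    polish = minimize(nll, x0=np.maximum(best.x, 0.0), method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxfev": 2000})
    if polish.fun < best.fun:
        best = polish
    tw, tb = float(max(best.x[0], 0.0)), float(max(best.x[1], 0.0))

    pooled_z, se = _gls_mean(tw, tb, effects)
    if ci_method == "knapp_hartung":
        # scale the Wald SE by the GLS residual dispersion, t reference
        ll = reml_loglik(tw, tb, effects)
        zc = float(stats.t.ppf(0.975, k - 1))
        # residual dispersion q~ = r' V^-1 r / (k - 1)
        qtilde = _kh_dispersion(tw, tb, effects, pooled_z)
        se_ci = se * math.sqrt(max(qtilde, 1.0))
    else:
        zc = 1.959963984540054
        se_ci = se
        ll = reml_loglik(tw, tb, effects)
    lo, hi = pooled_z - zc * se_ci, pooled_z + zc * se_ci
    i2w, i2b, i2t = multilevel_i2(tw, tb, effects)
    q, df, p = cochran_q(effects)
    result = MetaResult(pooled_z=float(pooled_z), pooled_rho=math.tanh(pooled_z),
                        se_z=float(se_ci), ci95_z=(lo, hi),
                        ci95_rho=(math.tanh(lo), math.tanh(hi)),
                        tau2_within=tw, tau2_between=tb,
                        i2_within=i2w, i2_between=i2b, i2_total=i2t,
                        q_stat=q, q_df=df, q_pvalue=p, k=k,
                        n_datasets=len(datasets), reml_loglik=float(ll),
                        ci_method=ci_method)
    logger.info("meta fit: k=%d datasets=%d pooled_rho=%.4f tau2=(%.5f, %.5f) I2=%.1f%%",
                k, len(datasets), result.pooled_rho, tw, tb, i2t)
    return result


def _kh_dispersion(tw, tb, effects, beta):
    z, v, blocks = _blocks(effects)
    total = 0.0
    for idx in blocks:
        d = v[np.array(idx)] + tw
        r = z[np.array(idx)] - beta
        dinv = 1.0 / d
        c = 1.0 + tb * dinv.sum()
        s1r = float(np.sum(dinv * r))
        total += float(np.sum(dinv * r * r)) - tb * s1r * s1r / c
    return total / (len(z) - 1)


# ---------------------------------------------------------------------------
# Sensitivity power analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerSpec:
    """Design of a sensitivity power analysis for a random-effects pool."""

    k: int = 19
    n_bar: float = 68.0
    alpha_sig: float = 0.05
    target_power: float = 0.80
    heterogeneity: str | float = "small"  # anchor name or explicit I2 in [0, 1)

    def __post_init__(self):
        if self.k < 2 or self.n_bar < 4:
            raise ValueError("need k >= 2 and n_bar >= 4")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0,1)")

    @property
    def i2(self) -> float:
        if isinstance(self.heterogeneity, str):
            try:
                return HETEROGENEITY_ANCHORS[self.heterogeneity]
            except KeyError:
                raise ValueError(f"unknown heterogeneity level {self.heterogeneity!r}")
        i2 = float(self.heterogeneity)
        if not 0 <= i2 < 1:
            raise ValueError("explicit I2 must lie in [0, 1); 1 implies infinite variance")
        return i2


def sensitivity_power(spec: PowerSpec, rounded: bool = True,
                      method: str = "closed_form", n_mc: int = 4000,
                      seed: int = 0) -> float:
    """Smallest correlation detectable with the target power.

    Closed form on the Fisher-z scale: with typical sampling variance
    v = 1/(n_bar - 3) and heterogeneity tau^2 = v * I2/(1 - I2), the pooled
    estimate has SE = sqrt((v + tau^2)/k) and the detectable effect is
    z* = (z_{1-alpha/2} + z_{power}) * SE, reported as tanh(z*).

    ``method="simulation"`` cross-checks the closed form by Monte-Carlo
    power at the closed-form solution (bisection on rho).
    """
    v = 1.0 / (spec.n_bar - 3.0)
    i2 = spec.i2
    tau2 = v * i2 / (1.0 - i2)
    se = math.sqrt((v + tau2) / spec.k)
    zc = float(stats.norm.ppf(1.0 - spec.alpha_sig / 2.0))
    zp = float(stats.norm.ppf(spec.target_power))
    if method == "closed_form":
        rho = math.tanh((zc + zp) * se)
        return round(rho, 2) if rounded else rho
    if method != "simulation":
        raise ValueError("method must be 'closed_form' or 'simulation'")
    rng = np.random.default_rng(seed)

    def power_at(rho):
        zt = math.atanh(rho)
        zs = rng.normal(zt, math.sqrt(v + tau2), size=(n_mc, spec.k))
        est = zs.mean(axis=1)
        return float(np.mean(np.abs(est / se) > zc))

    lo, hi = 1e-4, 0.9
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if power_at(mid) < spec.target_power:
            lo = mid
        else:
            hi = mid
    rho = 0.5 * (lo + hi)
    return round(rho, 2) if rounded else rho


def power_table(k: int = 19, n_bar: float = 68.0, alpha: float = 0.05,
                power: float = 0.80, levels=("small", "moderate", "large")) -> pd.DataFrame:
    """Detectable rho per heterogeneity level (the reporting table)."""
    rows = []
    for lev in levels:
        spec = PowerSpec(k=k, n_bar=n_bar, alpha_sig=alpha, target_power=power,
                         heterogeneity=lev)
        rows.append({"heterogeneity": lev, "i2_percent": 100.0 * spec.i2,
                     "detectable_rho": sensitivity_power(spec)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline: boundaries x subscales -> effects -> pooled results
# ---------------------------------------------------------------------------


def build_effects(boundaries: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """One Spearman correlation per (dataset, measure, subscale).

    ``boundaries``: dataset_id, subject_id, task_id, boundary_group,
    boundary.  ``scores``: subject_id, subscale, score (session-averaged).
    The measure label is ``task_id:boundary_group``.
    """
    for col in ("dataset_id", "subject_id", "task_id", "boundary_group", "boundary"):
        if col not in boundaries.columns:
            raise ValueError(f"boundaries missing column {col!r}")
    merged = boundaries.merge(scores, on="subject_id", how="inner")
    if len(merged) == 0:
        raise ValueError("empty join: no subjects shared between boundaries and scores")
    rows = []
    group_cols = ["dataset_id", "task_id", "boundary_group", "subscale"]
    for (ds, task, grp, sub), g in merged.groupby(group_cols, sort=True):
        g = g.dropna(subset=["boundary", "score"])
        if len(g) < 4:
            continue
        rho = spearman_rho(g["boundary"], g["score"])
        rho = float(np.clip(rho, -0.999999, 0.999999))
        z, var_z = to_fisher_z(rho, len(g))
        rows.append({"dataset_id": ds, "measure_id": f"{task}:{grp}", "subscale": sub,
                     "n": len(g), "rho": rho, "z": z, "var_z": var_z})
    return pd.DataFrame(rows)


def run_meta_pipeline(boundaries: pd.DataFrame, scores: pd.DataFrame,
                      ci_method: str = "wald"):
    """Full meta-analytic stage: effect table plus one pooled three-level
    result per subscale.  Returns ``(effects_df, {subscale: MetaResult})``."""
    effects_df = build_effects(boundaries, scores)
    results = {}
    for sub, g in effects_df.groupby("subscale", sort=True):
        effects = [EffectSize(rho=r.rho, n=int(r.n), dataset_id=str(r.dataset_id),
                              measure_id=r.measure_id, subscale=sub)
                   for r in g.itertuples()]
        results[sub] = fit_three_level(effects, ci_method=ci_method)
    return effects_df, results


def forest_plot(effects_df: pd.DataFrame, result: MetaResult, subscale: str, path) -> None:
    """Minimal forest plot for one subscale (per-effect CIs + pooled diamond)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = effects_df[effects_df["subscale"] == subscale].reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(g) + 1.5))
    for i, r in g.iterrows():
        half = 1.959963984540054 * math.sqrt(r.var_z)
        lo, hi = math.tanh(r.z - half), math.tanh(r.z + half)
        ax.plot([lo, hi], [i, i], color="0.4")
        ax.plot(r.rho, i, "o", color="0.2", ms=4)
    ax.axvline(0.0, color="0.8", lw=0.8)
    y = len(g)
    ax.plot(result.ci95_rho, [y, y], color="k", lw=2)
    ax.plot(result.pooled_rho, y, "D", color="k")
    ax.set_yticks(list(range(len(g))) + [y])
    ax.set_yticklabels([f"{r.dataset_id} {r.measure_id}" for _, r in g.iterrows()] + ["pooled"])
    ax.set_xlabel("Spearman rho")
    ax.set_title(subscale)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
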