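"""Forward simulators for evidence-accumulation models of choice RT.

Two generative models are provided:

* the standard drift-diffusion model (DDM): noisy accumulation of evidence
  with constant mean drift between two absorbing boundaries, where the
  boundary separation ``a`` quantifies response caution;
* the diffusion model for conflict tasks (DMC): the same accumulator, but
  the mean drift is the sum of a controlled component ``mu_c`` and the time
  derivative of a transient, gamma-shaped "automatic activation" that is
  driven by task-irrelevant stimulus features and pushes toward the correct
  response on congruent trials and the incorrect response on incongruent
  trials.

Internal convention: time in seconds, diffusion coefficient sigma fixed at
0.1 (the classic diffusion scale).  The DMC literature's ms / sigma = 4
convention is supported through :func:`from_dmc_convention`.

Simulation uses Euler–Maruyama with the Broadie–Glasserman–Kou continuity
correction: absorbing boundaries are shifted inward by 0.5826 * sigma *
sqrt(dt), which removes the O(sqrt(dt)) first-passage bias of the naive
discrete scheme.  Closed-form first-passage results for the constant-drift
case are exposed as a test oracle via :func:`ddm_closed_form`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

logger = logging.getLogger("cautionmeta")

# ---------------------------------------------------------------------------
# Package-wide constants and seed plumbing
# ---------------------------------------------------------------------------

#: diffusion coefficient (evidence-scale convention, fixed within a fit)
SIGMA_DEFAULT = 0.1
#: Euler-Maruyama step, seconds
DT_DEFAULT = 0.001
#: hard ceiling on simulated decision time, seconds; trials that have not
#: terminated by then are censored and flagged
RT_CEILING_DEFAULT = 5.0
#: Broadie-Glasserman-Kou continuity-correction constant |zeta(1/2)|/sqrt(2*pi)
BGK_CONSTANT = 0.5826

CONGRUENCIES = ("congruent", "incongruent", "neutral")
INSTRUCTIONS = ("speed", "accuracy", "both")

#: column schema of a tidy trial table
TRIAL_COLUMNS = (
    "subject_id",
    "dataset_id",
    "task_id",
    "session",
    "congruency",
    "instruction_block",
    "rt",
    "correct",
)


class InvalidParameterError(ValueError):
    """A model parameter violates its admissible range."""


class UnsupportedOracleError(ValueError):
    """Closed-form oracle requested for a configuration it does not cover."""


def child_seed(master_seed: int, *keys) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a master seed and keys.

    Counter-based fan-out: every stochastic stage of the pipeline draws its
    own stream from the run seed plus a stable identifier, so partial
    re-runs reproduce exactly.
    """
    import zlib

    ints = [int(master_seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, (int, np.integer)):
            ints.append(int(k) & 0xFFFFFFFF)
        else:
            ints.append(zlib.crc32(str(k).encode()))
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def validate_trial_table(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` naming the first problem in a trial table."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("trial table is empty")
    if df[list(TRIAL_COLUMNS)].isna().any().any():
        bad = int(df[list(TRIAL_COLUMNS)].isna().any(axis=1).idxmax())
        raise ValueError(f"trial table has missing fields (first bad row index {bad})")
    if (df["rt"] <= 0).any():
        bad = int((df["rt"] <= 0).idxmax())
        raise ValueError(f"non-positive rt at row index {bad}")
    bad_cong = set(df["congruency"].unique()) - set(CONGRUENCIES)
    if bad_cong:
        raise ValueError(f"unknown congruency values: {sorted(bad_cong)}")


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class DDMParams:
    """Parameters of one standard-diffusion participant/condition.

    ``boundary_a`` is the boundary separation ("response caution"),
    ``drift_v`` the mean evidence-accumulation rate toward the correct
    (upper) boundary, ``start_fraction_zr`` the relative starting point and
    ``nondecision_ter`` the non-decision time.  Trial-to-trial
    variabilities (``drift_sd_sv``, ``ter_range_st``, ``start_range_szr``)
    default to zero.
    """

    boundary_a: float
    drift_v: float
    start_fraction_zr: float = 0.5
    nondecision_ter: float = 0.3
    diffusion_sigma: float = SIGMA_DEFAULT
    drift_sd_sv: float = 0.0
    ter_range_st: float = 0.0
    start_range_szr: float = 0.0

    def __post_init__(self) -> None:
        for name in ("boundary_a", "drift_v", "start_fraction_zr", "nondecision_ter",
                     "diffusion_sigma", "drift_sd_sv", "ter_range_st", "start_range_szr"):
            _check(np.isfinite(getattr(self, name)), f"{name} must be finite")
        _check(self.boundary_a > 0, "boundary_a must be > 0")
        _check(0.0 < self.start_fraction_zr < 1.0, "start_fraction_zr must be in (0,1)")
        _check(self.nondecision_ter >= 0, "nondecision_ter must be >= 0")
        _check(self.diffusion_sigma > 0, "diffusion_sigma must be > 0")
        _check(self.drift_sd_sv >= 0, "drift_sd_sv must be >= 0")
        _check(self.ter_range_st >= 0, "ter_range_st must be >= 0")
        zr = self.start_fraction_zr
        _check(self.start_range_szr >= 0, "start_range_szr must be >= 0")
        _check(self.start_range_szr < 2.0 * min(zr, 1.0 - zr),
               "start_range_szr must be < 2*min(zr, 1-zr)")


@dataclass(frozen=True)
class DMCParams:
    """Parameters of one conflict-diffusion participant.

    The automatic activation has expected time course
    ``zeta * exp(-t/tau) * (t*e/((alpha-1)*tau))**(alpha-1)`` — a rescaled
    gamma density that rises from 0, peaks at amplitude ``zeta`` at time
    ``(alpha-1)*tau`` and decays back to 0.  Its time derivative is added
    to (congruent) or subtracted from (incongruent) the controlled drift
    ``controlled_drift_mu_c``.  With ``automatic_amplitude_zeta = 0`` the
    model is distributionally identical to a DDM with ``v = mu_c``.
    """

    boundary_a: float
    controlled_drift_mu_c: float
    automatic_amplitude_zeta: float = 0.016
    automatic_tau: float = 0.03
    automatic_shape_alpha: float = 2.0
    nondecision_ter: float = 0.3
    diffusion_sigma: float = SIGMA_DEFAULT
    start_beta_shape: float = 0.0  # 0 disables start-point variability
    ter_range_st: float = 0.0

    def __post_init__(self) -> None:
        for name in ("boundary_a", "controlled_drift_mu_c", "automatic_amplitude_zeta",
                     "automatic_tau", "automatic_shape_alpha", "nondecision_ter",
                     "diffusion_sigma", "start_beta_shape", "ter_range_st"):
            _check(np.isfinite(getattr(self, name)), f"{name} must be finite")
        _check(self.boundary_a > 0, "boundary_a must be > 0")
        _check(self.automatic_amplitude_zeta >= 0, "automatic_amplitude_zeta must be >= 0")
        _check(self.automatic_tau > 0, "automatic_tau must be > 0")
        _check(self.automatic_shape_alpha > 1, "automatic_shape_alpha must be > 1")
        _check(self.nondecision_ter >= 0, "nondecision_ter must be >= 0")
        _check(self.diffusion_sigma > 0, "diffusion_sigma must be > 0")
        _check(self.start_beta_shape == 0 or self.start_beta_shape >= 1,
               "start_beta_shape must be 0 (off) or >= 1")
        _check(self.ter_range_st >= 0, "ter_range_st must be >= 0")


def congruency_sign(congruency: str) -> int:
    """Sign of the automatic-activation contribution to the correct drift."""
    if congruency == "congruent":
        return 1
    if congruency == "incongruent":
        return -1
    if congruency == "neutral":
        return 0
    raise InvalidParameterError(f"unknown congruency {congruency!r}")


def from_dmc_convention(boundary_b: float, mu_c_per_ms: float, zeta: float,
                        tau_ms: float, alpha: float, ter_ms: float,
                        sigma: float = 4.0) -> DMCParams:
    """Convert DMC-literature parameters (ms time unit, sigma = 4, symmetric
    boundaries at ±b) to the internal seconds / sigma = 0.1 convention.

    Rescaling evidence by ``f = 0.1 / (sigma * sqrt(1000))`` and time by
    1000 maps the process exactly; the boundary *separation* is ``2*b*f``.
    """
    f = SIGMA_DEFAULT / (sigma * math.sqrt(1000.0))
    return DMCParams(
        boundary_a=2.0 * boundary_b * f,
        controlled_drift_mu_c=mu_c_per_ms * 1000.0 * f,
        automatic_amplitude_zeta=zeta * f,
        automatic_tau=tau_ms / 1000.0,
        automatic_shape_alpha=alpha,
        nondecision_ter=ter_ms / 1000.0,
    )


# ---------------------------------------------------------------------------
# Automatic activation (DMC)
# ---------------------------------------------------------------------------


def expected_automatic_activation(t, zeta: float, tau: float, alpha: float):
    """Expected automatic activation E[A(t)] of the conflict model.

    ``zeta * exp(-t/tau) * (t*e/((alpha-1)*tau))**(alpha-1)``: zero at
    ``t = 0`` (for alpha > 1), peak value ``zeta`` at ``t = (alpha-1)*tau``.
    Accepts scalar or array ``t``.
    """
    if not (np.isfinite(zeta) and np.isfinite(tau) and np.isfinite(alpha)):
        raise InvalidParameterError("zeta, tau, alpha must be finite")
    if tau <= 0 or alpha <= 1 or zeta < 0:
        raise InvalidParameterError("require tau > 0, alpha > 1, zeta >= 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or not np.all(np.isfinite(t_arr)):
        raise InvalidParameterError("t must be finite and >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = zeta * np.exp(-t_arr / tau) * (t_arr * math.e / ((alpha - 1.0) * tau)) ** (alpha - 1.0)
    out = np.where(t_arr == 0.0, 0.0, out)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def automatic_drift(t, zeta: float, tau: float, alpha: float):
    """Time derivative dE[A(t)]/dt, the automatic contribution to the drift.

    ``E[A](t) * ((alpha-1)/t - 1/tau)`` for t > 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise InvalidParameterError("automatic_drift requires t > 0")
    a_t = expected_automatic_activation(t_arr, zeta, tau, alpha)
    out = a_t * ((alpha - 1.0) / t_arr - 1.0 / tau)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def dmc_drift_profile(params: DMCParams, congruency: str, dt: float,
                      n_steps: int) -> np.ndarray:
    """Per-step mean drift for a DMC condition, evaluated at step midpoints.

    Midpoint evaluation avoids the t = 0 singularity of dE/dt for
    1 < alpha < 2 and halves the time-discretisation error of the
    deterministic drift component.
    """
    s = congruency_sign(congruency)
    mu = np.full(n_steps, params.controlled_drift_mu_c)
    if s != 0 and params.automatic_amplitude_zeta > 0:
        t_mid = (np.arange(n_steps) + 0.5) * dt
        mu += s * automatic_drift(t_mid, params.automatic_amplitude_zeta,
                                  params.automatic_tau, params.automatic_shape_alpha)
    return mu


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------


@njit(cache=False)
def _ddm_kernel(n, a, v, zr, ter, sigma, sv, st, szr, dt, ceiling, shift, seed):
    """Euler-Maruyama first-passage sampler, fresh RNG, optional trial
    variabilities.  Returns (rt, upper, censored)."""
    np.random.seed(seed)
    rts = np.empty(n)
    upper = np.empty(n, np.bool_)
    censored = np.empty(n, np.bool_)
    sq = sigma * np.sqrt(dt)
    lo = shift
    hi = a - shift
    m = 8192
    chunk = np.random.standard_normal(m)
    ci = 0
    for i in range(n):
        vi = v + sv * np.random.standard_normal() if sv > 0 else v
        zi = zr
        if szr > 0:
            zi = zr + szr * (np.random.random() - 0.5)
        ti = ter
        if st > 0:
            ti = ter + st * (np.random.random() - 0.5)
        x = zi * a
        t = 0.0
        mu = vi * dt
        while lo < x < hi and t < ceiling:
            if ci == m:
                chunk = np.random.standard_normal(m)
                ci = 0
            x += mu + sq * chunk[ci]
            ci += 1
            t += dt
        rts[i] = ti + t
        censored[i] = t >= ceiling
        upper[i] = x >= hi if not censored[i] else x >= zr * a
    return rts, upper, censored


@njit(cache=False)
def _dmc_kernel(n, a, mu_steps, zr, beta_shape, ter, st, sigma, dt, ceiling,
                shift, seed):
    """Conflict-model sampler: per-step mean drift from ``mu_steps``."""
    np.random.seed(seed)
    rts = np.empty(n)
    upper = np.empty(n, np.bool_)
    censored = np.empty(n, np.bool_)
    sq = sigma * np.sqrt(dt)
    lo = shift
    hi = a - shift
    n_steps = mu_steps.size
    m = 8192
    chunk = np.random.standard_normal(m)
    ci = 0
    for i in range(n):
        zi = zr
        if beta_shape > 0:
            b = np.random.beta(beta_shape, beta_shape)
            zi = 0.25 + 0.5 * b  # symmetric around 0.5, range (0.25, 0.75)
        ti = ter
        if st > 0:
            ti = ter + st * (np.random.random() - 0.5)
        x = zi * a
        t = 0.0
        k = 0
        while lo < x < hi and t < ceiling:
            if ci == m:
                chunk = np.random.standard_normal(m)
                ci = 0
            mu = mu_steps[k] if k < n_steps else mu_steps[n_steps - 1]
            x += mu * dt + sq * chunk[ci]
            ci += 1
            t += dt
            k += 1
        rts[i] = ti + t
        censored[i] = t >= ceiling
        upper[i] = x >= hi if not censored[i] else x >= zr * a
    return rts, upper, censored


@njit(cache=False)
def _ddm_pool_kernel(pool, base, n, a, v, ter, sigma, dt, ceiling, shift):
    """DDM sampler reading Gaussian increments from a fixed pool (common
    random numbers across objective evaluations).  zr fixed at 0.5, no
    trial variabilities: the fit path estimates none by default."""
    m = pool.size
    rts = np.empty(n)
    upper = np.empty(n, np.bool_)
    sq = sigma * np.sqrt(dt)
    lo = shift
    hi = a - shift
    mu = v * dt
    for i in range(n):
        j = (base + i * 7919) % m
        x = 0.5 * a
        t = 0.0
        while lo < x < hi and t < ceiling:
            x += mu + sq * pool[j]
            j += 1
            if j == m:
                j = 0
            t += dt
        rts[i] = ter + t
        upper[i] = x >= hi if t < ceiling else x >= 0.5 * a
    return rts, upper


@njit(cache=False)
def _dmc_pool_kernel(pool, base, n, a, mu_steps, ter, sigma, dt, ceiling, shift):
    """DMC sampler on a fixed Gaussian pool (fit path)."""
    m = pool.size
    rts = np.empty(n)
    upper = np.empty(n, np.bool_)
    sq = sigma * np.sqrt(dt)
    lo = shift
    hi = a - shift
    n_steps = mu_steps.size
    for i in range(n):
        j = (base + i * 7919) % m
        x = 0.5 * a
        t = 0.0
        k = 0
        while lo < x < hi and t < ceiling:
            mu = mu_steps[k] if k < n_steps else mu_steps[n_steps - 1]
            x += mu * dt + sq * pool[j]
            j += 1
            if j == m:
                j = 0
            t += dt
            k += 1
        rts[i] = ter + t
        upper[i] = x >= hi if t < ceiling else x >= 0.5 * a
    return rts, upper


# ---------------------------------------------------------------------------
# Public simulators
# ---------------------------------------------------------------------------


def _as_trial_table(rts, upper, censored, *, subject_id, dataset_id, task_id,
                    session, congruency, instruction_block) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "dataset_id": dataset_id,
            "task_id": task_id,
            "session": session,
            "congruency": congruency,
            "instruction_block": instruction_block,
            "rt": rts,
            "correct": upper,
        }
    )
    df["censored"] = censored
    return df


def _check_sim_args(n_trials: int, dt: float) -> None:
    if not (isinstance(n_trials, (int, np.integer)) and n_trials >= 1):
        raise InvalidParameterError("n_trials must be a positive integer")
    if not (np.isfinite(dt) and dt > 0):
        raise InvalidParameterError("dt must be positive and finite")


def simulate_ddm(params: DDMParams, n_trials: int, seed: int,
                 dt: float = DT_DEFAULT, rt_ceiling: float = RT_CEILING_DEFAULT,
                 continuity_correction: bool = True,
                 subject_id=0, dataset_id="sim", task_id="ddm", session=1,
                 congruency="neutral", instruction_block="both") -> pd.DataFrame:
    """Simulate ``n_trials`` standard-diffusion trials; returns a trial table.

    ``correct`` marks upper-boundary (correct-response) absorption; every
    ``rt`` is at least the trial's non-decision time.  Trials still
    unabsorbed at ``rt_ceiling`` are flagged in the ``censored`` column.
    """
    _check_sim_args(n_trials, dt)
    shift = BGK_CONSTANT * params.diffusion_sigma * math.sqrt(dt) if continuity_correction else 0.0
    shift = min(shift, 0.25 * params.boundary_a)
    rts, upper, cens = _ddm_kernel(
        n_trials, params.boundary_a, params.drift_v, params.start_fraction_zr,
        params.nondecision_ter, params.diffusion_sigma, params.drift_sd_sv,
        params.ter_range_st, params.start_range_szr, dt, rt_ceiling, shift,
        child_seed(seed, "ddm"))
    return _as_trial_table(rts, upper, cens, subject_id=subject_id,
                           dataset_id=dataset_id, task_id=task_id, session=session,
                           congruency=congruency, instruction_block=instruction_block)


def simulate_dmc(params: DMCParams, congruency: str, n_trials: int, seed: int,
                 dt: float = DT_DEFAULT, rt_ceiling: float = RT_CEILING_DEFAULT,
                 continuity_correction: bool = True,
                 subject_id=0, dataset_id="sim", task_id="dmc", session=1,
                 instruction_block="both") -> pd.DataFrame:
    """Simulate conflict-model trials for one congruency condition.

    The mean drift at step midpoint t is ``mu_c + s*dE[A(t)]/dt`` with
    s = +1 (congruent), -1 (incongruent) or 0 (neutral).
    """
    _check_sim_args(n_trials, dt)
    congruency_sign(congruency)  # validates
    n_steps = int(math.ceil(rt_ceiling / dt))
    mu_steps = dmc_drift_profile(params, congruency, dt, n_steps)
    shift = BGK_CONSTANT * params.diffusion_sigma * math.sqrt(dt) if continuity_correction else 0.0
    shift = min(shift, 0.25 * params.boundary_a)
    rts, upper, cens = _dmc_kernel(
        n_trials, params.boundary_a, mu_steps, 0.5, params.start_beta_shape,
        params.nondecision_ter, params.ter_range_st, params.diffusion_sigma,
        dt, rt_ceiling, shift, child_seed(seed, "dmc", congruency))
    return _as_trial_table(rts, upper, cens, subject_id=subject_id,
                           dataset_id=dataset_id, task_id=task_id, session=session,
                           congruency=congruency, instruction_block=instruction_block)


def ddm_closed_form(params: DDMParams) -> dict:
    """Closed-form P(correct) and mean decision time for the constant-drift
    Wiener process (test oracle; no trial-to-trial variabilities).

    P(upper) = (1 - exp(-2 v z / sigma^2)) / (1 - exp(-2 v a / sigma^2)),
    z = zr * a; E[T] = (a/v) * P(upper) - z/v for v != 0, and
    P(upper) = zr, E[T] = z (a - z) / sigma^2 for v = 0.
    """
    if params.drift_sd_sv != 0 or params.ter_range_st != 0 or params.start_range_szr != 0:
        raise UnsupportedOracleError(
            "closed form covers only the no-variability diffusion model")
    a, v, s2 = params.boundary_a, params.drift_v, params.diffusion_sigma ** 2
    z = params.start_fraction_zr * a
    if v == 0.0:
        p_upper = params.start_fraction_zr
        mean_t = z * (a - z) / s2
    else:
        p_upper = math.expm1(-2.0 * v * z / s2) / math.expm1(-2.0 * v * a / s2)
        mean_t = (a / v) * p_upper - z / v
    return {"p_correct": p_upper, "mean_decision_time": mean_t}
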