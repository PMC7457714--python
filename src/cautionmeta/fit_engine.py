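"""Quantile-deviance estimation of evidence-accumulation parameters.

The estimation procedure mirrors common practice for simulation-based
diffusion-model fitting:

1.  Observed RTs in each design cell (congruency x instruction block,
    sessions pooled) are split into quantile bins — cut points
    [.1, .3, .5, .7, .9] for correct responses, giving six bins.  Error
    responses use the same cuts when there are at least 11 errors, the
    sparser cuts [.3, .5, .7] with 5-10 errors, and below 5 errors only the
    error count and median error RT are scored.
2.  A candidate parameter set is scored by simulating the model and
    computing the multinomial deviance G^2 = 2 * sum O_i log(O_i/(N p_i))
    between observed bin counts and model-predicted bin proportions.
3.  The deviance is minimised by screening 5000 uniform random parameter
    sets and refining the best 15 with a Nelder-Mead simplex restarted 3
    times (all budgets configurable).

Model simulation inside the objective uses a common-random-number pool:
one Gaussian increment pool is drawn per fit and every objective
evaluation reads it with fixed per-trial strides, so the objective is a
deterministic, relatively smooth function of the parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .decision_models import (
    DT_DEFAULT,
    RT_CEILING_DEFAULT,
    SIGMA_DEFAULT,
    BGK_CONSTANT,
    InvalidParameterError,
    _ddm_pool_kernel,
    _dmc_pool_kernel,
    child_seed,
    congruency_sign,
    dmc_drift_profile,
    validate_trial_table,
)

logger = logging.getLogger("cautionmeta")

ERROR_MODES = ("full", "reduced", "median")


class FitFailureError(RuntimeError):
    """The objective returned no finite value for any refined start."""


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinSpec:
    """Quantile cut points and sparse-error thresholds.

    ``literal_three_bins`` switches the sparse-error cuts to [.3, .7] for a
    literal three-interval reading of "three bins"; the default honours the
    printed cut-point list [.3, .5, .7] (four intervals).
    """

    correct_quantiles: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    sparse_error_quantiles: tuple = (0.3, 0.5, 0.7)
    full_bins_min_errors: int = 11
    median_mode_below: int = 5
    literal_three_bins: bool = False

    def __post_init__(self):
        for q in (self.correct_quantiles, self.sparse_error_quantiles):
            arr = np.asarray(q, float)
            if arr.size and not (np.all(np.diff(arr) > 0) and np.all((arr > 0) & (arr < 1))):
                raise InvalidParameterError("quantiles must be strictly increasing in (0,1)")
        if not self.median_mode_below <= self.full_bins_min_errors:
            raise InvalidParameterError("median threshold must not exceed full-bin threshold")

    @property
    def effective_sparse_quantiles(self) -> tuple:
        return (0.3, 0.7) if self.literal_three_bins else self.sparse_error_quantiles


@dataclass
class BinnedData:
    """Observed quantile-bin counts for one design cell."""

    correct_counts: np.ndarray
    correct_edges: np.ndarray
    error_mode: str
    n_trials: int
    error_counts: np.ndarray | None = None  # full / reduced modes
    error_edges: np.ndarray | None = None
    error_count: int = 0
    median_error_rt: float | None = None  # median mode

    def __post_init__(self):
        total = int(self.correct_counts.sum()) + int(
            self.error_counts.sum() if self.error_counts is not None else self.error_count
        )
        if total != self.n_trials:
            raise ValueError("bin counts do not sum to n_trials")


def choose_error_mode(error_count: int, spec: BinSpec = BinSpec()) -> str:
    """Error-scoring mode from the number of error trials in a condition:
    >= 11 full quantile bins, 5-10 sparse bins, < 5 median-RT mode."""
    if error_count < 0:
        raise InvalidParameterError("error_count must be >= 0")
    if error_count >= spec.full_bins_min_errors:
        return "full"
    if error_count >= spec.median_mode_below:
        return "reduced"
    return "median"


def quantile_edges(rts, quantiles) -> np.ndarray:
    """Empirical quantiles of the data themselves, used as bin edges."""
    rts = np.asarray(rts, float)
    if rts.size == 0:
        raise ValueError("empty RT vector")
    return np.quantile(rts, np.asarray(quantiles, float))


def bin_rts(rts, quantiles=(0.1, 0.3, 0.5, 0.7, 0.9)) -> np.ndarray:
    """Counts of RTs in the intervals delimited by their own empirical
    quantiles: bin j collects values in (e_{j-1}, e_j] (with open ends).
    Counts always sum to ``len(rts)``."""
    rts = np.asarray(rts, float)
    if rts.size == 0:
        raise ValueError("empty RT vector")
    edges = quantile_edges(rts, quantiles)
    idx = np.searchsorted(edges, rts, side="left")
    return np.bincount(idx, minlength=len(edges) + 1).astype(int)


def counts_in_edges(values, edges) -> np.ndarray:
    """Bin arbitrary values into intervals defined by fixed edges."""
    idx = np.searchsorted(np.asarray(edges, float), np.asarray(values, float), side="left")
    return np.bincount(idx, minlength=len(edges) + 1).astype(int)


def bin_condition(rts: np.ndarray, correct: np.ndarray, spec: BinSpec = BinSpec()) -> BinnedData:
    """Bin one design cell's trials, choosing the error mode from the
    observed error count."""
    rts = np.asarray(rts, float)
    correct = np.asarray(correct, bool)
    c_rts = rts[correct]
    e_rts = rts[~correct]
    if c_rts.size == 0:
        raise ValueError("cell has no correct trials; cannot form correct-RT bins")
    c_edges = quantile_edges(c_rts, spec.correct_quantiles)
    c_counts = counts_in_edges(c_rts, c_edges)
    mode = choose_error_mode(e_rts.size, spec)
    if mode == "full":
        e_edges = quantile_edges(e_rts, spec.correct_quantiles)
        return BinnedData(c_counts, c_edges, mode, rts.size,
                          error_counts=counts_in_edges(e_rts, e_edges),
                          error_edges=e_edges, error_count=int(e_rts.size))
    if mode == "reduced":
        e_edges = quantile_edges(e_rts, spec.effective_sparse_quantiles)
        return BinnedData(c_counts, c_edges, mode, rts.size,
                          error_counts=counts_in_edges(e_rts, e_edges),
                          error_edges=e_edges, error_count=int(e_rts.size))
    med = float(np.median(e_rts)) if e_rts.size else None
    return BinnedData(c_counts, c_edges, mode, rts.size,
                      error_count=int(e_rts.size), median_error_rt=med)


# ---------------------------------------------------------------------------
# Deviance
# ---------------------------------------------------------------------------


@dataclass
class PredictedProportions:
    """Model-implied cell proportions aligned to one BinnedData."""

    p_correct_bins: np.ndarray
    p_error_bins: np.ndarray | None = None
    p_error: float | None = None
    median_error_rt: float | None = None


def predict_proportions(sim_rts, sim_correct, observed: BinnedData) -> PredictedProportions:
    """Proportions of simulated trials falling into the observed bins.

    Proportions are joint over response and bin (they sum to one across
    correct and error cells together)."""
    sim_rts = np.asarray(sim_rts, float)
    sim_correct = np.asarray(sim_correct, bool)
    n = sim_rts.size
    pc = counts_in_edges(sim_rts[sim_correct], observed.correct_edges) / n
    err_rts = sim_rts[~sim_correct]
    if observed.error_mode in ("full", "reduced"):
        pe = counts_in_edges(err_rts, observed.error_edges) / n
        return PredictedProportions(pc, p_error_bins=pe)
    med = float(np.median(err_rts)) if err_rts.size else None
    return PredictedProportions(pc, p_error=err_rts.size / n, median_error_rt=med)


def _gsq(obs: np.ndarray, p: np.ndarray, n_total: int, p_floor: float) -> float:
    p = np.clip(np.asarray(p, float), p_floor, None)
    obs = np.asarray(obs, float)
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / (n_total * p[mask]))))


def deviance(observed: BinnedData, predicted: PredictedProportions,
             n_model_trials: int, lambda_median: float = 1.0) -> float:
    """Multinomial deviance between observed bin counts and predicted
    proportions.

    In median mode the error side contributes one multinomial cell for the
    error count plus ``lambda * N * ((m_obs - m_pred)/m_obs)^2`` on the
    median error RT; if the model produces no errors at all, the penalty is
    capped at ``lambda * N``.
    """
    n = observed.n_trials
    floor = 1.0 / (2.0 * n_model_trials)  # finite deviance under finite simulation
    if observed.error_mode in ("full", "reduced"):
        if predicted.p_error_bins is None or len(predicted.p_error_bins) != len(observed.error_counts):
            raise ValueError("predicted proportions do not match observed bin structure")
        if len(predicted.p_correct_bins) != len(observed.correct_counts):
            raise ValueError("predicted proportions do not match observed bin structure")
        obs = np.concatenate([observed.correct_counts, observed.error_counts])
        p = np.concatenate([predicted.p_correct_bins, predicted.p_error_bins])
        return _gsq(obs, p, n, floor)
    if predicted.p_error is None:
        raise ValueError("median-mode observed data need a scalar predicted error rate")
    if len(predicted.p_correct_bins) != len(observed.correct_counts):
        raise ValueError("predicted proportions do not match observed bin structure")
    obs = np.concatenate([observed.correct_counts, [observed.error_count]])
    p = np.concatenate([predicted.p_correct_bins, [predicted.p_error]])
    dev = _gsq(obs, p, n, floor)
    if observed.error_count > 0 and observed.median_error_rt:
        if predicted.median_error_rt is None:
            dev += lambda_median * n
        else:
            rel = (observed.median_error_rt - predicted.median_error_rt) / observed.median_error_rt
            dev += lambda_median * n * min(rel * rel, 1.0)
    return dev


# ---------------------------------------------------------------------------
# Parameter maps and fit options
# ---------------------------------------------------------------------------

BOUNDARY_STRATEGIES = ("single", "per_congruency_block", "per_instruction")


@dataclass(frozen=True)
class ParameterMap:
    """Maps design cells to boundary-sharing groups.

    ``single`` fits one boundary for the whole task; ``per_congruency_block``
    one per congruency (blocked-condition designs); ``per_instruction`` one
    per speed/accuracy/both instruction block.  Non-boundary parameters are
    always shared across groups within a task.
    """

    strategy: str = "single"

    def __post_init__(self):
        if self.strategy not in BOUNDARY_STRATEGIES:
            raise InvalidParameterError(f"unknown boundary strategy {self.strategy!r}")

    def group_of(self, congruency: str, instruction_block: str) -> str:
        if self.strategy == "single":
            return "all"
        if self.strategy == "per_congruency_block":
            return str(congruency)
        return str(instruction_block)

    def n_groups_for(self, congruencies, instructions) -> int:
        if self.strategy == "single":
            return 1
        if self.strategy == "per_congruency_block":
            return len(set(congruencies))
        return len(set(instructions))


@dataclass(frozen=True)
class FitOptions:
    """Optimisation and simulation budget for one participant x task fit.

    Defaults follow the full published budget (5000 screening starts, best
    15 refined by Nelder-Mead with 3 restarts, 20000 model trials per
    objective evaluation); reduce for smoke runs and recovery studies.
    """

    n_starts: int = 5000
    n_refine: int = 15
    n_restarts: int = 3
    n_sim: int = 20000
    dt: float = DT_DEFAULT
    rt_ceiling: float = RT_CEILING_DEFAULT
    sigma: float = SIGMA_DEFAULT
    nm_maxfev: int = 200
    nm_xatol: float = 1e-4
    nm_fatol: float = 1e-3
    pool_size: int = 1 << 22
    continuity_correction: bool = True
    lambda_median: float = 1.0
    fit_tau: bool = False
    dmc_tau: float = 0.03
    dmc_alpha: float = 2.0
    bounds: dict = field(default_factory=dict, hash=False)

    def __post_init__(self):
        for name in ("n_starts", "n_refine", "n_restarts", "n_sim", "nm_maxfev", "pool_size"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")


#: uniform random-start box on the seconds / sigma = 0.1 scale
DEFAULT_BOUNDS = {
    "boundary": (0.05, 0.25),
    "drift": (0.05, 0.7),
    "zeta": (0.0, 0.05),
    "tau": (0.01, 0.12),
    "ter": (0.1, 0.6),
}


def random_starts(bounds: np.ndarray, n: int = 5000, seed: int = 0) -> np.ndarray:
    """``n`` parameter sets uniform in a box; reproducible under ``seed``."""
    bounds = np.asarray(bounds, float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise InvalidParameterError("bounds must be (d, 2)")
    if np.any(bounds[:, 1] < bounds[:, 0]) or not np.all(np.isfinite(bounds)):
        raise InvalidParameterError("bounds must be finite with lo <= hi")
    rng = np.random.default_rng(seed)
    return rng.uniform(bounds[:, 0], bounds[:, 1], size=(int(n), bounds.shape[0]))


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of one participant x task fit."""

    best_params: dict
    deviance: float
    n_random_starts: int
    n_refined: int
    n_restarts: int
    converged: bool
    seed: int
    trace: list = field(default_factory=list)
    error_modes: dict = field(default_factory=dict)
    x: np.ndarray | None = None
    param_names: list = field(default_factory=list)


def refine(top_sets, objective, n_restarts: int = 3, bounds=None,
           maxfev: int = 200, xatol: float = 1e-4, fatol: float = 1e-3):
    """Nelder-Mead refinement of screened starts.

    Each start is polished by a simplex run, then the simplex is
    re-initialised at the incumbent optimum ``n_restarts`` times to escape
    local minima.  Returns ``(x_best, f_best, converged, trace)`` where the
    trace holds each start's deviance path.
    """
    from scipy.optimize import Bounds

    scipy_bounds = None
    if bounds is not None:
        b = np.asarray(bounds, float)
        scipy_bounds = Bounds(b[:, 0], b[:, 1])
    best_x, best_f = None, np.inf
    converged = False
    trace = []
    opts = {"maxfev": maxfev, "xatol": xatol, "fatol": fatol}
    for x0 in top_sets:
        x0 = np.asarray(x0, float)
        f0 = objective(x0)
        path = [float(f0)]
        x_cur = x0
        for _ in range(1 + n_restarts):
            res = minimize(objective, x_cur, method="Nelder-Mead",
                           bounds=scipy_bounds, options=opts)
            x_cur = res.x
            path.append(float(res.fun))
            converged = converged or bool(res.success)
        trace.append(path)
        f_final = path[-1]
        if np.isfinite(f_final) and f_final < best_f:
            best_f, best_x = f_final, x_cur
        elif np.isfinite(f0) and f0 < best_f:  # NM should not worsen, but be safe
            best_f, best_x = f0, x0
    if best_x is None or not np.isfinite(best_f):
        raise FitFailureError("objective returned no finite value for any start")
    return np.asarray(best_x, float), float(best_f), converged, trace


# ---------------------------------------------------------------------------
# Full participant x task fit
# ---------------------------------------------------------------------------


class _Objective:
    """Total deviance across design cells for one participant x task."""

    def __init__(self, cells, model: str, pmap: ParameterMap, options: FitOptions,
                 pool: np.ndarray):
        # cells: list of (congruency, instruction, BinnedData)
        self.cells = cells
        self.model = model
        self.options = options
        self.pool = pool
        self.groups = sorted({pmap.group_of(c, i) for c, i, _ in cells})
        self.group_idx = [self.groups.index(pmap.group_of(c, i)) for c, i, _ in cells]
        self.shift = (BGK_CONSTANT * options.sigma * np.sqrt(options.dt)
                      if options.continuity_correction else 0.0)
        self.n_steps = int(np.ceil(options.rt_ceiling / options.dt))
        if model == "ddm":
            self.param_names = [f"boundary[{g}]" for g in self.groups] + ["drift", "ter"]
        elif model == "dmc":
            self.param_names = [f"boundary[{g}]" for g in self.groups] + ["drift", "zeta"]
            if options.fit_tau:
                self.param_names.append("tau")
            self.param_names.append("ter")
        else:
            raise InvalidParameterError(f"unknown model {model!r}")

    @property
    def bounds(self) -> np.ndarray:
        b = dict(DEFAULT_BOUNDS)
        b.update(self.options.bounds)
        rows = [b["boundary"]] * len(self.groups) + [b["drift"]]
        if self.model == "dmc":
            rows.append(b["zeta"])
            if self.options.fit_tau:
                rows.append(b["tau"])
        rows.append(b["ter"])
        return np.asarray(rows, float)

    def _unpack(self, x):
        g = len(self.groups)
        if self.model == "ddm":
            return x[:g], x[g], None, None, x[g + 1]
        zeta = x[g + 1]
        tau = x[g + 2] if self.options.fit_tau else self.options.dmc_tau
        ter = x[g + 3] if self.options.fit_tau else x[g + 2]
        return x[:g], x[g], zeta, tau, ter

    def __call__(self, x) -> float:
        x = np.asarray(x, float)
        boundaries, drift, zeta, tau, ter = self._unpack(x)
        o = self.options
        total = 0.0
        for ci, (cong, instr, binned) in enumerate(self.cells):
            a = float(boundaries[self.group_idx[ci]])
            shift = min(self.shift, 0.25 * a)
            base = (ci * 1000003) % self.pool.size
            if self.model == "ddm":
                rts, upper = _ddm_pool_kernel(self.pool, base, o.n_sim, a, float(drift),
                                              float(ter), o.sigma, o.dt, o.rt_ceiling, shift)
            else:
                from .decision_models import DMCParams

                params = DMCParams(boundary_a=a, controlled_drift_mu_c=float(drift),
                                   automatic_amplitude_zeta=float(max(zeta, 0.0)),
                                   automatic_tau=float(tau),
                                   automatic_shape_alpha=o.dmc_alpha,
                                   nondecision_ter=float(ter), diffusion_sigma=o.sigma)
                mu_steps = dmc_drift_profile(params, cong, o.dt, self.n_steps)
                rts, upper = _dmc_pool_kernel(self.pool, base, o.n_sim, a, mu_steps,
                                              float(ter), o.sigma, o.dt, o.rt_ceiling, shift)
            pred = predict_proportions(rts, upper, binned)
            total += deviance(binned, pred, o.n_sim, o.lambda_median)
        return total


def _build_cells(trials: pd.DataFrame, spec: BinSpec):
    cells = []
    for (cong, instr), sub in trials.groupby(["congruency", "instruction_block"], sort=True):
        if len(sub) == 0:
            raise ValueError(f"design cell ({cong}, {instr}) has no trials")
        cells.append((cong, instr, bin_condition(sub["rt"].to_numpy(),
                                                 sub["correct"].to_numpy(), spec)))
    if not cells:
        raise ValueError("no design cells in trial table")
    return cells


def fit_participant_task(trials: pd.DataFrame, model: str = "dmc",
                         pmap: ParameterMap = ParameterMap("single"),
                         spec: BinSpec = BinSpec(),
                         options: FitOptions = FitOptions(),
                         seed: int = 0) -> FitResult:
    """Fit one participant's data from one task.

    Sessions are pooled (binning happens after concatenation), the error
    mode is chosen per design cell from the pooled error count, and all
    boundary groups are fit jointly with shared non-boundary parameters.
    Identical (data, options, seed) give an identical result.
    """
    validate_trial_table(trials)
    if trials["subject_id"].nunique() != 1 or trials["task_id"].nunique() != 1:
        raise ValueError("fit_participant_task expects one subject x task")
    cells = _build_cells(trials, spec)
    rng_seed = child_seed(seed, "pool", str(trials["subject_id"].iloc[0]),
                          str(trials["task_id"].iloc[0]))
    pool = np.random.default_rng(rng_seed).standard_normal(options.pool_size)
    obj = _Objective(cells, model, ParameterMap(pmap.strategy), options, pool)
    bounds = obj.bounds
    starts = random_starts(bounds, options.n_starts, child_seed(seed, "starts"))
    screen = np.array([obj(x) for x in starts])
    finite = np.isfinite(screen)
    if not finite.any():
        raise FitFailureError("all screening deviances non-finite")
    order = np.argsort(screen, kind="stable")  # ties: lowest index wins
    n_ref = min(options.n_refine, len(starts))
    top = starts[order[:n_ref]]
    x, f, converged, trace = refine(top, obj, options.n_restarts, bounds,
                                    options.nm_maxfev, options.nm_xatol, options.nm_fatol)
    best_screen = float(screen[order[0]])
    if f > best_screen:  # refinement can never lose to screening
        x, f = starts[order[0]], best_screen
    boundaries, drift, zeta, tau, ter = obj._unpack(np.asarray(x, float))
    best = {"boundary": {g: float(b) for g, b in zip(obj.groups, boundaries)},
            "drift": float(drift), "ter": float(ter)}
    if model == "dmc":
        best["zeta"] = float(zeta)
        best["tau"] = float(tau)
        best["alpha"] = options.dmc_alpha
    logger.info("fit subject=%s task=%s model=%s deviance=%.3f groups=%s",
                trials["subject_id"].iloc[0], trials["task_id"].iloc[0], model, f,
                obj.groups)
    return FitResult(best_params=best, deviance=float(f),
                     n_random_starts=options.n_starts, n_refined=n_ref,
                     n_restarts=options.n_restarts, converged=converged, seed=seed,
                     trace=[[best_screen]] + trace,
                     error_modes={(c, i): b.error_mode for c, i, b in cells},
                     x=np.asarray(x, float), param_names=obj.param_names)


def fit_study(trials: pd.DataFrame, task_models: dict | None = None,
              spec: BinSpec = BinSpec(), options: FitOptions = FitOptions(),
              seed: int = 0) -> pd.DataFrame:
    """Fit every subject x task in a study's trial table.

    ``task_models`` maps task_id to ``{"model": ..., "boundary_groups": ...}``
    (defaults: conflict model, single boundary).  Returns one row per
    subject x task x boundary group.
    """
    validate_trial_table(trials)
    task_models = task_models or {}
    rows = []
    for (ds, subj, task), sub in trials.groupby(["dataset_id", "subject_id", "task_id"],
                                                sort=True):
        meta = task_models.get(task, {})
        model = meta.get("model", "dmc")
        pmap = ParameterMap(meta.get("boundary_groups", "single"))
        res = fit_participant_task(sub, model=model, pmap=pmap, spec=spec,
                                   options=options,
                                   seed=child_seed(seed, ds, subj, task))
        for grp, a in res.best_params["boundary"].items():
            rows.append({"dataset_id": ds, "subject_id": subj, "task_id": task,
                         "boundary_group": grp, "boundary": a,
                         "drift": res.best_params["drift"],
                         "ter": res.best_params["ter"],
                         "zeta": res.best_params.get("zeta", np.nan),
                         "deviance": res.deviance,
                         "converged": res.converged,
                         "error_modes": "|".join(sorted(set(res.error_modes.values())))})
    return pd.DataFrame(rows)
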