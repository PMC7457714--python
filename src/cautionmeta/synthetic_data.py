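"""Synthetic multi-dataset studies with a known caution-impulsivity link.

The generator emulates the structure of a five-dataset choice-RT study:
datasets of differing sample size, conflict tasks with intermixed or
blocked congruency conditions, speed/accuracy instruction manipulations,
two-session designs, and a 59-item Likert questionnaire — with a
configurable latent correlation between a "caution" trait (which drives
boundary separation) and five impulsivity traits (which drive the
questionnaire responses).  Because the latent truth is known, the
generated studies support parameter-recovery scoring and null-calibration
experiments for the whole pipeline.

Per-subject generative model:

* latent traits: (caution, 5 impulsivity traits) ~ multivariate normal with
  unit variances, caution-trait correlations set per subscale and a common
  inter-trait correlation among the impulsivity traits;
* boundary separation (log scale, positive by construction):
  ``log a = log a_mean + instruction offset + loading * caution + noise``,
  with speed < both < accuracy instruction offsets;
* behaviour: trials simulated from the conflict model (or the standard
  diffusion model) via :mod:`cautionmeta.decision_models`; sessions share
  generating parameters exactly;
* questionnaire: item response = graded thresholds applied to a noisy copy
  of the item's subscale trait; sessions share the trait through a
  test-retest correlation; reverse-coded items are inverted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decision_models import (
    DDMParams,
    DMCParams,
    child_seed,
    simulate_ddm,
    simulate_dmc,
)
from .upps_scoring import SUBSCALES, default_scoring_key

logger = logging.getLogger("cautionmeta")


# ---------------------------------------------------------------------------
# Study designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskSpec:
    """One task within a dataset.

    ``conditions`` lists stimulus-condition labels; labels outside
    {congruent, incongruent, neutral} (e.g. motion directions) map to
    neutral congruency.  Total condition count = len(conditions) x
    len(instruction_levels); ``trials_per_condition`` is the total across
    sessions.
    """

    task_id: str
    model: str = "dmc"  # "dmc" or "ddm"
    conditions: tuple = ("congruent", "neutral", "incongruent")
    trials_per_condition: int = 336
    boundary_groups: str = "single"  # single | per_congruency_block | per_instruction
    instruction_levels: tuple = ("both",)

    def congruency_of(self, condition: str) -> str:
        return condition if condition in ("congruent", "incongruent", "neutral") else "neutral"

    @property
    def n_conditions(self) -> int:
        return len(self.conditions) * len(self.instruction_levels)

    @property
    def n_boundary_groups(self) -> int:
        if self.boundary_groups == "single":
            return 1
        if self.boundary_groups == "per_congruency_block":
            return len({self.congruency_of(c) for c in self.conditions})
        if self.boundary_groups == "per_instruction":
            return len(set(self.instruction_levels))
        raise ValueError(f"unknown boundary_groups {self.boundary_groups!r}")

    def group_of(self, condition: str, instruction: str) -> str:
        if self.boundary_groups == "single":
            return "all"
        if self.boundary_groups == "per_congruency_block":
            return self.congruency_of(condition)
        return instruction


@dataclass(frozen=True)
class DatasetSpec:
    dataset_id: str
    n_subjects: int
    tasks: tuple
    n_sessions: int = 1


@dataclass(frozen=True)
class StudyDesign:
    datasets: tuple

    @property
    def n_subjects_total(self) -> int:
        return sum(d.n_subjects for d in self.datasets)


SPEED_ACCURACY = ("speed", "accuracy", "both")


def default_design() -> StudyDesign:
    """The five-dataset design: sample sizes 50/103/102/43/69, conflict
    tasks with intermixed or blocked congruency, two speed-accuracy
    manipulated datasets, and a dot-motion task fit with the standard
    diffusion model.  Yields 19 boundary estimates in total."""
    d1 = DatasetSpec("ds1", 50, (
        TaskSpec("flanker", "dmc", ("congruent", "neutral", "incongruent"), 336, "single"),
        TaskSpec("simon", "dmc", ("congruent", "neutral", "incongruent"), 336, "single"),
    ))
    d2 = DatasetSpec("ds2", 103, (
        TaskSpec("flanker", "dmc", ("congruent", "neutral", "incongruent"), 480, "single"),
        TaskSpec("stroop", "dmc", ("congruent", "neutral", "incongruent"), 480, "single"),
    ), n_sessions=2)
    d3 = DatasetSpec("ds3", 102, (
        TaskSpec("simon_blocked", "dmc", ("congruent", "incongruent"), 288,
                 "per_congruency_block"),
        TaskSpec("simon_intermixed", "dmc", ("congruent", "incongruent"), 288, "single"),
    ))
    d4 = DatasetSpec("ds4", 43, (
        TaskSpec("flanker", "dmc", ("congruent", "neutral", "incongruent"), 576,
                 "per_instruction", SPEED_ACCURACY),
        TaskSpec("stroop", "dmc", ("congruent", "neutral", "incongruent"), 576,
                 "per_instruction", SPEED_ACCURACY),
    ), n_sessions=2)
    d5 = DatasetSpec("ds5", 69, (
        TaskSpec("flanker", "dmc", ("congruent", "neutral", "incongruent"), 192,
                 "per_instruction", SPEED_ACCURACY),
        TaskSpec("dotmotion", "ddm", ("motion_left", "motion_right"), 240,
                 "per_instruction", SPEED_ACCURACY),
    ))
    return StudyDesign((d1, d2, d3, d4, d5))


def enumerate_boundary_estimates(design: StudyDesign) -> int:
    """Number of boundary estimates (= correlations per subscale) the
    design yields: one per task boundary group."""
    return sum(t.n_boundary_groups for d in design.datasets for t in d.tasks)


# ---------------------------------------------------------------------------
# Generating configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthConfig:
    """Generating parameters of a synthetic study.

    ``true_corr`` is the latent correlation between the caution trait and
    every impulsivity trait (scalar, or a per-subscale mapping).  The
    boundary is generated on the log scale with ``caution_loading`` and
    ``boundary_noise_sd`` chosen so the between-subject boundary SD is
    about 20% of its mean.  Instruction offsets order the generated truth
    speed < both < accuracy.
    """

    design: StudyDesign = field(default_factory=default_design)
    true_corr: float | dict = 0.0
    trait_intercorr: float = 0.3
    caution_loading: float = 0.18
    boundary_noise_sd: float = 0.09
    boundary_log_mean: float = float(np.log(0.11))
    instruction_offsets: tuple = (("speed", -0.25), ("both", 0.0), ("accuracy", 0.25))
    mu_c_mean: float = 0.40
    mu_c_sd: float = 0.08
    zeta_mean: float = 0.016
    zeta_sd: float = 0.004
    tau_mean: float = 0.03
    alpha: float = 2.0
    ter_mean: float = 0.30
    ter_sd: float = 0.03
    likert_thresholds: tuple = (-1.0, 0.0, 1.0)
    likert_item_noise_sd: float = 1.0
    test_retest: float = 0.8
    seed: int = 0

    def corr_for(self, subscale: str) -> float:
        if isinstance(self.true_corr, dict):
            return float(self.true_corr.get(subscale, 0.0))
        return float(self.true_corr)


def latent_correlation_matrix(config: SynthConfig) -> np.ndarray:
    """6x6 correlation matrix for (caution, 5 impulsivity traits);
    validated positive semi-definite."""
    m = np.full((6, 6), config.trait_intercorr)
    np.fill_diagonal(m, 1.0)
    for j, sub in enumerate(SUBSCALES, start=1):
        m[0, j] = m[j, 0] = config.corr_for(sub)
    eig = np.linalg.eigvalsh(m)
    if eig.min() < -1e-10:
        raise ValueError("latent correlation matrix is not positive semi-definite")
    return m


def draw_latents(config: SynthConfig, n_subjects: int, seed: int) -> pd.DataFrame:
    """Per-subject latent traits ~ MVN(0, R); columns caution + subscales."""
    corr = latent_correlation_matrix(config)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(np.zeros(6), corr, size=n_subjects,
                                    method="cholesky" if np.linalg.eigvalsh(corr).min() > 1e-10 else "svd")
    return pd.DataFrame(draws, columns=["caution"] + list(SUBSCALES))


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------


def true_boundaries(latents: pd.DataFrame, dataset: DatasetSpec, config: SynthConfig,
                    seed: int) -> pd.DataFrame:
    """Generative boundary separation per subject x task x boundary group."""
    rng = np.random.default_rng(child_seed(seed, dataset.dataset_id, "boundaries"))
    offsets = dict(config.instruction_offsets)
    rows = []
    for si in range(dataset.n_subjects):
        caution = float(latents["caution"].iloc[si])
        subj = f"{dataset.dataset_id}_s{si:03d}"
        for task in dataset.tasks:
            groups = sorted({task.group_of(c, i)
                             for c in task.conditions for i in task.instruction_levels})
            for grp in groups:
                off = offsets.get(grp, 0.0)  # instruction groups shift the mean
                log_a = (config.boundary_log_mean + off
                         + config.caution_loading * caution
                         + config.boundary_noise_sd * rng.standard_normal())
                rows.append({"dataset_id": dataset.dataset_id, "subject_id": subj,
                             "task_id": task.task_id, "boundary_group": grp,
                             "boundary": float(np.exp(log_a)), "caution": caution})
    return pd.DataFrame(rows)


def realise_behaviour(latents: pd.DataFrame, dataset: DatasetSpec, config: SynthConfig,
                      seed: int, dt: float = 0.001) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the dataset's trial table from the latent traits.

    Returns ``(trials, truth)`` where truth holds the generative boundary
    per subject x task x group.  Sessions share generating parameters;
    trials are split evenly across sessions.
    """
    truth = true_boundaries(latents, dataset, config, seed)
    rng = np.random.default_rng(child_seed(seed, dataset.dataset_id, "params"))
    frames = []
    for si in range(dataset.n_subjects):
        subj = f"{dataset.dataset_id}_s{si:03d}"
        for task in dataset.tasks:
            mu_c = max(rng.normal(config.mu_c_mean, config.mu_c_sd), 0.05)
            zeta = max(rng.normal(config.zeta_mean, config.zeta_sd), 0.0)
            ter = max(rng.normal(config.ter_mean, config.ter_sd), 0.1)
            t_truth = truth[(truth["subject_id"] == subj) & (truth["task_id"] == task.task_id)]
            a_of = dict(zip(t_truth["boundary_group"], t_truth["boundary"]))
            for cond in task.conditions:
                for instr in task.instruction_levels:
                    a = a_of[task.group_of(cond, instr)]
                    cong = task.congruency_of(cond)
                    n = task.trials_per_condition
                    s = child_seed(seed, dataset.dataset_id, subj, task.task_id, cond, instr)
                    if task.model == "dmc":
                        df = simulate_dmc(
                            DMCParams(boundary_a=a, controlled_drift_mu_c=mu_c,
                                      automatic_amplitude_zeta=zeta,
                                      automatic_tau=config.tau_mean,
                                      automatic_shape_alpha=config.alpha,
                                      nondecision_ter=ter),
                            cong, n, s, dt=dt, subject_id=subj,
                            dataset_id=dataset.dataset_id, task_id=task.task_id,
                            instruction_block=instr)
                    else:
                        df = simulate_ddm(
                            DDMParams(boundary_a=a, drift_v=mu_c, nondecision_ter=ter),
                            n, s, dt=dt, subject_id=subj,
                            dataset_id=dataset.dataset_id, task_id=task.task_id,
                            congruency=cong, instruction_block=instr)
                    # split evenly across sessions (generating params shared)
                    df["session"] = 1 + (np.arange(n) * dataset.n_sessions) // n
                    frames.append(df)
    trials = pd.concat(frames, ignore_index=True)
    return trials, truth


# ---------------------------------------------------------------------------
# Questionnaire
# ---------------------------------------------------------------------------


def realise_questionnaire(latents: pd.DataFrame, subject_ids, config: SynthConfig,
                          seed: int, n_sessions: int = 1,
                          key: pd.DataFrame | None = None) -> pd.DataFrame:
    """Graded-threshold Likert responses from the impulsivity traits.

    For each session the subject's trait is mixed with session-unique
    noise (weight ``sqrt(test_retest)`` on the shared trait), item noise is
    added, and the latent propensity is cut at ``likert_thresholds`` into
    1..4; reverse-coded items are inverted so they behave like the real
    instrument's reversed statements.
    """
    key = default_scoring_key() if key is None else key
    rng = np.random.default_rng(seed)
    r = float(np.clip(config.test_retest, 0.0, 1.0))
    edges = np.asarray(config.likert_thresholds, float)
    subject_ids = list(subject_ids)
    n_subj = len(subject_ids)
    frames = []
    for sess in range(1, n_sessions + 1):
        for sub in SUBSCALES:
            trait = latents[sub].to_numpy(float)[:n_subj]
            sess_trait = (np.sqrt(r) * trait
                          + np.sqrt(1.0 - r) * rng.standard_normal(n_subj))
            items = key[key["subscale"] == sub]
            noise = config.likert_item_noise_sd * rng.standard_normal((n_subj, len(items)))
            propensity = sess_trait[:, None] + noise
            base = 1 + np.searchsorted(edges, propensity.ravel(), side="left").reshape(
                n_subj, len(items))
            resp = np.where(items["reversed"].to_numpy(bool)[None, :], 5 - base, base)
            frames.append(pd.DataFrame({
                "subject_id": np.repeat(subject_ids, len(items)),
                "session": sess,
                "item_id": np.tile(items["item_id"].to_numpy(int), n_subj),
                "response": resp.ravel().astype(int),
            }))
    return (pd.concat(frames, ignore_index=True)
            .sort_values(["subject_id", "session", "item_id"], kind="stable")
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """A generated study: trials, questionnaire, and the generative truth."""

    trials: dict  # dataset_id -> TrialTable
    questionnaire: dict  # dataset_id -> item responses
    truth_boundaries: pd.DataFrame
    latents: dict  # dataset_id -> latent trait table
    config: SynthConfig

    def save(self, outdir) -> list:
        """Write the study as the CSV formats the pipeline reads."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for ds, df in self.trials.items():
            p = outdir / f"trials_{ds}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        quest = pd.concat(self.questionnaire.values(), ignore_index=True)
        p = outdir / "questionnaire.csv"
        quest.to_csv(p, index=False)
        written.append(p)
        p = outdir / "truth_boundaries.csv"
        self.truth_boundaries.to_csv(p, index=False)
        written.append(p)
        return written


def generate_study(config: SynthConfig, behaviour: bool = True,
                   dt: float = 0.001) -> SyntheticStudy:
    """Generate a full multi-dataset study from one master seed.

    ``behaviour=False`` skips trial simulation (latents, truth boundaries
    and questionnaires only) for analyses that start from known
    boundaries.
    """
    trials, quests, truths, latents = {}, {}, [], {}
    for dataset in config.design.datasets:
        lat = draw_latents(config, dataset.n_subjects,
                           child_seed(config.seed, dataset.dataset_id, "latents"))
        latents[dataset.dataset_id] = lat
        subj_ids = [f"{dataset.dataset_id}_s{si:03d}" for si in range(dataset.n_subjects)]
        if behaviour:
            tr, truth = realise_behaviour(lat, dataset, config, config.seed, dt=dt)
            trials[dataset.dataset_id] = tr
        else:
            truth = true_boundaries(lat, dataset, config, config.seed)
        truths.append(truth)
        quests[dataset.dataset_id] = realise_questionnaire(
            lat, subj_ids, config, child_seed(config.seed, dataset.dataset_id, "quest"),
            n_sessions=dataset.n_sessions)
    logger.info("generated study: %d datasets, %d boundary estimates, true_corr=%s",
                len(config.design.datasets),
                enumerate_boundary_estimates(config.design), config.true_corr)
    return SyntheticStudy(trials=trials, questionnaire=quests,
                          truth_boundaries=pd.concat(truths, ignore_index=True),
                          latents=latents, config=config)
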