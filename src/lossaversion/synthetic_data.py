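"""Synthetic cohorts with the statistical structure the analyses assume.

The generator draws subject-level prospect-theory parameters from
zero-truncated group normals (default group means: loss aversion 1.561,
risk attitude 1.033, choice consistency 1.0; all group sds 0.4), then
builds trait scores and neural signals on top of them:

* greed score (GPT, 7-35) declines linearly in ln(lambda) plus noise —
  greedier subjects are less loss averse;
* impulsivity score (IPT, BIS-11 total 30-150) increases with GPT,
  targeting their moderate positive correlation;
* neural loss aversion (NLA, a.u.) increases with ln(lambda); the
  underlying GLM betas are constructed so that -beta_loss - beta_gain
  equals the drawn NLA exactly.

Choices are simulated from the softmax rule trial by trial, and ROI BOLD
series are forward-simulated from the GLM design matrix.  Every source of
randomness flows through explicit seeds.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import roi_glm
from .prospect_model import ChoiceDataset, PTParams, choice_prob
from .task_design import TaskSet, assemble_task

__all__ = [
    "Coupling",
    "CohortSpec",
    "SyntheticCohort",
    "draw_cohort",
    "simulate_choices",
    "simulate_roi_bold",
    "generate_cohort",
]


@dataclasses.dataclass(frozen=True)
class Coupling:
    """A linear coupling: target = intercept + slope * source + noise."""

    intercept: float
    slope: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def from_target_r(cls, r: float, source_sd: float, target_sd: float,
                      intercept_at_source_zero: float) -> "Coupling":
        """Build a coupling that implies correlation ``r`` between source
        and target given their sds; errors if ``|r| > 1`` (infeasible)."""
        if abs(r) > 1:
            raise ValueError(f"implied correlation {r} exceeds 1 in magnitude")
        slope = r * target_sd / source_sd
        noise_sd = target_sd * np.sqrt(1.0 - r * r)
        return cls(intercept=intercept_at_source_zero, slope=slope,
                   noise_sd=noise_sd)

    def apply(self, source: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return (self.intercept + self.slope * source
                + self.noise_sd * rng.standard_normal(source.shape))


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults mirror the modelled study: 25 subjects, group-mean risk
    attitude 1.033 and loss aversion 1.561 (group sds 0.4 are fixture
    choices — the between-subject spreads are not published), greed
    scores negatively coupled to ln(lambda), impulsivity positively
    coupled to greed (target correlation about 0.5), and neural loss
    aversion positively coupled to ln(lambda).
    """

    n_subjects: int = 25
    group_means: tuple[float, float, float] = (1.033, 1.561, 1.0)  # alpha, lam, tau
    group_sds: tuple[float, float, float] = (0.4, 0.4, 0.4)
    gpt_coupling: Coupling = Coupling(22.0, -9.0, 3.5)    # GPT on ln(lam)
    ipt_coupling: Coupling = Coupling(44.0, 0.8, 7.0)     # IPT on GPT
    nla_coupling: Coupling = Coupling(0.3, 0.9, 0.45)     # NLA on ln(lam)
    beta_gain_mean: float = 0.4
    beta_gain_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if any(s <= 0 for s in self.group_sds):
            raise ValueError("group sds must be positive")


@dataclasses.dataclass
class SyntheticCohort:
    """A drawn cohort: per-subject true parameters, traits and signals."""

    spec: CohortSpec
    traits: pd.DataFrame
    task: TaskSet | None = None
    choices: ChoiceDataset | None = None
    bold: dict | None = None

    @property
    def subject_ids(self) -> list[int]:
        return list(self.traits["subject_id"])

    def true_params(self, subject_id: int) -> PTParams:
        row = self.traits.set_index("subject_id").loc[subject_id]
        return PTParams(alpha=row["true_alpha"], lam=row["true_lam"],
                        tau=row["true_tau"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.traits.to_csv(outdir / "traits.csv", index=False)
        if self.task is not None:
            self.task.to_csv(outdir / "task.csv")
        if self.choices is not None:
            self.choices.to_csv(outdir / "choices.csv")
        if self.bold is not None:
            frames = [
                pd.DataFrame({"subject_id": sid,
                              "t_index": np.arange(len(ts)),
                              "bold": ts.values})
                for sid, ts in self.bold.items()
            ]
            pd.concat(frames).to_csv(outdir / "bold.csv", index=False)


def _truncated_normal(rng, mean, sd, size):
    """Normal(mean, sd) truncated to positive values."""
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                         random_state=rng)


def draw_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw subject parameters and traits (no choices or BOLD yet).

    Greed and impulsivity totals are rounded and clipped to their
    questionnaire ranges (7-35 and 30-150).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    alpha, lam, tau = (
        _truncated_normal(rng, m, s, n)
        for m, s in zip(spec.group_means, spec.group_sds)
    )
    ln_lam = np.log(lam)
    gpt = np.clip(np.round(spec.gpt_coupling.apply(ln_lam, rng)), 7, 35)
    ipt = np.clip(np.round(spec.ipt_coupling.apply(gpt, rng)), 30, 150)
    nla = spec.nla_coupling.apply(ln_lam, rng)
    beta_gain = spec.beta_gain_mean + spec.beta_gain_sd * rng.standard_normal(n)
    beta_loss = -(nla + beta_gain)  # so that -beta_loss - beta_gain == nla
    traits = pd.DataFrame({
        "subject_id": np.arange(n),
        "gpt": gpt.astype(int),
        "ipt": ipt.astype(int),
        "true_alpha": alpha,
        "true_lam": lam,
        "true_ln_lam": ln_lam,
        "true_tau": tau,
        "true_beta_gain": beta_gain,
        "true_beta_loss": beta_loss,
        "true_nla": nla,
    })
    return SyntheticCohort(spec=spec, traits=traits)


def simulate_choices(task: TaskSet, params: PTParams, seed: int,
                     subject_id: int = 0) -> ChoiceDataset:
    """Simulate one subject's choices on a task.

    Non-catch trials are Bernoulli draws from the softmax gamble
    probability; catch trials deterministically take the dominant option
    (the engagement check all subjects pass).
    """
    rng = np.random.default_rng(seed)
    choices = np.empty(len(task))
    for i, trial in enumerate(task.trials):
        if trial.condition.is_catch:
            choices[i] = 1.0 if trial.dominant == "gamble" else 0.0
        else:
            choices[i] = float(rng.random() < choice_prob(trial, params))
    return ChoiceDataset.from_task(task, subject_id, choices)


def simulate_roi_bold(task: TaskSet, betas: tuple[float, float, float],
                      tr: float = 2.0, noise_sd: float = 0.0, seed: int = 0,
                      beta_onset: float = 1.0, beta_decision: float = 0.5,
                      rt_s: float = 2.0) -> roi_glm.RoiTimeSeries:
    """Forward-simulate an ROI BOLD series from the GLM design.

    ``betas`` are (beta_gain, beta_loss, beta_sure) on the mean-centred
    modulator columns; white Gaussian noise of sd ``noise_sd`` is added.
    The series covers the task plus a 32 s tail at the given TR.
    """
    beta_gain, beta_loss, beta_sure = (float(b) for b in betas)
    if not all(np.isfinite([beta_gain, beta_loss, beta_sure])):
        raise ValueError("betas must be finite")
    schedule = roi_glm.EventSchedule.from_task(task, rt_s=rt_s)
    duration = task.trials[-1].onset + roi_glm.HRF_DURATION_S + 2 * tr
    n_scans = int(np.ceil(duration / tr))
    X = roi_glm.build_design(schedule, tr, n_scans)
    full = np.array([beta_onset, beta_gain, beta_loss, beta_sure,
                     beta_decision, 0.0])
    y = X @ full
    if noise_sd > 0:
        y = y + noise_sd * np.random.default_rng(seed).standard_normal(n_scans)
    return roi_glm.RoiTimeSeries(values=y, tr=tr)


def generate_cohort(spec: CohortSpec, task: TaskSet | None = None,
                    with_bold: bool = False, bold_noise_sd: float = 0.5,
                    tr: float = 2.0) -> SyntheticCohort:
    """Draw a cohort and simulate its choices (and optionally BOLD).

    Per-subject seeds are spawned deterministically from ``spec.seed``.
    """
    cohort = draw_cohort(spec)
    if task is None:
        task = assemble_task(spec.seed)
    cohort.task = task
    children = np.random.SeedSequence(spec.seed).spawn(2 * spec.n_subjects + 1)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in children]
    frames = []
    bold = {}
    for i, sid in enumerate(cohort.subject_ids):
        ds = simulate_choices(task, cohort.true_params(sid),
                              seed=seeds[i], subject_id=sid)
        frames.append(ds.df)
        if with_bold:
            row = cohort.traits.iloc[i]
            bold[sid] = simulate_roi_bold(
                task,
                (row["true_beta_gain"], row["true_beta_loss"], 0.2),
                tr=tr, noise_sd=bold_noise_sd,
                seed=seeds[spec.n_subjects + i])
    cohort.choices = ChoiceDataset(pd.concat(frames, ignore_index=True))
    if with_bold:
        cohort.bold = bold
    return cohort
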