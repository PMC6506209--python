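"""Prospect-theory valuation and softmax choice rule.

The value function is the standard two-branch power function

    u(x) = x**alpha            for x >= 0
    u(x) = -lam * (-x)**alpha  for x <  0

with risk attitude ``alpha`` (curvature; <1 risk averse, 1 neutral) and
loss aversion ``lam`` (losses weighted ``lam`` times gains).  A dual-risk
variant allows separate exponents ``alpha_plus`` / ``alpha_minus`` in the
gain and loss domains.  A fair gamble's value is the mean of its two
outcome utilities, and the probability of choosing the gamble over the
sure amount is a logistic in the utility difference scaled by the
choice-consistency (inverse-temperature) parameter ``tau``:

    P(gamble) = 1 / (1 + exp(-tau * (u_gamble - u_sure)))

``tau = 0`` is random choice; large ``tau`` approaches maximisation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .task_design import Condition, GambleOption, TaskSet, Trial

__all__ = [
    "PTParams",
    "PTParamsDual",
    "ChoiceDataset",
    "utility",
    "gamble_value",
    "choice_prob",
    "dataset_nll",
]

# cap on |tau * du| before exponentiation; tau is unbounded during sampling
_LOGIT_CAP = 500.0


@dataclasses.dataclass(frozen=True)
class PTParams:
    """Single risk-attitude prospect-theory parameters (all positive)."""

    alpha: float
    lam: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.lam > 0 and self.tau >= 0):
            raise ValueError("require alpha > 0, lam > 0, tau >= 0")

    @property
    def alpha_plus(self) -> float:
        return self.alpha

    @property
    def alpha_minus(self) -> float:
        return self.alpha


@dataclasses.dataclass(frozen=True)
class PTParamsDual:
    """Dual risk-attitude variant: separate exponents per outcome domain."""

    alpha_plus: float
    alpha_minus: float
    lam: float
    tau: float

    def __post_init__(self) -> None:
        ok = (self.alpha_plus > 0 and self.alpha_minus > 0
              and self.lam > 0 and self.tau >= 0)
        if not ok:
            raise ValueError("require alpha_plus, alpha_minus, lam > 0, tau >= 0")


Params = Union[PTParams, PTParamsDual]


def utility(x, params: Params):
    """Prospect-theory utility of a monetary amount (vectorised).

    ``u(0) = 0``; gains are raised to the gain-domain exponent, losses to
    the loss-domain exponent and scaled by ``-lam``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("monetary amounts must be finite")
    ax = np.abs(x)
    pos = x >= 0
    with np.errstate(divide="ignore"):
        u = np.where(pos, ax ** params.alpha_plus,
                     -params.lam * ax ** params.alpha_minus)
    return u if u.ndim else float(u)


def gamble_value(gamble: GambleOption, params: Params) -> float:
    """Expected utility of a fair gamble: mean of the two outcome utilities."""
    return 0.5 * (utility(gamble.outcome1, params) + utility(gamble.outcome2, params))


def choice_prob(trial: Trial, params: Params) -> float:
    """Probability of choosing the gamble over the sure amount.

    Logistic in ``tau * (u_gamble - u_sure)``, computed with a saturating
    guard so extreme utility differences never produce NaN; the result is
    clipped into the open interval (0, 1).
    """
    du = gamble_value(trial.gamble, params) - utility(trial.sure, params)
    x = np.clip(params.tau * du, -_LOGIT_CAP, _LOGIT_CAP)
    p = float(expit(x))
    tiny = np.finfo(float).tiny
    return float(np.clip(p, tiny, 1.0 - np.finfo(float).epsneg))


class ChoiceDataset:
    """Trial-by-trial choices for one or more subjects.

    Wraps a DataFrame with columns ``subject_id, trial_index, condition,
    gamble_out1, gamble_out2, sure, choice`` (0 = sure, 1 = gamble; NaN =
    missed) and optionally ``rt_s``.  Catch trials and missed responses
    are excluded from model fitting via :meth:`modeled`.
    """

    REQUIRED = ("subject_id", "trial_index", "condition",
                "gamble_out1", "gamble_out2", "sure", "choice")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"choice data missing columns: {missing}")
        bad = df["choice"].dropna()
        if not bad.isin([0, 1]).all():
            raise ValueError("choice must be 0 (sure), 1 (gamble) or missing")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.df["subject_id"]))

    def for_subject(self, subject_id) -> "ChoiceDataset":
        return ChoiceDataset(self.df[self.df["subject_id"] == subject_id])

    def modeled(self) -> "ChoiceDataset":
        """Non-catch trials with a recorded choice (the likelihood's data)."""
        m = (~self.df["condition"].isin(["catch_gain", "catch_loss"])
             & self.df["choice"].notna())
        return ChoiceDataset(self.df[m])

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChoiceDataset":
        return cls(pd.read_csv(path))

    @classmethod
    def from_task(cls, task: TaskSet, subject_id, choices: Sequence[float],
                  rts: Sequence[float] | None = None) -> "ChoiceDataset":
        """Pair a task with a per-trial choice vector (NaN = missed)."""
        if len(choices) != len(task):
            raise ValueError("one choice per trial required")
        df = task.to_dataframe()[["trial_index", "condition",
                                  "gamble_out1", "gamble_out2", "sure"]].copy()
        df.insert(0, "subject_id", subject_id)
        df["choice"] = np.asarray(choices, dtype=float)
        if rts is not None:
            df["rt_s"] = np.asarray(rts, dtype=float)
        return cls(df)


def _loglik_terms(df: pd.DataFrame, params: Params) -> np.ndarray:
    u1 = utility(df["gamble_out1"].to_numpy(), params)
    u2 = utility(df["gamble_out2"].to_numpy(), params)
    us = utility(df["sure"].to_numpy(), params)
    x = np.clip(params.tau * (0.5 * (u1 + u2) - us), -_LOGIT_CAP, _LOGIT_CAP)
    chose_gamble = df["choice"].to_numpy() == 1
    # log P(gamble) = -log(1+e^{-x}); log P(sure) = -log(1+e^{x})
    return -np.logaddexp(0.0, np.where(chose_gamble, -x, x))


def dataset_nll(data: ChoiceDataset, params: Params) -> float:
    """Negative log-likelihood of the recorded choices under the model.

    Catch trials and missed responses are excluded.  Raises on an empty
    dataset.
    """
    df = data.modeled().df
    if len(df) == 0:
        raise ValueError("no modeled trials: dataset is empty after exclusions")
    return float(-_loglik_terms(df, params).sum())
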