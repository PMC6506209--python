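"""Construction of the 230-trial mixed-gamble task.

The task crosses four trial types:

* 40 *gain* trials: a sure reward of 1..15 yuan against a 50/50 gamble
  of ``{0, g}`` with ``g`` between 3 and 30 yuan, such that the ratio
  gamble/sure spans 1.5 to 3.4;
* 40 *loss* trials: the exact sign-flip of the gain set;
* 144 *mixed* trials: the full 12 x 12 factorial of gains {8, 10, ..., 30}
  with losses {-5, -7, ..., -27} against a sure amount of zero;
* 6 *catch* trials with an objectively dominant option (engagement check).

Trials are presented in a seeded random order with inter-trial intervals
jittered uniformly on [4, 8] s (mean 6 s), a 5 s response window and a 1 s
choice highlight, split into two equal scanning sessions.
"""

from __future__ import annotations

import dataclasses
import enum
import itertools
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "GambleOption",
    "Trial",
    "TaskSet",
    "build_gain_trials",
    "build_loss_trials",
    "build_mixed_trials",
    "build_catch_trials",
    "assemble_task",
]

N_GAIN = 40
N_LOSS = 40
N_MIXED = 144
N_CATCH = 6
N_TRIALS = N_GAIN + N_LOSS + N_MIXED + N_CATCH

RATIO_MIN = 1.5
RATIO_MAX = 3.4
RESPONSE_WINDOW_S = 5.0
HIGHLIGHT_S = 1.0
ITI_RANGE_S = (4.0, 8.0)


class Condition(str, enum.Enum):
    GAIN = "gain"
    LOSS = "loss"
    MIXED = "mixed"
    CATCH_GAIN = "catch_gain"
    CATCH_LOSS = "catch_loss"

    @property
    def is_catch(self) -> bool:
        return self in (Condition.CATCH_GAIN, Condition.CATCH_LOSS)


@dataclasses.dataclass(frozen=True)
class GambleOption:
    """A fair 50/50 gamble over two monetary outcomes (yuan, signed)."""

    outcome1: float
    outcome2: float
    prob: float = 0.5

    def __post_init__(self) -> None:
        if self.prob != 0.5:
            raise ValueError("gambles are fair coin flips: prob must be exactly 0.5")
        if not (np.isfinite(self.outcome1) and np.isfinite(self.outcome2)):
            raise ValueError("gamble outcomes must be finite")

    @property
    def outcomes(self) -> tuple[float, float]:
        return (self.outcome1, self.outcome2)


@dataclasses.dataclass(frozen=True)
class Trial:
    """One choice between a gamble and a sure amount.

    ``dominant`` is set only on catch trials and names the option
    (``"sure"`` or ``"gamble"``) that first-order stochastically
    dominates (weakly) the other.
    """

    condition: Condition
    gamble: GambleOption
    sure: float
    onset: float = float("nan")
    iti: float = float("nan")
    dominant: str | None = None


def _validate_gain_trial(trial: Trial) -> None:
    if trial.condition is not Condition.GAIN:
        raise ValueError(f"expected a gain trial, got {trial.condition!r}")
    outs = sorted(trial.gamble.outcomes)
    s, g = trial.sure, outs[1]
    if outs[0] != 0:
        raise ValueError("gain gambles must have a zero outcome")
    if not (1 <= s <= 15 and float(s).is_integer()):
        raise ValueError("gain sure amount must be an integer in [1, 15]")
    if not (3 <= g <= 30 and float(g).is_integer()):
        raise ValueError("gain gamble reward must be an integer in [3, 30]")
    if not (RATIO_MIN <= g / s <= RATIO_MAX):
        raise ValueError("gamble/sure ratio outside [1.5, 3.4]")


def build_gain_trials(seed: int) -> list[Trial]:
    """Build the 40 gain trials.

    Three anchor pairs pin the grid — (sure 10, gamble 15) at ratio 1.5,
    (sure 5, gamble 17) at ratio 3.4, and (sure 10, gamble 30) reaching
    the 30-yuan stake ceiling (so the sign-flipped loss set attains the
    maximum single-trial loss) — and the remaining 37 pairs are drawn by
    sampling a sure amount uniformly from {1..15} and a target ratio
    uniformly on [1.5, 3.4], rounding the gamble reward to an integer and
    re-drawing whenever the rounded pair violates a constraint.
    """
    rng = np.random.default_rng(seed)
    # ratios 1.5 and 3.4 exactly, plus the max-stake pair
    pairs: list[tuple[int, int]] = [(10, 15), (5, 17), (10, 30)]
    while len(pairs) < N_GAIN:
        s = int(rng.integers(1, 16))
        ratio = rng.uniform(RATIO_MIN, RATIO_MAX)
        g = int(round(ratio * s))
        if 3 <= g <= 30 and RATIO_MIN <= g / s <= RATIO_MAX:
            pairs.append((s, g))
    trials = [
        Trial(Condition.GAIN, GambleOption(0.0, float(g)), float(s)) for s, g in pairs
    ]
    for t in trials:
        _validate_gain_trial(t)
    return trials


def build_loss_trials(gain_trials: Sequence[Trial]) -> list[Trial]:
    """Sign-flip a gain set into the 40 loss trials."""
    for t in gain_trials:
        _validate_gain_trial(t)
    return [
        Trial(
            Condition.LOSS,
            GambleOption(-t.gamble.outcome1, -t.gamble.outcome2),
            -t.sure,
        )
        for t in gain_trials
    ]


def build_mixed_trials() -> list[Trial]:
    """The 144 mixed trials: full factorial of 12 gains x 12 losses, sure = 0."""
    gains = range(8, 31, 2)  # 8, 10, ..., 30
    losses = range(-5, -28, -2)  # -5, -7, ..., -27
    return [
        Trial(Condition.MIXED, GambleOption(float(g), float(l)), 0.0)
        for g, l in itertools.product(gains, losses)
    ]


def build_catch_trials() -> list[Trial]:
    """Six engagement-check trials with an objectively dominant option.

    Gain-framed: sure ``a`` versus gamble ``{0, a}`` — the sure amount
    weakly dominates.  Loss-framed mirror: sure ``-a`` versus gamble
    ``{0, -a}`` — the gamble weakly dominates (cannot do worse, may
    avoid the loss).
    """
    amounts = (8.0, 10.0, 12.0)
    trials = [
        Trial(Condition.CATCH_GAIN, GambleOption(0.0, a), a, dominant="sure")
        for a in amounts
    ]
    trials += [
        Trial(Condition.CATCH_LOSS, GambleOption(0.0, -a), -a, dominant="gamble")
        for a in amounts
    ]
    return trials


@dataclasses.dataclass(frozen=True)
class TaskSet:
    """The full ordered 230-trial task for one subject/run."""

    trials: tuple[Trial, ...]
    seed: int

    def __post_init__(self) -> None:
        counts = self.condition_counts()
        expected = {"gain": N_GAIN, "loss": N_LOSS, "mixed": N_MIXED, "catch": N_CATCH}
        if counts != expected:
            raise ValueError(f"bad condition counts {counts}, expected {expected}")

    def __len__(self) -> int:
        return len(self.trials)

    def condition_counts(self) -> dict[str, int]:
        counts = {"gain": 0, "loss": 0, "mixed": 0, "catch": 0}
        for t in self.trials:
            key = "catch" if t.condition.is_catch else t.condition.value
            counts[key] += 1
        return counts

    def session(self, index: int) -> int:
        """1-based session label; the first 115 trials form session 1."""
        return 1 if index < N_TRIALS // 2 else 2

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "trial_index": i,
                "session": self.session(i),
                "condition": t.condition.value,
                "gamble_out1": t.gamble.outcome1,
                "gamble_out2": t.gamble.outcome2,
                "sure": t.sure,
                "onset_s": t.onset,
                "iti_s": t.iti,
                "dominant": t.dominant if t.dominant is not None else "",
            }
            for i, t in enumerate(self.trials)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps({"seed": self.seed, "generator": "lossaversion.task_design",
                        "version": 1}, indent=2)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TaskSet":
        path = Path(path)
        df = pd.read_csv(path, keep_default_na=False)
        sidecar = path.with_suffix(".json")
        seed = -1
        if sidecar.exists():
            seed = json.loads(sidecar.read_text()).get("seed", -1)
        trials = tuple(
            Trial(
                Condition(row.condition),
                GambleOption(float(row.gamble_out1), float(row.gamble_out2)),
                float(row.sure),
                onset=float(row.onset_s),
                iti=float(row.iti_s),
                dominant=(row.dominant or None),
            )
            for row in df.itertuples()
        )
        return cls(trials=trials, seed=int(seed))


def assemble_task(seed: int) -> TaskSet:
    """Assemble the full 230-trial task in seeded random order.

    ITIs are uniform on [4, 8] s; onsets accumulate a 5 s response
    window plus 1 s highlight plus the ITI.  Timing is a single
    continuous clock; the session column is a label (first 115 trials
    are session 1).
    """
    ss = np.random.SeedSequence(seed)
    gain_seed, order_seed, iti_seed = (int(s.generate_state(1)[0] % 2**31)
                                      for s in ss.spawn(3))
    gains = build_gain_trials(gain_seed)
    pool = gains + build_loss_trials(gains) + build_mixed_trials() + build_catch_trials()
    order = np.random.default_rng(order_seed).permutation(len(pool))
    itis = np.random.default_rng(iti_seed).uniform(*ITI_RANGE_S, size=len(pool))

    trials = []
    t = 0.0
    for i, idx in enumerate(order):
        base = pool[idx]
        trials.append(dataclasses.replace(base, onset=t, iti=float(itis[i])))
        t += RESPONSE_WINDOW_S + HIGHLIGHT_S + itis[i]
    return TaskSet(trials=tuple(trials), seed=seed)
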