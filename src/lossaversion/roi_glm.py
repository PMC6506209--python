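"""Single-ROI first-level GLM with parametric modulators.

Events at option revelation are modelled as stick functions modulated by
three mean-centred parametric regressors — potential gain of the gamble,
loss magnitude of the gamble (coded as a positive magnitude with an
expected negative-going coefficient), and the sure option value — plus a
decision-onset nuisance regressor and an intercept.  Event columns are
convolved with the canonical double-gamma haemodynamic response function
and fitted by OLS after discrete-cosine high-pass filtering (1/128 Hz
cutoff by default).  The per-subject neural loss-aversion statistic is

    NLA = -beta_loss - beta_gain,

large when responses ramp down steeply with loss magnitude relative to
how steeply they ramp up with gains.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .task_design import Condition, TaskSet

__all__ = [
    "EventSchedule",
    "GlmBetas",
    "RoiTimeSeries",
    "canonical_hrf",
    "build_design",
    "DESIGN_COLUMNS",
    "dct_basis",
    "highpass_dct",
    "ols_betas",
    "fit_roi_glm",
    "neural_loss_aversion",
]

DESIGN_COLUMNS = ("onset", "gain", "loss", "sure", "decision", "intercept")
MICROTIME_BINS = 16
HRF_DURATION_S = 32.0


@dataclasses.dataclass(frozen=True)
class EventSchedule:
    """Per-trial event timing and parametric modulators.

    ``loss`` holds the magnitude of the potential loss (positive, 0 when
    the gamble has no loss arm); ``decision_onsets`` are nuisance events
    at the time of response.
    """

    onsets: np.ndarray
    gain: np.ndarray
    loss: np.ndarray
    sure: np.ndarray
    decision_onsets: np.ndarray

    def __post_init__(self) -> None:
        for name in ("onsets", "gain", "loss", "sure", "decision_onsets"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.diff(self.onsets) >= 0):
            raise ValueError("onsets must be non-decreasing")
        for name in ("gain", "loss", "sure", "decision_onsets"):
            arr = getattr(self, name)
            if arr.shape != self.onsets.shape or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite, one value per onset")

    @classmethod
    def from_task(cls, task: TaskSet, rt_s: float = 2.0) -> "EventSchedule":
        """Build a schedule from a task: gains/losses split by outcome sign.

        ``rt_s`` places the nuisance decision events at onset + a nominal
        response time.
        """
        onsets, gains, losses, sures = [], [], [], []
        for t in task.trials:
            onsets.append(t.onset)
            outs = t.gamble.outcomes
            gains.append(max(max(outs), 0.0))
            losses.append(abs(min(min(outs), 0.0)))
            sures.append(t.sure)
        onsets = np.asarray(onsets)
        return cls(onsets=onsets, gain=np.asarray(gains),
                   loss=np.asarray(losses), sure=np.asarray(sures),
                   decision_onsets=onsets + rt_s)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "trial_index": np.arange(self.onsets.size),
            "onset_s": self.onsets, "gain_mod": self.gain,
            "loss_mod": self.loss, "sure_mod": self.sure,
            "decision_onset_s": self.decision_onsets,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventSchedule":
        df = pd.read_csv(path)
        return cls(onsets=df["onset_s"], gain=df["gain_mod"],
                   loss=df["loss_mod"], sure=df["sure_mod"],
                   decision_onsets=df["decision_onset_s"])


@dataclasses.dataclass(frozen=True)
class GlmBetas:
    beta_onset: float
    beta_gain: float
    beta_loss: float
    beta_sure: float
    beta_decision: float
    beta_intercept: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


@dataclasses.dataclass(frozen=True)
class RoiTimeSeries:
    """BOLD samples on the scanner's TR grid (arbitrary units)."""

    values: np.ndarray
    tr: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    def __len__(self) -> int:
        return self.values.size


def canonical_hrf(tr: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``tr``, peak-normalised.

    Response gamma peaks at 6 s, undershoot gamma at 16 s, with a
    peak-to-undershoot amplitude ratio of 6, over 32 s of support.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    from scipy.stats import gamma

    t = np.arange(0.0, HRF_DURATION_S + 1e-9, tr)
    h = gamma.pdf(t, a=6.0, scale=1.0) - gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    return h / h.max()


def build_design(schedule: EventSchedule, tr: float, n_scans: int,
                 center: bool = True) -> np.ndarray:
    """HRF-convolved design matrix (n_scans x 6).

    Columns: onset stick, gain / loss / sure parametric modulators
    (mean-centred before convolution), decision-onset nuisance stick,
    intercept.  Events are laid on a microtime grid (16 bins per TR),
    convolved, then sampled at scan times.  Identical onsets collapse
    with summed modulators.
    """
    duration = n_scans * tr
    if np.max(schedule.onsets) >= duration or np.max(schedule.decision_onsets) >= duration:
        raise ValueError("schedule does not fit within n_scans * tr")
    dt = tr / MICROTIME_BINS
    n_fine = n_scans * MICROTIME_BINS
    hrf = canonical_hrf(dt)

    def convolved(onsets, heights):
        fine = np.zeros(n_fine)
        bins = np.round(onsets / dt).astype(int)
        np.add.at(fine, bins, heights)
        return np.convolve(fine, hrf)[:n_fine][::MICROTIME_BINS]

    mods = [schedule.gain, schedule.loss, schedule.sure]
    if center:
        mods = [m - m.mean() for m in mods]
    ones = np.ones_like(schedule.onsets)
    cols = [convolved(schedule.onsets, ones)]
    cols += [convolved(schedule.onsets, m) for m in mods]
    cols.append(convolved(schedule.decision_onsets, ones))
    cols.append(np.ones(n_scans))
    return np.column_stack(cols)


def dct_basis(n_scans: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Orthonormal discrete-cosine drift basis (including the constant).

    Contains the constant plus every DCT component with period longer
    than ``cutoff`` seconds.
    """
    if cutoff <= 2 * tr:
        raise ValueError("cutoff must exceed 2 * tr")
    order = int(np.floor(2.0 * n_scans * tr / cutoff))
    n = np.arange(n_scans)
    basis = [np.full(n_scans, 1.0 / np.sqrt(n_scans))]
    for k in range(1, order + 1):
        bk = np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * n + 1) / (2 * n_scans))
        basis.append(bk)
    return np.column_stack(basis)


def highpass_dct(ts: RoiTimeSeries | np.ndarray, tr: float | None = None,
                 cutoff: float = 128.0) -> np.ndarray:
    """Project out slow discrete-cosine drifts (and the mean)."""
    if isinstance(ts, RoiTimeSeries):
        values, tr = ts.values, ts.tr
    else:
        values = np.asarray(ts, dtype=float)
        if tr is None:
            raise ValueError("tr required when passing a bare array")
    X = dct_basis(values.shape[0], tr, cutoff)
    return values - X @ (X.T @ values)


def ols_betas(design: np.ndarray, ts: RoiTimeSeries | np.ndarray,
              column_names=DESIGN_COLUMNS) -> GlmBetas:
    """Least-squares coefficients of the ROI GLM.

    Raises on rank deficiency, naming the dependent columns.
    """
    y = ts.values if isinstance(ts, RoiTimeSeries) else np.asarray(ts, float)
    if y.shape[0] < design.shape[0]:
        raise ValueError("time series shorter than the design")
    y = y[:design.shape[0]]
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        u, s, vt = np.linalg.svd(design)
        null = np.abs(vt[rank:]).max(axis=0)
        bad = [column_names[i] for i in np.nonzero(null > 1e-8)[0]]
        raise ValueError(f"design is rank deficient; dependent columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return GlmBetas(*(float(b) for b in beta))


def fit_roi_glm(schedule: EventSchedule, ts: RoiTimeSeries,
                n_scans: int | None = None, cutoff: float = 128.0) -> GlmBetas:
    """Build the design, high-pass filter data and regressors, and fit.

    The DCT filter is applied consistently to the time series and to all
    design columns except the intercept (filtered columns are mean-free,
    so the intercept stays estimable).
    """
    if n_scans is None:
        n_scans = len(ts)
    X = build_design(schedule, ts.tr, n_scans)
    Xf = X.copy()
    Xf[:, :-1] = np.column_stack(
        [highpass_dct(X[:, j], ts.tr, cutoff) for j in range(X.shape[1] - 1)])
    yf = highpass_dct(RoiTimeSeries(ts.values[:n_scans], ts.tr), cutoff=cutoff)
    return ols_betas(Xf, yf)


def neural_loss_aversion(betas: GlmBetas) -> float:
    """The neural loss-aversion statistic ``-beta_loss - beta_gain``."""
    return -betas.beta_loss - betas.beta_gain
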