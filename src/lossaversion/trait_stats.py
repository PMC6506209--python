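"""Questionnaire scoring and the correlation/regression machinery.

Covers the Dispositional Greed Scale (GPT, 7 items, totals 7-35) and the
Barratt Impulsiveness Scale (IPT, BIS-11, 30 items in three subscales),
risky-choice percentages per condition, Pearson and partial correlation
(the latter used to control impulsivity as a covariate of no interest),
robust regression with a redescending weight function, and one-sample
t-tests.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .prospect_model import ChoiceDataset

__all__ = [
    "load_bis11_map",
    "IDENTITY_BIS11_MAP",
    "score_dgs",
    "score_bis",
    "risky_percentage",
    "CorrResult",
    "pearson_r",
    "partial_r",
    "regression_control",
    "RobustFit",
    "robust_regression",
    "one_sample_t",
    "build_trait_table",
]


def load_bis11_map() -> dict:
    """The packaged BIS-11 subscale/reverse-scoring map (a config file)."""
    text = resources.files("lossaversion").joinpath("data/bis11_map.json").read_text()
    return json.loads(text)


#: A map with the standard subscale assignment but no reverse scoring,
#: for raw-sum totals.
IDENTITY_BIS11_MAP = {
    "subscales": load_bis11_map()["subscales"],
    "reversed": [],
}


def score_dgs(items: Sequence[int]) -> int:
    """Total Dispositional Greed Scale score (7 items rated 1-5)."""
    items = np.asarray(items)
    if items.shape != (7,):
        raise ValueError("DGS has exactly 7 items")
    if not np.all((items >= 1) & (items <= 5)):
        raise ValueError("DGS items must be integers in 1..5")
    return int(items.sum())


def score_bis(items: Sequence[int], subscale_map: dict | None = None) -> dict:
    """BIS-11 subscale totals and grand total (30 items rated 1-5).

    ``subscale_map`` assigns 1-based item numbers to the cognitive,
    motor and non-planning subscales and lists reverse-scored items
    (scored ``6 - response``); defaults to the packaged standard map.
    """
    items = np.asarray(items)
    if items.shape != (30,):
        raise ValueError("BIS-11 has exactly 30 items")
    if not np.all((items >= 1) & (items <= 5)):
        raise ValueError("BIS-11 items must be integers in 1..5")
    m = subscale_map if subscale_map is not None else load_bis11_map()
    assigned = sorted(i for sub in m["subscales"].values() for i in sub)
    if assigned != list(range(1, 31)):
        raise ValueError("subscale map must partition items 1..30")
    scored = items.copy()
    for i in m.get("reversed", []):
        scored[i - 1] = 6 - items[i - 1]
    out = {name: int(scored[np.asarray(sub) - 1].sum())
           for name, sub in m["subscales"].items()}
    out["total"] = int(sum(out.values()))
    return out


def risky_percentage(data: ChoiceDataset, condition: str | None = None) -> float:
    """Percentage of answered non-catch trials on which the gamble was chosen.

    ``condition`` restricts to ``"gain"``, ``"loss"`` or ``"mixed"``;
    ``None`` pools all non-catch trials.  Returns NaN (a missing value,
    not 0) when no trial in the condition was answered.
    """
    df = data.modeled().df
    if condition is not None:
        df = df[df["condition"] == condition]
    if len(df) == 0:
        return float("nan")
    return float(100.0 * (df["choice"] == 1).mean())


@dataclasses.dataclass(frozen=True)
class CorrResult:
    r: float
    t: float
    p: float
    df: int
    n: int


def pearson_r(x, y) -> CorrResult:
    """Pearson correlation with its t statistic and two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-d arrays with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    n = x.size
    df = n - 2
    denom = max(1.0 - r * r, np.finfo(float).tiny)
    t = r * np.sqrt(df / denom)
    return CorrResult(r=float(r), t=float(t), p=float(p), df=df, n=n)


def partial_r(x, y, covariates=None) -> CorrResult:
    """Partial correlation of x and y controlling for covariates.

    Residualises both variables on the covariates (with intercept) and
    correlates the residuals; degrees of freedom are ``n - k - 2`` for
    ``k`` covariates.  With no covariates this is exactly ``pearson_r``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (np.size(covariates) == 0):
        return pearson_r(x, y)
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != x.size:
        c = c.T
    if c.shape[0] != x.size:
        raise ValueError("covariates must have one row per observation")
    n, k = c.shape
    if n <= k + 2:
        raise ValueError("need n > #covariates + 2")
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    df = n - k - 2
    # a variable fully explained by the covariates has no residual signal
    # left to correlate: partial r is 0 by definition
    if np.std(rx) <= 1e-10 * max(np.std(x), 1e-300) or \
            np.std(ry) <= 1e-10 * max(np.std(y), 1e-300):
        return CorrResult(r=0.0, t=0.0, p=1.0, df=df, n=n)
    r = float(np.corrcoef(rx, ry)[0, 1])
    denom = max(1.0 - r * r, np.finfo(float).tiny)
    t = r * np.sqrt(df / denom)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrResult(r=r, t=float(t), p=p, df=df, n=n)


def regression_control(x, y, covariates) -> dict:
    """Covariate control via multiple regression: y ~ x + covariates.

    The t test on the x coefficient is numerically equivalent to the
    partial-correlation test; both formulations are exposed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != x.size:
        c = c.T
    design = sm.add_constant(np.column_stack([x, c]))
    res = sm.OLS(y, design).fit()
    return {"slope": float(res.params[1]), "t": float(res.tvalues[1]),
            "p": float(res.pvalues[1]), "df": int(res.df_resid)}


@dataclasses.dataclass(frozen=True)
class RobustFit:
    slope: float
    intercept: float
    t: float
    p: float
    weights: np.ndarray
    n: int


def robust_regression(x, y, max_iter: int = 100) -> RobustFit:
    """Robust simple regression via IRLS with Tukey's bisquare weights.

    Tuning constant 4.685 (95% Gaussian efficiency), scale estimated by
    MAD.  Returns the slope with its t statistic and two-sided p value;
    raises if the reweighting does not converge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4 or x.shape != y.shape:
        raise ValueError("need equal-length arrays with n >= 4")
    model = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight(4.685))
    res = model.fit(maxiter=max_iter, scale_est="mad")
    if res.fit_history["iteration"] >= max_iter:
        raise RuntimeError("robust regression did not converge")
    return RobustFit(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        t=float(res.tvalues[1]), p=float(res.pvalues[1]),
        weights=np.asarray(res.weights), n=x.size,
    )


def one_sample_t(values, null_mean: float) -> tuple[float, float]:
    """One-sample t-test against ``null_mean`` (two-sided)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need n >= 2")
    if np.std(values) == 0:
        raise ValueError("zero variance input")
    res = stats.ttest_1samp(values, null_mean)
    return float(res.statistic), float(res.pvalue)


def build_trait_table(traits: pd.DataFrame, choices: ChoiceDataset,
                      estimates: pd.DataFrame | None = None,
                      nla: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the per-subject analysis table.

    ``traits`` needs ``subject_id, gpt, ipt``; ``estimates`` (optional)
    contributes ``alpha, lam, ln_lam``; ``nla`` (optional) contributes
    the neural loss aversion column.  Risky-choice percentages per
    condition are computed from ``choices``.
    """
    table = traits[["subject_id", "gpt", "ipt"]].copy()
    rows = []
    for sid in table["subject_id"]:
        sub = choices.for_subject(sid)
        rows.append({
            "subject_id": sid,
            "pct_risky_gain": risky_percentage(sub, "gain"),
            "pct_risky_loss": risky_percentage(sub, "loss"),
            "pct_risky_mixed": risky_percentage(sub, "mixed"),
            "pct_risky_all": risky_percentage(sub),
        })
    table = table.merge(pd.DataFrame(rows), on="subject_id")
    if estimates is not None:
        cols = [c for c in ("subject_id", "alpha", "lam", "ln_lam")
                if c in estimates.columns]
        table = table.merge(estimates[cols], on="subject_id")
    if nla is not None:
        table = table.merge(nla[["subject_id", "nla"]], on="subject_id")
    return table
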