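"""Simple mediation with covariates and bias-corrected bootstrap CIs.

Three ordinary least-squares regressions define the paths (covariates
enter every regression):

    m = i1 + a  x + f  cov          (path a)
    y = i2 + c' x + b m + g cov     (paths b and c')
    y = i3 + c  x + h cov           (total effect c)

The indirect effect is ``a * b`` and, with shared covariates, the OLS
decomposition ``c = c' + a*b`` holds exactly.  Confidence intervals for
the indirect and direct effects come from a bias-corrected (BC, not
accelerated) percentile bootstrap over subjects.  Classification: *full*
mediation when the indirect CI excludes zero but the direct CI does not,
*partial* when both exclude zero, *none* when the indirect CI covers
zero.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "MediationSpec",
    "MediationResult",
    "fit_paths",
    "bc_bootstrap",
    "classify",
    "mediate",
]


@dataclasses.dataclass(frozen=True)
class MediationSpec:
    x: str
    m: str
    y: str
    covariates: tuple[str, ...] = ()
    n_boot: int = 5000
    level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if len({self.x, self.m, self.y}) != 3:
            raise ValueError("x, m, y must be distinct columns")
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")


@dataclasses.dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    ci_ab: tuple[float, float] | None = None
    ci_c_prime: tuple[float, float] | None = None
    classification: str | None = None
    n: int = 0
    n_boot: int = 0
    n_skipped: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("ci_ab", "ci_c_prime"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _design(data: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(data))]
                        + [data[c].to_numpy(dtype=float) for c in cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear predictors among {['intercept', *cols]}")
    return X


def _paths_from_arrays(Xm, m_v, Xy, y_v, Xc):
    """a, b, c', c from the three least-squares fits (batched-friendly)."""
    coef_m = np.linalg.lstsq(Xm, m_v, rcond=None)[0]
    coef_y = np.linalg.lstsq(Xy, y_v, rcond=None)[0]
    coef_c = np.linalg.lstsq(Xc, y_v, rcond=None)[0]
    a = coef_m[1]
    c_prime, b = coef_y[1], coef_y[2]
    c = coef_c[1]
    return a, b, c, c_prime


def fit_paths(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Point estimates of the mediation paths on complete cases."""
    cols = [spec.x, spec.m, spec.y, *spec.covariates]
    df = data[cols].dropna()
    n = len(df)
    if n < len(spec.covariates) + 4:
        raise ValueError("too few complete cases for the path regressions")
    Xm = _design(df, [spec.x, *spec.covariates])
    Xy = _design(df, [spec.x, spec.m, *spec.covariates])
    a, b, c, c_prime = _paths_from_arrays(
        Xm, df[spec.m].to_numpy(float), Xy, df[spec.y].to_numpy(float), Xm)
    return MediationResult(a=float(a), b=float(b), c=float(c),
                           c_prime=float(c_prime), ab=float(a * b), n=n)


def _bc_interval(boot: np.ndarray, point: float, level: float):
    """Bias-corrected percentile interval (no acceleration)."""
    frac_below = np.mean(boot < point)
    z0 = ndtri(np.clip(frac_below, 1e-7, 1 - 1e-7))
    z = ndtri([(1 - level) / 2, (1 + level) / 2])
    lo_q, hi_q = ndtr(2 * z0 + z)
    return (float(np.quantile(boot, lo_q)), float(np.quantile(boot, hi_q)))


def bc_bootstrap(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Resample subjects, refit all paths, and form BC intervals.

    Degenerate resamples (a predictor collapsing to a constant) are
    skipped and counted in ``n_skipped``.  Deterministic given
    ``spec.seed``.
    """
    point = fit_paths(data, spec)
    cols = [spec.x, spec.m, spec.y, *spec.covariates]
    df = data[cols].dropna()
    n = len(df)
    x_v = df[spec.x].to_numpy(float)
    m_v = df[spec.m].to_numpy(float)
    y_v = df[spec.y].to_numpy(float)
    covs = df[list(spec.covariates)].to_numpy(float) if spec.covariates else \
        np.empty((n, 0))

    rng = np.random.default_rng(spec.seed)
    idx = rng.integers(0, n, size=(spec.n_boot, n))
    ones = np.ones((spec.n_boot, n, 1))
    xb = x_v[idx][..., None]
    mb = m_v[idx][..., None]
    cb = covs[idx]
    Xm = np.concatenate([ones, xb, cb], axis=2)
    Xy = np.concatenate([ones, xb, mb, cb], axis=2)

    def batched_ols(X, yv):
        xtx = np.einsum("bij,bik->bjk", X, X)
        xty = np.einsum("bij,bi->bj", X, yv)
        ok = np.linalg.matrix_rank(xtx) == X.shape[2]
        coef = np.full((X.shape[0], X.shape[2]), np.nan)
        if np.any(ok):
            coef[ok] = np.linalg.solve(xtx[ok], xty[ok][..., None])[..., 0]
        return coef, ok

    coef_m, ok_m = batched_ols(Xm, m_v[idx])
    coef_y, ok_y = batched_ols(Xy, y_v[idx])
    ok = ok_m & ok_y
    ab_boot = coef_m[ok, 1] * coef_y[ok, 2]
    cp_boot = coef_y[ok, 1]
    n_skipped = int(spec.n_boot - ok.sum())
    if ok.sum() < max(100, spec.n_boot // 10):
        raise RuntimeError("too many degenerate bootstrap resamples")

    point.ci_ab = _bc_interval(ab_boot, point.ab, spec.level)
    point.ci_c_prime = _bc_interval(cp_boot, point.c_prime, spec.level)
    point.n_boot = spec.n_boot
    point.n_skipped = n_skipped
    point.seed = spec.seed
    return point


def classify(result: MediationResult) -> str:
    """Label the mediation pattern from the two bootstrap intervals."""
    if result.ci_ab is None or result.ci_c_prime is None:
        raise ValueError("classify requires bootstrap intervals")

    def excludes_zero(ci):
        return ci[0] > 0 or ci[1] < 0

    if not excludes_zero(result.ci_ab):
        return "none"
    return "partial" if excludes_zero(result.ci_c_prime) else "full"


def mediate(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Full mediation analysis: paths, BC bootstrap CIs, classification."""
    result = bc_bootstrap(data, spec)
    result.classification = classify(result)
    return result
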