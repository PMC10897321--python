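"""Single-mediator linear mediation with nonparametric bootstrap CIs.

Model: ``M = alpha1 + a X`` and ``Y = alpha2 + c' X + b M`` by ordinary least
squares; the indirect effect (ACME) is ``a * b``, the direct effect (ADE) is
``c'``, and the total effect is their sum (an exact identity for the point
estimates).  Confidence intervals are percentile bootstrap over subjects
resampled with replacement; the bootstrap p is the two-sided proportion
``2 * min(P(est <= 0), P(est >= 0))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

COLLINEARITY_R = 0.999


@dataclass
class PathEstimate:
    coef: float
    se: float
    p: float


@dataclass
class MediationResult:
    a: PathEstimate  # M on X
    b: PathEstimate  # Y on M, adjusting X
    c_prime: PathEstimate  # Y on X, adjusting M (ADE)
    indirect: float  # ACME = a * b
    total: float  # c' + a * b
    ci_indirect: tuple[float, float]
    ci_direct: tuple[float, float]
    ci_total: tuple[float, float]
    p_indirect: float
    p_direct: float
    p_total: float
    n: int
    n_boot: int
    seed: int
    ci_level: float
    standardized: bool = False


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficients, standard errors and two-sided p-values (with intercept)."""
    n, k = X.shape
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - k
    if dof <= 0:
        raise ValueError("not enough observations for OLS")
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    return coef, se, p


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    ones = np.ones_like(x)
    a = np.linalg.lstsq(np.column_stack([ones, x]), m, rcond=None)[0][1]
    cy = np.linalg.lstsq(np.column_stack([ones, x, m]), y, rcond=None)[0]
    return float(a), float(cy[2]), float(cy[1])  # a, b, c'


def _boot_p(draws: np.ndarray) -> float:
    lo = float(np.mean(draws <= 0.0))
    hi = float(np.mean(draws >= 0.0))
    return min(1.0, 2.0 * min(lo, hi))


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    standardize: bool = False,
) -> MediationResult:
    """Estimate ACME / ADE / total effect of X on Y through mediator M."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    x, m, y = x[keep], m[keep], y[keep]
    n = len(x)
    if n < 10:
        raise ValueError(f"need at least 10 complete (X, M, Y) triples, got {n}")
    if abs(np.corrcoef(x, m)[0, 1]) > COLLINEARITY_R:
        raise ValueError("X and M are collinear (|r| > 0.999): mediation paths not identifiable")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)
        m = (m - m.mean()) / m.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)

    ones = np.ones(n)
    coef_a, se_a, p_a = _ols(np.column_stack([ones, x]), m)
    coef_y, se_y, p_y = _ols(np.column_stack([ones, x, m]), y)
    a = PathEstimate(float(coef_a[1]), float(se_a[1]), float(p_a[1]))
    c_prime = PathEstimate(float(coef_y[1]), float(se_y[1]), float(p_y[1]))
    b = PathEstimate(float(coef_y[2]), float(se_y[2]), float(p_y[2]))
    indirect = a.coef * b.coef
    total = c_prime.coef + indirect

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, 3))  # indirect, direct, total
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            ab, bb, cb = _paths(x[idx], m[idx], y[idx])
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate resample
            ab, bb, cb = np.nan, np.nan, np.nan
        boot[i] = (ab * bb, cb, cb + ab * bb)
    boot = boot[np.all(np.isfinite(boot), axis=1)]
    alpha = 1.0 - ci_level
    qs = np.percentile(boot, [100 * alpha / 2.0, 100 * (1 - alpha / 2.0)], axis=0)

    return MediationResult(
        a=a,
        b=b,
        c_prime=c_prime,
        indirect=float(indirect),
        total=float(total),
        ci_indirect=(float(qs[0, 0]), float(qs[1, 0])),
        ci_direct=(float(qs[0, 1]), float(qs[1, 1])),
        ci_total=(float(qs[0, 2]), float(qs[1, 2])),
        p_indirect=_boot_p(boot[:, 0]),
        p_direct=_boot_p(boot[:, 1]),
        p_total=_boot_p(boot[:, 2]),
        n=n,
        n_boot=int(n_boot),
        seed=int(seed),
        ci_level=float(ci_level),
        standardized=bool(standardize),
    )


def to_dict(res: MediationResult) -> dict:
    return {
        "a": vars(res.a),
        "b": vars(res.b),
        "c_prime": vars(res.c_prime),
        "indirect": res.indirect,
        "total": res.total,
        "ci_indirect": list(res.ci_indirect),
        "ci_direct": list(res.ci_direct),
        "ci_total": list(res.ci_total),
        "p_indirect": res.p_indirect,
        "p_direct": res.p_direct,
        "p_total": res.p_total,
        "n": res.n,
        "n_boot": res.n_boot,
        "seed": res.seed,
        "ci_level": res.ci_level,
        "standardized": res.standardized,
    }
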