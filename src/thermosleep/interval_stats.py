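"""Per-bin paired tests with BH-FDR, cumulative sums, effect sizes, correlations.

The timecourse post-hoc is a one-sample two-sided t test of the per-subject
HM - LM delta against zero in each 10-min bin, with Benjamini-Hochberg
adjustment across the bins of one variable (one FDR family per variable).
The condition-level test is the classical repeated-measures decomposition,
which for a two-level within-subject factor coincides with the squared paired
t statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import FIRST_PART_BINS, SECOND_PART_BINS, PairedDelta

logger = logging.getLogger(__name__)

MIN_SUBJECTS_PER_BIN = 3


@dataclass
class TimecourseTestResult:
    variable: str
    table: pd.DataFrame  # per bin: n, mean, sem, t, p, p_adj, sig
    q: float

    @property
    def significant_bins(self) -> list[int]:
        return [int(b) for b in self.table.index[self.table["sig"].fillna(False)]]


@dataclass
class EffectSizes:
    cohens_d: float
    eta_squared: float
    r_squared: float


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    eta_squared: float
    n: int
    study_means: dict | None = None


@dataclass
class PearsonResult:
    r: float
    r_squared: float
    p: float
    n: int


def delta_matrix(deltas: Iterable[PairedDelta], variable: str) -> pd.DataFrame:
    """Subjects x 45 bins matrix of per-bin deltas for one variable."""
    return pd.DataFrame(
        {d.subject_id: d.delta[variable] for d in deltas}
    ).T


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def per_bin_paired_test(
    deltas: pd.DataFrame, variable: str = "", q: float = 0.05
) -> TimecourseTestResult:
    """One-sample t per bin on a subjects x bins delta matrix, BH across bins."""
    n = deltas.notna().sum(axis=0)
    mean = deltas.mean(axis=0)
    sd = deltas.std(axis=0, ddof=1)
    sem = sd / np.sqrt(n)
    too_few = n < MIN_SUBJECTS_PER_BIN
    if too_few.any():
        logger.info(
            "%s: bins %s excluded (< %d subjects)",
            variable or "timecourse",
            list(deltas.columns[too_few]),
            MIN_SUBJECTS_PER_BIN,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / sem
    p = pd.Series(
        2.0 * stats.t.sf(np.abs(t), df=n - 1), index=deltas.columns
    )
    p[too_few | (sd == 0)] = np.nan
    t[too_few] = np.nan
    p_adj = pd.Series(bh_adjust(p), index=deltas.columns)
    table = pd.DataFrame(
        {
            "n": n,
            "mean": mean,
            "sem": sem,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "sig": p_adj < q,
        }
    )
    table.loc[p_adj.isna(), "sig"] = False
    return TimecourseTestResult(variable=variable, table=table, q=q)


def cumsum_timecourse(
    deltas: pd.DataFrame, variable: str = "", q: float = 0.05
) -> TimecourseTestResult:
    """Per-subject running sum over bins, then the same per-bin test + BH."""
    csum = deltas.cumsum(axis=1)
    res = per_bin_paired_test(csum, variable=f"cumsum({variable})" if variable else "cumsum", q=q)
    return res


def cohens_d_paired(
    mean_diff: float | None = None,
    sd_diff: float | None = None,
    diffs: Sequence[float] | None = None,
) -> float:
    """Paired Cohen's d = mean difference / SD of differences."""
    if diffs is not None:
        arr = np.asarray(diffs, dtype=float)
        arr = arr[np.isfinite(arr)]
        mean_diff = float(arr.mean())
        sd_diff = float(arr.std(ddof=1))
    if mean_diff is None or sd_diff is None:
        raise ValueError("provide either (mean_diff, sd_diff) or diffs")
    if sd_diff == 0:
        if mean_diff == 0:
            return 0.0
        raise ZeroDivisionError("Cohen's d undefined: sd_diff = 0 with nonzero mean")
    return float(mean_diff) / float(sd_diff)


def condition_anova(
    hm: Sequence[float],
    lm: Sequence[float],
    study: Sequence[int] | None = None,
) -> AnovaResult:
    """Within-subject MATTRESS effect via the paired-design decomposition.

    For a two-level repeated factor the F statistic equals the square of the
    paired t statistic (df 1, n-1); eta^2 is SS_condition / SS_total over all
    subject x condition cells.  Unpaired subjects are dropped with a log entry.
    """
    hm = np.asarray(hm, dtype=float)
    lm = np.asarray(lm, dtype=float)
    if hm.shape != lm.shape:
        raise ValueError("hm and lm must be the same length (paired subjects)")
    keep = np.isfinite(hm) & np.isfinite(lm)
    if (~keep).any():
        logger.info("condition_anova: %d unpaired/missing subjects excluded", int((~keep).sum()))
    hm, lm = hm[keep], lm[keep]
    n = len(hm)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    d = hm - lm
    sd = d.std(ddof=1)
    if sd == 0:
        F, p = 0.0, 1.0
    else:
        t = d.mean() / (sd / np.sqrt(n))
        F = float(t**2)
        p = float(stats.f.sf(F, 1, n - 1))
    grand = np.concatenate([hm, lm]).mean()
    ss_total = float(((np.concatenate([hm, lm]) - grand) ** 2).sum())
    ss_cond = float(n * d.mean() ** 2 / 2.0)
    eta2 = ss_cond / ss_total if ss_total > 0 else 0.0
    study_means = None
    if study is not None:
        study = np.asarray(study)[keep]
        study_means = {
            int(s): float(d[study == s].mean()) for s in np.unique(study)
        }
    return AnovaResult(F=F, df1=1, df2=n - 1, p=p, eta_squared=eta2, n=n, study_means=study_means)


def f_upper_p(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    if F < 0:
        raise ValueError(f"F must be >= 0, got {F}")
    return float(stats.f.sf(F, df1, df2))


def chi2_upper_p(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if x < 0:
        raise ValueError(f"statistic must be >= 0, got {x}")
    return float(stats.chi2.sf(x, df))


def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with the t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return PearsonResult(r=r, r_squared=r**2, p=p, n=n)


def correlation_table(deltas: Sequence[PairedDelta]) -> pd.DataFrame:
    """Night-part correlation matrix of temperature/HR deltas vs sleep deltas.

    Rows: CBT, PBT, CBT-PBT, HR deltas; columns: (N3, REM) x (first, second)
    part, each cell giving r, p, r^2; per-row N reflects missingness.
    """
    predictors = ("CBT", "PBT", "CBT-PBT", "HR")
    outcomes = ("N3", "REM")
    parts = ("first", "second")
    rows = []
    for pred in predictors:
        for out in outcomes:
            for part in parts:
                x = np.array([d.part_means.loc[part, pred] for d in deltas])
                y = np.array([d.part_means.loc[part, out] for d in deltas])
                res = pearson(x, y)
                rows.append(
                    {
                        "predictor": pred,
                        "outcome": out,
                        "part": part,
                        "n": res.n,
                        "r": res.r,
                        "p": res.p,
                        "r2": res.r_squared,
                    }
                )
    return pd.DataFrame(rows)
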