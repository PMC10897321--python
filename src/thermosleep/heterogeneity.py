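"""Median-split heterogeneity analysis and the study-balance G-test.

Subjects are split at the sample median of their nightly-mean CBT-PBT
gradient response (value < median -> "small", >= median -> "large"); the
split's balance across study subpopulations is assessed with a likelihood-
ratio chi-square (G) test.  Subgroup folded-cycle comparisons and cosinor
fits reuse the parent modules unchanged; the subgroup FDR family is the 11
folded-cycle bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cosinor import PopulationCosinor, population_cosinor
from .cycle_spectral import FoldedCycle, fold_cycles, folded_matrix
from .interval_stats import TimecourseTestResult, chi2_upper_p, per_bin_paired_test

SMALL, LARGE = "small", "large"


@dataclass
class GTestResult:
    g2: float
    df: int
    p: float
    table: pd.DataFrame


@dataclass
class SubgroupCycleResult:
    label: str
    n: int
    tests: dict[str, TimecourseTestResult]  # per variable, 11-bin family
    cosinor: dict[str, PopulationCosinor]


@dataclass
class MedianSplitResult:
    labels: pd.Series  # subject_id -> 'small' | 'large'
    median: float
    contingency: GTestResult | None
    subgroups: dict[str, SubgroupCycleResult]


def median_split(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Label subjects 'small' (< median) or 'large' (>= median).

    Subjects with undefined (NaN) values are dropped.  With even n and
    distinct values the groups have equal size; ties at the median all go to
    'large' (documented tie rule).
    """
    s = pd.Series(values, dtype=float).dropna()
    if len(s) < 2:
        raise ValueError(f"need at least 2 defined values, got {len(s)}")
    if s.nunique() == 1:
        raise ValueError("median split undefined: all values identical")
    med = float(s.median())
    return pd.Series(np.where(s < med, SMALL, LARGE), index=s.index, name="median_group")


def g_test(table: pd.DataFrame | np.ndarray) -> GTestResult:
    """Likelihood-ratio test of independence: G^2 = 2 sum O ln(O/E)."""
    tab = pd.DataFrame(table).astype(float)
    obs = tab.to_numpy()
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row/column margin: expected counts undefined")
    expected = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g2 = float(2.0 * terms.sum())
    g2 = max(g2, 0.0)
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return GTestResult(g2=g2, df=df, p=chi2_upper_p(g2, df), table=tab)


def study_balance_test(labels: pd.Series, studies: Mapping[str, int]) -> GTestResult:
    """STUDY x MEDIAN contingency G-test."""
    df = pd.DataFrame({"group": labels, "study": pd.Series(studies)}).dropna()
    table = pd.crosstab(df["study"], df["group"])
    for g in (SMALL, LARGE):
        if g not in table.columns:
            table[g] = 0
    return g_test(table[[SMALL, LARGE]])


def subgroup_cycle_comparison(
    delta_timecourses: Mapping[str, Mapping[str, Sequence[float]]],
    labels: pd.Series,
    period_min: float = 110.0,
    q: float = 0.05,
) -> dict[str, SubgroupCycleResult]:
    """Folded-cycle per-bin tests + population cosinor per median subgroup.

    ``delta_timecourses[variable][subject_id]`` is a 45-bin delta timecourse.
    """
    out: dict[str, SubgroupCycleResult] = {}
    for label in (SMALL, LARGE):
        members = list(labels.index[labels == label])
        tests: dict[str, TimecourseTestResult] = {}
        cos: dict[str, PopulationCosinor] = {}
        for var, per_subject in delta_timecourses.items():
            folded = [
                fold_cycles(per_subject[sid], period_min=period_min, variable=var)
                for sid in members
                if sid in per_subject
            ]
            mat = folded_matrix(folded)
            tests[var] = per_bin_paired_test(mat, variable=f"{var}[{label}]", q=q)
            cos[var] = population_cosinor(
                [f.cycle_mean for f in folded],
                t_min=folded[0].bin_midpoints_min,
                period_min=period_min,
            )
        out[label] = SubgroupCycleResult(
            label=label, n=len(members), tests=tests, cosinor=cos
        )
    return out


def median_split_analysis(
    split_values: Mapping[str, float] | pd.Series,
    studies: Mapping[str, int] | None = None,
    delta_timecourses: Mapping[str, Mapping[str, Sequence[float]]] | None = None,
    period_min: float = 110.0,
    q: float = 0.05,
) -> MedianSplitResult:
    labels = median_split(split_values)
    contingency = study_balance_test(labels, studies) if studies is not None else None
    subgroups = (
        subgroup_cycle_comparison(delta_timecourses, labels, period_min=period_min, q=q)
        if delta_timecourses is not None
        else {}
    )
    med = float(pd.Series(split_values, dtype=float).dropna().median())
    return MedianSplitResult(
        labels=labels, median=med, contingency=contingency, subgroups=subgroups
    )
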