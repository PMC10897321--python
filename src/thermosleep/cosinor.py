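"""Fixed-period cosinor fits, population rhythmicity test, phase differences.

Per subject, ``y = M + beta cos(omega t) + gamma sin(omega t)`` is fitted by
least squares at the fixed cycle period (110 min by default).  The population
layer averages (M, beta, gamma) across subjects; its amplitude and acrophase
derive from the mean coefficient vector.  Rhythmicity is the population-mean
cosinor zero-amplitude test: a Hotelling T^2 on the bivariate mean of
(beta_i, gamma_i) against (0, 0), with F = ((n-2) / (2(n-1))) T^2 on
(2, n-2) degrees of freedom.  Phase differences are wrapped to half a period,
(-period/2, +period/2].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_PERIOD_MIN = 110.0
#: relative amplitude below which the acrophase is treated as undefined
AMPLITUDE_TOL_REL = 1e-6


@dataclass
class CosinorFit:
    period_min: float
    mesor: float
    beta: float  # cos coefficient
    gamma: float  # sin coefficient

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.beta, self.gamma))

    @property
    def acrophase_min(self) -> float:
        """Time of the fitted maximum, minutes after cycle start in [0, period)."""
        phi = np.arctan2(self.gamma, self.beta)
        return float((self.period_min * phi / (2.0 * np.pi)) % self.period_min)

    def acrophase_defined(self, scale: float = 1.0) -> bool:
        return self.amplitude > AMPLITUDE_TOL_REL * max(scale, np.finfo(float).tiny)


@dataclass
class RhythmicityTest:
    statistic: float  # F statistic
    df1: int
    df2: int
    p: float
    n: int


@dataclass
class PopulationCosinor:
    fit: CosinorFit  # from the mean coefficient vector
    subject_fits: list[CosinorFit]
    rhythmicity: RhythmicityTest


@dataclass
class PhaseDifference:
    per_subject_min: np.ndarray  # wrapped differences, (-period/2, period/2]
    mean_min: float
    sd_min: float
    p: float
    cohens_d: float
    n: int
    period_min: float


def fit_cosinor(
    y: Sequence[float],
    t_min: Sequence[float] | None = None,
    period_min: float = DEFAULT_PERIOD_MIN,
) -> CosinorFit:
    """Least-squares single-component cosinor at a fixed period.

    ``t_min`` defaults to folded-bin midpoints (5, 15, ..., minutes after
    cycle start) matching the folded-cycle layout.
    """
    y = np.asarray(y, dtype=float)
    if t_min is None:
        t_min = (np.arange(len(y)) + 0.5) * 10.0
    t = np.asarray(t_min, dtype=float)
    if len(y) != len(t):
        raise ValueError("y and t_min must have the same length")
    if len(y) < 3:
        raise ValueError(f"need at least 3 time points, got {len(y)}")
    omega = 2.0 * np.pi / period_min
    X = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("singular cosinor design (time points do not span the period)")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return CosinorFit(period_min=float(period_min), mesor=float(coef[0]), beta=float(coef[1]), gamma=float(coef[2]))


def rhythmicity_test(
    betas: Sequence[float], gammas: Sequence[float]
) -> RhythmicityTest:
    """Hotelling T^2 zero-amplitude test on the population of (beta, gamma)."""
    b = np.asarray(betas, dtype=float)
    g = np.asarray(gammas, dtype=float)
    if b.shape != g.shape:
        raise ValueError("betas and gammas must have the same length")
    n = len(b)
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    m = np.array([b.mean(), g.mean()])
    S = np.cov(np.vstack([b, g]), ddof=1)
    det = np.linalg.det(S)
    if not np.isfinite(det) or det <= 0:
        if np.allclose(m, 0.0):
            # no signal and no spread: rhythmicity cannot be claimed
            return RhythmicityTest(statistic=0.0, df1=2, df2=n - 2, p=1.0, n=n)
        raise ValueError("degenerate coefficient covariance; rhythmicity test undefined")
    t2 = float(n * m @ np.linalg.solve(S, m))
    F = (n - 2) / (2.0 * (n - 1)) * t2
    p = float(stats.f.sf(F, 2, n - 2))
    return RhythmicityTest(statistic=float(F), df1=2, df2=n - 2, p=p, n=n)


def population_cosinor(
    series: Sequence[Sequence[float]],
    t_min: Sequence[float] | None = None,
    period_min: float = DEFAULT_PERIOD_MIN,
) -> PopulationCosinor:
    """Per-subject cosinor fits plus the population-mean fit and rhythmicity."""
    fits = [fit_cosinor(y, t_min=t_min, period_min=period_min) for y in series]
    mean_fit = CosinorFit(
        period_min=float(period_min),
        mesor=float(np.mean([f.mesor for f in fits])),
        beta=float(np.mean([f.beta for f in fits])),
        gamma=float(np.mean([f.gamma for f in fits])),
    )
    rhythm = rhythmicity_test([f.beta for f in fits], [f.gamma for f in fits])
    return PopulationCosinor(fit=mean_fit, subject_fits=fits, rhythmicity=rhythm)


def wrap_phase(diff_min: float | np.ndarray, period_min: float = DEFAULT_PERIOD_MIN) -> np.ndarray:
    """Wrap phase differences to (-period/2, +period/2]."""
    half = period_min / 2.0
    wrapped = np.mod(np.asarray(diff_min, dtype=float) + half, period_min) - half
    # map the -half boundary to +half so the interval is half-open on the left
    wrapped = np.where(np.isclose(wrapped, -half), half, wrapped)
    return wrapped


def phase_difference(
    fits_a: Sequence[CosinorFit],
    fits_b: Sequence[CosinorFit],
    amplitude_scale: float = 1.0,
) -> PhaseDifference:
    """Per-subject wrapped acrophase difference (A - B), with paired test.

    Subjects for whom either fit's amplitude is below tolerance (acrophase
    undefined) are excluded pairwise and logged.
    """
    if len(fits_a) != len(fits_b):
        raise ValueError("fit lists must be paired (same subjects, same order)")
    period = fits_a[0].period_min if fits_a else DEFAULT_PERIOD_MIN
    diffs = []
    excluded = 0
    for fa, fb in zip(fits_a, fits_b):
        if fa.period_min != fb.period_min:
            raise ValueError("fits have different periods")
        if not (fa.acrophase_defined(amplitude_scale) and fb.acrophase_defined(amplitude_scale)):
            excluded += 1
            continue
        diffs.append(wrap_phase(fa.acrophase_min - fb.acrophase_min, fa.period_min))
    if excluded:
        logger.info("phase_difference: %d subjects excluded (undefined acrophase)", excluded)
    if len(diffs) < 3:
        raise ValueError(f"fewer than 3 usable subjects ({len(diffs)})")
    d = np.asarray(diffs, dtype=float)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        p = 0.0 if mean != 0 else 1.0
        cd = 0.0 if mean == 0 else np.inf
    else:
        tstat, p = stats.ttest_1samp(d, 0.0)
        p = float(p)
        cd = mean / sd
    return PhaseDifference(
        per_subject_min=d,
        mean_min=mean,
        sd_min=sd,
        p=p,
        cohens_d=float(cd),
        n=len(d),
        period_min=float(period),
    )
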