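"""NREM-REM cycle period estimation via detrended periodogram, and cycle folding.

The spectral window is bins 1..44 of the 45-bin grid (minutes 10-450 after
lights-off; the first 10 min are omitted), n = 44 samples at 10-min spacing.
Power is the squared DFT amplitude scaled by (n/2)^2, so a unit-amplitude
on-grid cosine yields peak power 1 in (min/10 min)^2 units.  No tapering or
zero-padding is applied: reported frequencies are exactly k/440 per minute.

Folding reshapes the same 44 bins into consecutive cycles of the (fixed or
data-derived) period and averages positionally; with the default 110-min
period this is 4 cycles x 11 bins, origin at minute 10 for every subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

SPECTRAL_BINS = tuple(range(1, 45))  # bins used for spectra and folding
N_SPECTRAL = 44
BIN_MIN = 10.0
WINDOW_MIN = N_SPECTRAL * BIN_MIN  # 440


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray  # cycles per minute, k / 440 for k = 1..22
    power: np.ndarray  # squared amplitude, (units)^2
    variable: str = ""
    condition: str = ""


@dataclass
class FoldedCycle:
    per_cycle: np.ndarray  # shape (n_cycles, bins_per_cycle)
    cycle_mean: np.ndarray  # shape (bins_per_cycle,)
    period_min: float
    variable: str = ""

    @property
    def n_cycles(self) -> int:
        return self.per_cycle.shape[0]

    @property
    def bin_midpoints_min(self) -> np.ndarray:
        """Within-cycle time (minutes after cycle start) of each folded bin."""
        nb = self.per_cycle.shape[1]
        return (np.arange(nb) + 0.5) * BIN_MIN


@dataclass
class GroupSpectrum:
    frequencies: np.ndarray
    mean_power: np.ndarray
    sem_power: np.ndarray
    peak_frequency: float
    peak_period_min: float
    n: int
    variable: str = ""
    condition: str = ""


def detrend_linear(x: np.ndarray) -> np.ndarray:
    """Subtract the least-squares line."""
    x = np.asarray(x, dtype=float)
    t = np.arange(len(x), dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    return x - (slope * t + intercept)


def spectral_window(timecourse45: Sequence[float]) -> np.ndarray:
    """Extract bins 1..44 from a 45-bin timecourse."""
    x = np.asarray(timecourse45, dtype=float)
    if len(x) != 45:
        raise ValueError(f"expected a 45-bin timecourse, got length {len(x)}")
    return x[1:]


def periodogram(timecourse: Sequence[float], variable: str = "", condition: str = "") -> PowerSpectrum:
    """Squared-amplitude spectrum of the linearly detrended 44-bin series."""
    x = np.asarray(timecourse, dtype=float)
    if len(x) != N_SPECTRAL:
        raise ValueError(f"expected {N_SPECTRAL} bins, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("timecourse contains non-finite values")
    xd = detrend_linear(x)
    X = np.fft.rfft(xd)
    k = np.arange(1, N_SPECTRAL // 2 + 1)
    power = (np.abs(X[1:]) / (N_SPECTRAL / 2.0)) ** 2
    freqs = k / WINDOW_MIN
    return PowerSpectrum(frequencies=freqs, power=power, variable=variable, condition=condition)


def group_spectrum(
    spectra: Sequence[PowerSpectrum],
    max_period_min: float = WINDOW_MIN / 2.0,
    variable: str = "",
    condition: str = "",
) -> GroupSpectrum:
    """Pointwise mean +/- SEM spectrum and the peak of the mean power.

    The peak search excludes k = 0 by construction and is restricted to
    periods no longer than half the window; ties break toward the lower
    frequency.
    """
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    freqs = spectra[0].frequencies
    P = np.vstack([s.power for s in spectra])
    mean = P.mean(axis=0)
    sem = P.std(axis=0, ddof=1) / np.sqrt(len(spectra)) if len(spectra) > 1 else np.zeros_like(mean)
    eligible = (1.0 / freqs) <= max_period_min + 1e-12
    idx_eligible = np.flatnonzero(eligible)
    best = idx_eligible[np.argmax(mean[idx_eligible])]  # argmax takes first max: lower freq
    return GroupSpectrum(
        frequencies=freqs,
        mean_power=mean,
        sem_power=sem,
        peak_frequency=float(freqs[best]),
        peak_period_min=float(1.0 / freqs[best]),
        n=len(spectra),
        variable=variable,
        condition=condition,
    )


def fold_cycles(
    timecourse45: Sequence[float], period_min: float = 110.0, variable: str = ""
) -> FoldedCycle:
    """Fold bins 1..44 into consecutive cycles of ``period_min`` and average.

    Requires the period to be a whole number of 10-min bins dividing the
    440-min window exactly.
    """
    x = spectral_window(timecourse45)
    bins_per_cycle = period_min / BIN_MIN
    if abs(bins_per_cycle - round(bins_per_cycle)) > 1e-9:
        raise ValueError(f"period {period_min} min is not a whole number of 10-min bins")
    bins_per_cycle = int(round(bins_per_cycle))
    if N_SPECTRAL % bins_per_cycle != 0:
        raise ValueError(
            f"period {period_min} min does not divide the {WINDOW_MIN:.0f}-min window"
        )
    n_cycles = N_SPECTRAL // bins_per_cycle
    per_cycle = x.reshape(n_cycles, bins_per_cycle)
    return FoldedCycle(
        per_cycle=per_cycle,
        cycle_mean=per_cycle.mean(axis=0),
        period_min=float(period_min),
        variable=variable,
    )


def folded_matrix(folded: Sequence[FoldedCycle]) -> pd.DataFrame:
    """Subjects x folded-bin matrix of cycle-average values."""
    return pd.DataFrame([f.cycle_mean for f in folded])
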