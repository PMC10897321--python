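"""Reading, 10-min binning, paired deltas and nocturnal summaries.

Everything downstream operates on the 45-bin grid: bin ``b`` covers minutes
``[10b, 10(b+1))`` after lights-off (0-based, half-open).  Stage minutes are
reported per 10 min with W and N1 pooled; physiological variables are in-bin
means (PBT and MAT averaged over their sensors with equal weights) plus the
derived CBT-PBT gradient.  The night is split into a first ([0, 190) min) and
second ([190, 450) min) part; the boundary bin 19 belongs to the second part.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import (
    CONDITIONS,
    PHYSIO_SAMPLING,
    STAGES,
    CohortSpec,
    NightRecording,
    PhysioSeries,
    SubjectData,
)

logger = logging.getLogger(__name__)

N_BINS = 45
BIN_MIN = 10.0
BIN_S = 600
N_EPOCHS = 900
EPOCHS_PER_BIN = 20
PART_BOUNDARY_MIN = 190.0
FIRST_PART_BINS = tuple(range(0, 19))  # minutes [0, 190)
SECOND_PART_BINS = tuple(range(19, 45))  # minutes [190, 450)

STAGE_VARIABLES = ("W+N1", "N2", "N3", "REM")
PHYSIO_VARIABLES = ("HR", "MAT", "PBT", "CBT", "CBT-PBT")
ALL_VARIABLES = ("HR", "MAT", "PBT", "CBT", "CBT-PBT", "W+N1", "N2", "N3", "REM")

#: fraction of expected samples below which a bin is invalid
MIN_BIN_SAMPLE_FRAC = 0.5
#: fraction of invalid bins above which a subject's variable is dropped
MAX_INVALID_BIN_FRAC = 0.2


class LoadError(ValueError):
    """Raised for malformed hypnogram / physio input files."""


@dataclass
class BinnedTimecourse:
    """One subject-night on the 45 x 10-min analysis grid."""

    subject_id: str
    condition: str
    stage_min: pd.DataFrame  # 45 x (W+N1, N2, N3, REM), minutes per 10 min
    physio: pd.DataFrame  # 45 x (HR, MAT, PBT, CBT, CBT-PBT)
    valid: pd.DataFrame  # 45 x physio columns, bool

    def variable(self, name: str) -> pd.Series:
        if name in self.stage_min.columns:
            return self.stage_min[name]
        return self.physio[name]

    def valid_mask(self, name: str) -> pd.Series:
        if name in self.stage_min.columns:
            return pd.Series(True, index=self.stage_min.index)
        return self.valid[name]


@dataclass
class PairedDelta:
    """Per-subject HM - LM difference timecourses and summaries."""

    subject_id: str
    delta: pd.DataFrame  # 45 x ALL_VARIABLES, NaN where either night invalid
    nightly_mean: pd.Series  # per-variable mean over jointly valid bins
    part_means: pd.DataFrame  # index ('first', 'second') x ALL_VARIABLES


def pool_stage(stage: str) -> str:
    return "W+N1" if stage in ("W", "N1") else stage


def bin_hypnogram(stages: Sequence[str]) -> pd.DataFrame:
    """Stage minutes per 10-min bin, W and N1 pooled; each bin sums to 10."""
    stages = np.asarray(stages, dtype=object)
    if len(stages) != N_EPOCHS:
        raise ValueError(f"expected {N_EPOCHS} epochs of 30 s, got {len(stages)}")
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage labels: {sorted(unknown)}")
    out = pd.DataFrame(0.0, index=range(N_BINS), columns=list(STAGE_VARIABLES))
    epoch_min = 0.5
    bins = np.arange(N_EPOCHS) // EPOCHS_PER_BIN
    for var in STAGE_VARIABLES:
        member = np.array([pool_stage(s) == var for s in stages], dtype=float)
        out[var] = np.bincount(bins, weights=member, minlength=N_BINS) * epoch_min
    return out


def bin_physio(
    physio: Mapping[str, PhysioSeries],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """In-bin means per variable plus validity flags and the CBT-PBT gradient.

    PBT/MAT are equal-weight means over their sensors' in-bin samples.  A bin
    with fewer than half of its expected samples is flagged invalid; an empty
    or absent variable yields an all-invalid column (with a warning).
    """
    means = pd.DataFrame(np.nan, index=range(N_BINS), columns=list(PHYSIO_VARIABLES))
    valid = pd.DataFrame(False, index=range(N_BINS), columns=list(PHYSIO_VARIABLES))
    for var in ("HR", "MAT", "PBT", "CBT"):
        series = physio.get(var)
        if series is None or series.values.size == 0:
            logger.warning("physio variable %s empty: all bins invalid", var)
            continue
        times = np.asarray(series.times_s, dtype=float)
        if times.size and (times.min() < 0 or times.max() >= N_BINS * BIN_S):
            raise ValueError(f"{var}: sample times outside [0, {N_BINS * BIN_S}) s")
        bin_idx = (times // BIN_S).astype(int)
        n_sensors = series.values.shape[0]
        counts = np.bincount(bin_idx, minlength=N_BINS) * n_sensors
        sums = np.zeros(N_BINS)
        for s in range(n_sensors):
            sums += np.bincount(bin_idx, weights=series.values[s], minlength=N_BINS)
        with np.errstate(invalid="ignore"):
            means[var] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        step, expected_sensors = PHYSIO_SAMPLING.get(var, (None, n_sensors))
        expected = (BIN_S // step) * n_sensors if step else counts.max()
        valid[var] = counts >= MIN_BIN_SAMPLE_FRAC * max(expected, 1)
    means["CBT-PBT"] = means["CBT"] - means["PBT"]
    valid["CBT-PBT"] = valid["CBT"] & valid["PBT"]
    means[~valid] = np.nan
    return means, valid


def bin_night(recording: NightRecording) -> BinnedTimecourse:
    stage_min = bin_hypnogram(recording.hypnogram)
    physio, valid = bin_physio(recording.physio)
    return BinnedTimecourse(
        subject_id=recording.subject_id,
        condition=recording.condition,
        stage_min=stage_min,
        physio=physio,
        valid=valid,
    )


def nocturnal_summary(btc: BinnedTimecourse) -> pd.DataFrame:
    """Subject-level mean/SD/min/max over valid bins for every variable.

    A variable with more than ``MAX_INVALID_BIN_FRAC`` invalid bins is marked
    missing (all-NaN row), which propagates as a reduced N at the group layer.
    """
    rows = {}
    for var in ALL_VARIABLES:
        vals = btc.variable(var)
        mask = btc.valid_mask(var)
        ok = vals[mask].dropna()
        if len(ok) == 0 or (1.0 - mask.mean()) > MAX_INVALID_BIN_FRAC:
            rows[var] = dict(mean=np.nan, sd=np.nan, min=np.nan, max=np.nan)
            continue
        rows[var] = dict(
            mean=float(ok.mean()),
            sd=float(ok.std(ddof=1)) if len(ok) > 1 else 0.0,
            min=float(ok.min()),
            max=float(ok.max()),
        )
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(ALL_VARIABLES)]


def group_summary(summaries: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Group layer: mean/SD/min/max across the subjects' nocturnal means."""
    means = pd.DataFrame({i: s["mean"] for i, s in enumerate(summaries)}).T
    out = pd.DataFrame(
        {
            "n": means.notna().sum(),
            "mean": means.mean(),
            "sd": means.std(ddof=1),
            "min": means.min(),
            "max": means.max(),
        }
    )
    return out.loc[[v for v in ALL_VARIABLES if v in out.index]]


def part_bins(boundary_min: float = PART_BOUNDARY_MIN) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """First/second night-part bin indices for a half-open boundary (minutes).

    The bin containing the boundary minute belongs to the second part.
    """
    n_first = int(boundary_min // BIN_MIN)
    if not 1 <= n_first < N_BINS:
        raise ValueError(f"boundary {boundary_min} min outside the night")
    return tuple(range(0, n_first)), tuple(range(n_first, N_BINS))


def paired_delta(
    hm: BinnedTimecourse, lm: BinnedTimecourse, boundary_min: float = PART_BOUNDARY_MIN
) -> PairedDelta:
    """Per-bin, nightly and night-part HM - LM differences for one subject."""
    first_bins, second_bins = part_bins(boundary_min)
    if hm.subject_id != lm.subject_id:
        raise ValueError(f"subject mismatch: {hm.subject_id!r} vs {lm.subject_id!r}")
    if hm.condition != "HM" or lm.condition != "LM":
        raise ValueError(
            f"condition mismatch: expected (HM, LM), got ({hm.condition!r}, {lm.condition!r})"
        )
    delta = pd.DataFrame(index=range(N_BINS), columns=list(ALL_VARIABLES), dtype=float)
    for var in ALL_VARIABLES:
        both = hm.valid_mask(var) & lm.valid_mask(var)
        d = hm.variable(var) - lm.variable(var)
        delta[var] = d.where(both)

    nightly = pd.Series(index=list(ALL_VARIABLES), dtype=float)
    parts = pd.DataFrame(
        index=["first", "second"], columns=list(ALL_VARIABLES), dtype=float
    )
    for var in ALL_VARIABLES:
        col = delta[var]
        if col.notna().mean() >= 1.0 - MAX_INVALID_BIN_FRAC:
            nightly[var] = col.mean()
        else:
            nightly[var] = np.nan
        parts.loc["first", var] = col.iloc[list(first_bins)].mean()
        parts.loc["second", var] = col.iloc[list(second_bins)].mean()
    return PairedDelta(
        subject_id=hm.subject_id, delta=delta, nightly_mean=nightly, part_means=parts
    )


# ---------------------------------------------------------------------------
# CSV / manifest I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: Sequence[SubjectData], outdir: str | Path, spec: CohortSpec) -> dict:
    """Write hypnogram.csv, physio.csv and manifest.json for a cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hyp_rows = []
    phys_rows = []
    for profile, hm, lm in cohort:
        for rec in (hm, lm):
            for e, stage in enumerate(rec.hypnogram):
                hyp_rows.append((profile.subject_id, profile.study, rec.condition, e, stage))
            for var, series in rec.physio.items():
                for s in range(series.values.shape[0]):
                    col = series.values[s]
                    phys_rows.extend(
                        zip(
                            [profile.subject_id] * len(col),
                            [profile.study] * len(col),
                            [rec.condition] * len(col),
                            [var] * len(col),
                            [s] * len(col),
                            series.times_s,
                            col,
                        )
                    )
    pd.DataFrame(
        hyp_rows, columns=["subject_id", "study", "condition", "epoch_index", "stage"]
    ).to_csv(outdir / "hypnogram.csv", index=False)
    pd.DataFrame(
        phys_rows,
        columns=["subject_id", "study", "condition", "variable", "sensor_id", "time_s", "value"],
    ).to_csv(outdir / "physio.csv", index=False, float_format="%.10g")
    manifest = {
        "spec": spec.to_dict(),
        "seed": spec.seed,
        "subjects": [
            {"subject_id": p.subject_id, "study": p.study, "g_i": p.g_i}
            for p, _, _ in cohort
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_hypnogram_csv(path: str | Path) -> dict[tuple[str, str], np.ndarray]:
    """Load per-(subject, condition) stage sequences, validating labels/epochs."""
    df = pd.read_csv(path, dtype={"subject_id": str, "condition": str, "stage": str})
    required = {"subject_id", "condition", "epoch_index", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise LoadError(f"hypnogram CSV missing columns: {sorted(missing)}")
    bad = ~df["stage"].isin(STAGES)
    if bad.any():
        row = int(df.index[bad][0])
        raise LoadError(
            f"unknown stage label {df.loc[row, 'stage']!r} at row {row + 2}"
        )
    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        row = int(df.index[bad_cond][0])
        raise LoadError(
            f"unknown condition {df.loc[row, 'condition']!r} at row {row + 2}"
        )
    out: dict[tuple[str, str], np.ndarray] = {}
    for (subject, condition), grp in df.groupby(["subject_id", "condition"], sort=True):
        grp = grp.sort_values("epoch_index")
        epochs = grp["epoch_index"].to_numpy()
        dup = pd.Series(epochs).duplicated()
        if dup.any():
            row = int(grp.index[dup.to_numpy()][0])
            raise LoadError(
                f"duplicate epoch {epochs[dup.to_numpy()][0]} for "
                f"{subject}/{condition} at row {row + 2}"
            )
        if epochs[0] != 0 or not np.array_equal(epochs, np.arange(len(epochs))):
            raise LoadError(
                f"epochs for {subject}/{condition} not contiguous from 0"
            )
        out[(subject, condition)] = grp["stage"].to_numpy(dtype=object)
    return out


def read_physio_csv(path: str | Path) -> dict[tuple[str, str], dict[str, PhysioSeries]]:
    df = pd.read_csv(path, dtype={"subject_id": str, "condition": str, "variable": str})
    required = {"subject_id", "condition", "variable", "sensor_id", "time_s", "value"}
    missing = required - set(df.columns)
    if missing:
        raise LoadError(f"physio CSV missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], dict[str, PhysioSeries]] = {}
    for (subject, condition, var), grp in df.groupby(
        ["subject_id", "condition", "variable"], sort=True
    ):
        sensors = sorted(grp["sensor_id"].unique())
        per_sensor = []
        times = None
        for s in sensors:
            g = grp[grp["sensor_id"] == s].sort_values("time_s")
            if times is None:
                times = g["time_s"].to_numpy()
            elif not np.array_equal(times, g["time_s"].to_numpy()):
                raise LoadError(
                    f"sensor time grids differ for {subject}/{condition}/{var}"
                )
            per_sensor.append(g["value"].to_numpy())
        out.setdefault((subject, condition), {})[var] = PhysioSeries(
            var, times, np.vstack(per_sensor)
        )
    return out


def binned_to_tidy(btcs: Iterable[BinnedTimecourse]) -> pd.DataFrame:
    """Tidy CSV form: one row per subject x condition x bin x variable."""
    rows = []
    for btc in btcs:
        for var in ALL_VARIABLES:
            vals = btc.variable(var)
            mask = btc.valid_mask(var)
            for b in range(N_BINS):
                rows.append(
                    (btc.subject_id, btc.condition, b, var, vals.iloc[b], bool(mask.iloc[b]))
                )
    return pd.DataFrame(
        rows, columns=["subject_id", "condition", "bin", "variable", "value", "valid"]
    )
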