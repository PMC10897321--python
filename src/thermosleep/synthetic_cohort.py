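"""Synthetic paired-night cohort generator.

Produces, for each subject, one HM (high-heat-capacity, cooling) and one LM
(control) night consisting of a 900-epoch hypnogram and physiological series
(CBT, PBT x 3 sensors, MAT x 5 sensors, HR).  The generative model is the
simplest one that carries the structure the downstream analyses detect:

* hypnograms come from a softmax stage-propensity model with a cosine
  NREM-REM cycle term (N3 peaking early in the cycle, REM roughly half a
  period later), linear night trends (N3 declining, REM rising) and a
  persistence (sticky-sampling + minimum-bout) smoother;
* the HM condition subtracts exponential-kinetics cooling terms from the
  temperature series, with time constants ordered MAT < PBT < CBT, scaled by
  a subject-level cooling response ``g_i`` (degC of nightly-mean CBT-PBT
  gradient increase);
* the same ``g_i`` drives the HM sleep effects: extra N3 propensity in the
  second part of the night (``hm_n3_gain`` minutes of N3 per degC) and a
  phase advance of the cycle term, which induces the positive correlation
  between the gradient response and the N3 response across subjects;
* HR is linearly coupled to the noiseless CBT curve, so the HM-LM heart-rate
  difference is exactly ``hr_cbt_slope`` times the CBT difference.

All randomness flows through named substreams keyed by (seed, subject index,
component), so regenerating one component never perturbs another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
CONDITIONS: tuple[str, str] = ("HM", "LM")

#: physiological variables and their sampling intervals in seconds / sensor counts
PHYSIO_SAMPLING: dict[str, tuple[int, int]] = {
    "CBT": (15, 1),
    "PBT": (60, 3),
    "MAT": (60, 5),
    "HR": (1, 1),
}

# rng substream component codes (order is part of the determinism contract)
_COMP_PROFILE = 0
_COMP_HYP = {"HM": 1, "LM": 2}
_COMP_PHYS = {"HM": 3, "LM": 4}

# fixed LM-night transient shapes: (depth in variable units, time constant min).
# PBT/MAT rise and HR falls quickly after lights-off; CBT declines slowly.
_LM_TRANSIENTS = {
    "CBT": (0.30, 150.0),  # slow decline, ~0.3 degC over the night
    "PBT": (-0.80, 25.0),  # fast rise by 0.8 degC
    "MAT": (-4.00, 30.0),  # fast rise by 4 degC
    "HR": (6.0, 20.0),  # fast decline from an elevated onset value
}

# relative weights for where the second-part N3 probability shift is taken from
_SHIFT_REMOVAL_WEIGHT = {"W": 1.0, "N1": 1.0, "N2": 1.0, "N3": 0.0, "REM": 4.5}

_STUDY_STAGE_BIAS = {
    1: {"N3": 0.25, "REM": 0.20},
    2: {"N3": -0.20, "REM": -0.15},
    3: {},
}


def _as_float_map(d: Mapping[str, float]) -> dict[str, float]:
    return {str(k): float(v) for k, v in d.items()}


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a synthetic paired-night cohort.

    The default values give a cohort whose nocturnal summary statistics,
    cycle structure and heterogeneity of the HM response are on the scale of
    a three-center crossover study of n = 15 + 33 + 24 subjects.
    """

    study_sizes: tuple[int, int, int] = (15, 33, 24)
    seed: int = 0

    # NREM-REM cycle structure
    cycle_period_min: float = 110.0
    cycle_phase_min: float = 25.0  # minutes after lights-off of the first N3 propensity peak
    rem_phase_offset_min: float = 72.0  # REM propensity peak lag behind N3 within the cycle
    n3_cycle_amplitude: float = 1.1  # propensity-score units
    rem_cycle_amplitude: float = 1.4
    n3_night_decline: float = -0.0035  # score units per minute
    rem_night_rise: float = 0.004

    # HM (cooling) effects
    hm_gradient_mean: float = 0.29  # degC, mean of the subject cooling response g_i
    hm_gradient_sd: float = 0.30
    hm_n3_gain: float = 25.0  # minutes of N3 per degC of g_i, second night-part
    hm_phase_advance_min: float = 10.0  # cycle phase advance for the mean responder

    # temperatures / heart rate
    temp_baselines: Mapping[str, float] = field(
        default_factory=lambda: {"CBT": 36.77, "PBT": 35.08, "MAT": 33.70}
    )
    # nightly-mean cooling depth per degC of g_i; PBT - CBT = 1 so that the
    # nightly-mean HM-LM gradient change equals g_i
    cooling_response: Mapping[str, float] = field(
        default_factory=lambda: {"CBT": 0.52, "PBT": 1.52, "MAT": 9.7}
    )
    tau_mat: float = 15.0  # minutes; exponential cooling time constants
    tau_pbt: float = 45.0
    tau_cbt: float = 95.0
    tau_recovery: float = 600.0  # shared slow-recovery constant of the cooling kinetics
    hr_baseline: float = 64.0
    hr_cbt_slope: float = 15.5  # bpm per degC

    # noise scales
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"CBT": 0.04, "PBT": 0.10, "MAT": 0.12, "HR": 2.0}
    )
    sensor_offset_sd: Mapping[str, float] = field(
        default_factory=lambda: {"PBT": 0.20, "MAT": 0.30}
    )
    baseline_offset_sd: Mapping[str, float] = field(
        default_factory=lambda: {"CBT": 0.15, "PBT": 0.35, "MAT": 0.50, "HR": 6.5}
    )
    resp_jitter_sd: Mapping[str, float] = field(
        default_factory=lambda: {"CBT": 0.50, "PBT": 0.18, "MAT": 0.10}
    )
    stage_offset_sd: float = 0.30

    # stage propensity baselines (softmax scores)
    stage_base: Mapping[str, float] = field(
        default_factory=lambda: {"W": -1.20, "N1": -1.46, "N2": 0.0, "N3": -0.54, "REM": -2.49}
    )

    persistence: float = 0.75  # sticky-sampling probability, in [0, 1]
    part_boundary_min: float = 190.0  # first/second night-part split
    epoch_s: int = 30
    night_min: int = 450

    def __post_init__(self) -> None:
        object.__setattr__(self, "study_sizes", tuple(int(n) for n in self.study_sizes))
        for name in ("temp_baselines", "cooling_response", "noise_sd", "sensor_offset_sd",
                     "baseline_offset_sd", "resp_jitter_sd", "stage_base"):
            object.__setattr__(self, name, _as_float_map(getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        if len(self.study_sizes) != 3 or any(n <= 0 for n in self.study_sizes):
            raise ValueError(f"study_sizes must be three positive counts, got {self.study_sizes}")
        if not (self.tau_mat < self.tau_pbt < self.tau_cbt):
            raise ValueError(
                "tau ordering violated: require tau_mat < tau_pbt < tau_cbt, got "
                f"tau_mat={self.tau_mat}, tau_pbt={self.tau_pbt}, tau_cbt={self.tau_cbt}"
            )
        if not (0.0 <= self.persistence <= 1.0):
            raise ValueError(f"persistence must be in [0, 1], got {self.persistence}")
        if self.cycle_period_min <= 0:
            raise ValueError(f"cycle_period_min must be positive, got {self.cycle_period_min}")
        if self.epoch_s != 30:
            raise ValueError(f"epoch_s must be 30, got {self.epoch_s}")
        if self.night_min != 450:
            raise ValueError(f"night_min must be 450, got {self.night_min}")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.study_sizes))

    @property
    def n_epochs(self) -> int:
        return self.night_min * 60 // self.epoch_s

    def null_effect(self) -> "CohortSpec":
        """A copy with all HM effect parameters set to zero (HM == LM in law)."""
        return dataclasses.replace(
            self,
            hm_gradient_mean=0.0,
            hm_gradient_sd=0.0,
            hm_n3_gain=0.0,
            hm_phase_advance_min=0.0,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_sizes"] = list(self.study_sizes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown CohortSpec fields: {sorted(unknown)}")
        return cls(**dict(d))


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    study: int
    g_i: float  # degC of HM-induced nightly-mean CBT-PBT gradient increase
    resp_mult: Mapping[str, float]  # per-variable cooling-response multipliers
    baseline_offset: Mapping[str, float]
    stage_offset: Mapping[str, float]
    sensor_offset: Mapping[str, tuple[float, ...]]


@dataclass
class PhysioSeries:
    variable: str
    times_s: np.ndarray  # shape (n,)
    values: np.ndarray  # shape (n_sensors, n)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times_s = np.asarray(self.times_s)


@dataclass
class NightRecording:
    subject_id: str
    condition: str
    hypnogram: np.ndarray  # 900 stage labels
    physio: dict[str, PhysioSeries]


class SubjectData(NamedTuple):
    profile: SubjectProfile
    hm: NightRecording
    lm: NightRecording


def _rng(seed: int, subject_index: int, component: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject_index, component)))


def _shape_mean(tau: float, rec: float, night_min: float) -> float:
    # nightly mean of s(t) = (1 - e^{-t/tau}) e^{-t/rec}, closed form
    h = rec * tau / (rec + tau)
    integral = rec * (1.0 - np.exp(-night_min / rec)) - h * (1.0 - np.exp(-night_min / h))
    return integral / night_min


def cooling_peak_time_min(tau: float, rec: float) -> float:
    """Time of the deepest HM-LM difference for a given time constant."""
    return tau * np.log(1.0 + rec / tau)


def _cooling_profile(t_min: np.ndarray, tau: float, rec: float, night_min: float) -> np.ndarray:
    """Unit-nightly-mean cooling shape: fast onset (tau), slow recovery (rec)."""
    s = (1.0 - np.exp(-t_min / tau)) * np.exp(-t_min / rec)
    return s / _shape_mean(tau, rec, night_min)


def _phase_scale(spec: CohortSpec, g_i: float) -> float:
    if spec.hm_gradient_mean > 0:
        return g_i / spec.hm_gradient_mean
    return 0.0


def draw_profile(spec: CohortSpec, subject_index: int, study: int) -> SubjectProfile:
    rng = _rng(spec.seed, subject_index, _COMP_PROFILE)
    g_i = float(rng.normal(spec.hm_gradient_mean, spec.hm_gradient_sd))
    resp_mult = {
        v: float(1.0 + rng.normal(0.0, spec.resp_jitter_sd[v])) for v in ("CBT", "PBT", "MAT")
    }
    baseline_offset = {
        v: float(rng.normal(0.0, spec.baseline_offset_sd[v])) for v in ("CBT", "PBT", "MAT", "HR")
    }
    stage_offset = {s: float(rng.normal(0.0, spec.stage_offset_sd)) for s in STAGES}
    bias = _STUDY_STAGE_BIAS.get(study, {})
    stage_offset = {s: stage_offset[s] + bias.get(s, 0.0) for s in STAGES}
    sensor_offset = {
        v: tuple(
            float(x)
            for x in rng.normal(0.0, spec.sensor_offset_sd[v], size=PHYSIO_SAMPLING[v][1])
        )
        for v in ("PBT", "MAT")
    }
    return SubjectProfile(
        subject_id=f"S{subject_index:03d}",
        study=study,
        g_i=g_i,
        resp_mult=resp_mult,
        baseline_offset=baseline_offset,
        stage_offset=stage_offset,
        sensor_offset=sensor_offset,
    )


def _enforce_min_bouts(codes: np.ndarray, min_len: int = 2) -> np.ndarray:
    """Merge bouts shorter than ``min_len`` epochs into the neighbouring bout."""
    if min_len <= 1 or len(codes) == 0:
        return codes
    out = codes.copy()
    boundaries = np.flatnonzero(np.diff(out)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(out)]))
    for i, (s, e) in enumerate(zip(starts, ends)):
        if e - s < min_len:
            if s > 0:
                out[s:e] = out[s - 1]
            elif e < len(out):
                out[s:e] = out[e]
    return out


def generate_hypnogram(
    profile: SubjectProfile, condition: str, spec: CohortSpec, rng: np.random.Generator
) -> np.ndarray:
    """One night of 900 30-s epochs from the stage-propensity model."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    n = spec.n_epochs
    t = (np.arange(n) + 0.5) * (spec.epoch_s / 60.0)  # epoch midpoints, minutes
    omega = 2.0 * np.pi / spec.cycle_period_min

    phase = spec.cycle_phase_min
    if condition == "HM":
        phase = phase - spec.hm_phase_advance_min * _phase_scale(spec, profile.g_i)

    scores = np.empty((n, len(STAGES)))
    for j, s in enumerate(STAGES):
        scores[:, j] = spec.stage_base[s] + profile.stage_offset[s]
    i_n3 = STAGES.index("N3")
    i_rem = STAGES.index("REM")
    scores[:, i_n3] += spec.n3_cycle_amplitude * np.cos(omega * (t - phase))
    scores[:, i_n3] += spec.n3_night_decline * t
    scores[:, i_rem] += spec.rem_cycle_amplitude * np.cos(
        omega * (t - phase - spec.rem_phase_offset_min)
    )
    scores[:, i_rem] += spec.rem_night_rise * t

    scores -= scores.max(axis=1, keepdims=True)
    p = np.exp(scores)
    p /= p.sum(axis=1, keepdims=True)

    if condition == "HM" and spec.hm_n3_gain != 0.0:
        # second night-part N3 propensity shift calibrated so the expected
        # extra N3 equals hm_n3_gain * g_i minutes over the second part; the
        # displaced mass is drawn from the other stages with REM weighted
        # highest, so stronger responders also lose REM late in the night
        second = t >= spec.part_boundary_min
        part_min = spec.night_min - spec.part_boundary_min
        delta = spec.hm_n3_gain * profile.g_i / part_min
        p_n3 = p[second, i_n3]
        p_n3_new = np.clip(p_n3 + delta, 0.002, 0.97)
        removal_w = np.array([_SHIFT_REMOVAL_WEIGHT[s] for s in STAGES])
        w = p[second, :] * removal_w[None, :]
        w[:, i_n3] = 0.0
        shift = (p_n3_new - p_n3)[:, None] * w / w.sum(axis=1, keepdims=True)
        p[second, :] = np.clip(p[second, :] - shift, 1e-4, None)
        p[second, i_n3] = p_n3_new
        p[second, :] /= p[second, :].sum(axis=1, keepdims=True)

    # sticky categorical sampling: keep the previous stage with prob
    # `persistence`, else redraw from the current propensities
    cumprob = np.cumsum(p, axis=1)
    u = rng.random(n)
    iid = (u[:, None] < cumprob).argmax(axis=1)
    resample = rng.random(n) >= spec.persistence
    resample[0] = True
    src = np.where(resample, np.arange(n), -1)
    src = np.maximum.accumulate(src)
    codes = iid[src]
    codes = _enforce_min_bouts(codes, min_len=2)
    return np.asarray(STAGES, dtype=object)[codes]


def _base_curves(
    profile: SubjectProfile, spec: CohortSpec, t_min: np.ndarray
) -> dict[str, np.ndarray]:
    """Noise-free LM curves for all variables at the given times (minutes)."""
    out: dict[str, np.ndarray] = {}
    cbt0 = spec.temp_baselines["CBT"] + profile.baseline_offset["CBT"]
    pbt0 = spec.temp_baselines["PBT"] + profile.baseline_offset["PBT"]
    mat0 = spec.temp_baselines["MAT"] + profile.baseline_offset["MAT"]
    out["CBT"] = cbt0 - _LM_TRANSIENTS["CBT"][0] * (1.0 - np.exp(-t_min / _LM_TRANSIENTS["CBT"][1]))
    out["PBT"] = pbt0 + _LM_TRANSIENTS["PBT"][0] * np.exp(-t_min / _LM_TRANSIENTS["PBT"][1])
    out["MAT"] = mat0 + _LM_TRANSIENTS["MAT"][0] * np.exp(-t_min / _LM_TRANSIENTS["MAT"][1])
    return out


def cooling_delta(
    profile: SubjectProfile, spec: CohortSpec, variable: str, t_min: np.ndarray
) -> np.ndarray:
    """HM minus LM of the noiseless temperature curve for one variable."""
    tau = {"MAT": spec.tau_mat, "PBT": spec.tau_pbt, "CBT": spec.tau_cbt}[variable]
    depth = spec.cooling_response[variable] * profile.resp_mult[variable] * profile.g_i
    return -depth * _cooling_profile(t_min, tau, spec.tau_recovery, float(spec.night_min))


def generate_physiology(
    profile: SubjectProfile, condition: str, spec: CohortSpec, rng: np.random.Generator
) -> dict[str, PhysioSeries]:
    """Sampled CBT / PBT / MAT / HR series for one night."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    series: dict[str, PhysioSeries] = {}
    night_s = spec.night_min * 60

    def curve(variable: str, t_min: np.ndarray) -> np.ndarray:
        base = _base_curves(profile, spec, t_min)[variable]
        if condition == "HM":
            base = base + cooling_delta(profile, spec, variable, t_min)
        return base

    for v in ("CBT", "PBT", "MAT"):
        step, n_sensors = PHYSIO_SAMPLING[v]
        times = np.arange(0, night_s, step)
        t_min = times / 60.0
        clean = curve(v, t_min)
        vals = np.empty((n_sensors, len(times)))
        offsets = profile.sensor_offset.get(v, (0.0,) * n_sensors)
        for s in range(n_sensors):
            vals[s] = clean + offsets[s] + rng.normal(0.0, spec.noise_sd[v], size=len(times))
        series[v] = PhysioSeries(v, times, np.clip(vals, 25.0, 40.0))

    step, _ = PHYSIO_SAMPLING["HR"]
    times = np.arange(0, night_s, step)
    t_min = times / 60.0
    cbt_clean = curve("CBT", t_min)
    cbt0 = spec.temp_baselines["CBT"] + profile.baseline_offset["CBT"]
    drop, tau = _LM_TRANSIENTS["HR"]
    hr = (
        spec.hr_baseline
        + profile.baseline_offset["HR"]
        + drop * np.exp(-t_min / tau)
        + spec.hr_cbt_slope * (cbt_clean - cbt0)
        + rng.normal(0.0, spec.noise_sd["HR"], size=len(times))
    )
    series["HR"] = PhysioSeries("HR", times, np.clip(hr, 30.0, 120.0))
    return series


def generate_night(
    profile: SubjectProfile, condition: str, spec: CohortSpec, subject_index: int
) -> NightRecording:
    hyp_rng = _rng(spec.seed, subject_index, _COMP_HYP[condition])
    phys_rng = _rng(spec.seed, subject_index, _COMP_PHYS[condition])
    return NightRecording(
        subject_id=profile.subject_id,
        condition=condition,
        hypnogram=generate_hypnogram(profile, condition, spec, hyp_rng),
        physio=generate_physiology(profile, condition, spec, phys_rng),
    )


def generate_cohort(spec: CohortSpec) -> list[SubjectData]:
    """Deterministically generate the full cohort (both nights per subject)."""
    spec.validate()
    studies: list[int] = []
    for study, size in enumerate(spec.study_sizes, start=1):
        studies.extend([study] * size)
    cohort: list[SubjectData] = []
    for idx, study in enumerate(studies):
        profile = draw_profile(spec, idx, study)
        hm = generate_night(profile, "HM", spec, idx)
        lm = generate_night(profile, "LM", spec, idx)
        cohort.append(SubjectData(profile, hm, lm))
    return cohort
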