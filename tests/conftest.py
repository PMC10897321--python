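import dataclasses

import numpy as np
import pytest

from thermosleep import preprocess as prep
from thermosleep import synthetic_cohort as sc


def make_deltas(spec):
    """Generate a cohort and return (profiles, per-subject PairedDelta list)."""
    cohort = sc.generate_cohort(spec)
    deltas = []
    for profile, hm, lm in cohort:
        deltas.append(prep.paired_delta(prep.bin_night(hm), prep.bin_night(lm)))
    return [c.profile for c in cohort], deltas


@pytest.fixture(scope="session")
def default_spec():
    return sc.CohortSpec(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    return sc.generate_cohort(default_spec)


@pytest.fixture(scope="session")
def default_binned(default_cohort):
    return [
        (c.profile, prep.bin_night(c.hm), prep.bin_night(c.lm)) for c in default_cohort
    ]


@pytest.fixture(scope="session")
def default_deltas(default_binned):
    return [prep.paired_delta(hm, lm) for _, hm, lm in default_binned]


@pytest.fixture(scope="session")
def tiny_spec():
    return dataclasses.replace(sc.CohortSpec(seed=7), study_sizes=(2, 2, 2))


def second_part_stage_minutes(recording, stage):
    """Independent epoch count of stage minutes in the second night-part."""
    hyp = np.asarray(recording.hypnogram, dtype=object)
    return float((hyp[380:] == stage).sum()) * 0.5
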