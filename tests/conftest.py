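"""Shared fixtures: audiogram builders and the packaged cohort."""

from __future__ import annotations

import pytest

from wfs_hearing.audiometry import (
    OCTAVE_FREQUENCIES,
    AudiogramSession,
    EarAudiogram,
    SiiConstants,
    Threshold,
)
from wfs_hearing.cohort import packaged_cohort


def make_ear(levels, ear="left", conductive=False, invalid=False):
    """Build an ear audiogram from a level per octave.

    ``levels`` is either a single level, a dict frequency -> level, or a
    6-sequence in octave order; ``None`` marks a no-response.
    """
    if isinstance(levels, dict):
        mapping = levels
    elif isinstance(levels, (int, float)) or levels is None:
        mapping = {f: levels for f in OCTAVE_FREQUENCIES}
    else:
        mapping = dict(zip(OCTAVE_FREQUENCIES, levels))
    thresholds = {
        f: Threshold(f, no_response=True) if lv is None else Threshold(f, level=lv)
        for f, lv in mapping.items()
    }
    return EarAudiogram(ear=ear, thresholds=thresholds,
                        conductive_flag=conductive, invalid_flag=invalid)


def make_session(left_levels, right_levels, patient_id="P1", age=10.0, index=1,
                 **ear_kwargs):
    return AudiogramSession(
        patient_id=patient_id,
        age_at_session=age,
        session_index=index,
        left=make_ear(left_levels, ear="left"),
        right=make_ear(right_levels, ear="right"),
    )


@pytest.fixture(scope="session")
def constants():
    return SiiConstants.default()


@pytest.fixture(scope="session")
def cohort():
    return packaged_cohort()
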