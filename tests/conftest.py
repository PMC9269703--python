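"""Shared fixtures: small synthetic subjects and cohorts, built in-process."""

from __future__ import annotations

import numpy as np
import pytest

from bendreturn import (
    Group,
    Recording,
    SensorFrame,
    SensorId,
    generate_cohort,
    generate_subject,
    nlbp_params,
    trim_warmup,
)


@pytest.fixture(scope="session")
def nlbp_subject():
    """One default healthy synthetic subject, trimmed to the 60 s window."""
    rec, truth = generate_subject(nlbp_params(), Group.NLBP, "N00", seed=7)
    return trim_warmup(rec), truth


@pytest.fixture(scope="session")
def small_cohort():
    """3 + 3 contrasted subjects, trimmed; enough for structural tests."""
    recs, truths = generate_cohort(n_per_group=3, seed=11)
    return [trim_warmup(r) for r in recs], truths


def make_recording(
    channel_fn=None, n: int = 700, fs: float = 100.0, group: str = "NLBP"
) -> Recording:
    """A minimal hand-built recording; channel_fn(sensor, channel) -> array."""
    def default_fn(sid, name):
        return np.zeros(n)

    fn = channel_fn or default_fn
    sensors = {}
    for sid in SensorId:
        channels = {
            name: np.asarray(fn(sid, name), dtype=float)
            for name in ("Acc X", "Acc Y", "Acc Z", "Gyr X", "Gyr Y", "Gyr Z")
        }
        sensors[sid] = SensorFrame(sensor_id=sid, channels=channels, fs=fs)
    return Recording(subject_id="test", group=Group(group), sensors=sensors, fs=fs)


@pytest.fixture
def flat_recording():
    return make_recording()
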