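import dataclasses

import numpy as np
import pytest

from apneahrv.rr_io import RRSeries
from apneahrv.synthetic_cohort import SyntheticConfig, generate_cohort


def make_series(rr_ms, subject_id="s1", sensor="patch", filtered=False,
                onsets_s=None):
    rr = np.asarray(rr_ms, dtype=float)
    if onsets_s is None:
        onsets_s = np.cumsum(rr) / 1000.0
    return RRSeries(subject_id=subject_id, sensor=sensor,
                    onsets_s=onsets_s, rr_ms=rr, filtered=filtered)


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects, 2 h nights, both sensors — shared across test modules."""
    cfg = dataclasses.replace(SyntheticConfig(), n_subjects=20,
                              night_duration_s=7200.0, seed=11)
    records, manifest = generate_cohort(cfg)
    return cfg, records, manifest
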