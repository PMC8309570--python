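import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def make_event_frame(rows):
    """Event-table helper: rows of (subject, group, f, psd, dur_periods, bw)."""
    rec = []
    for sid, group, f, psd, dur, bw in rows:
        rec.append({"subject_id": sid, "group": group, "arm": "right",
                    "muscle": "extensor", "t_peak_s": 1.0, "f_central_hz": f,
                    "psd_max": psd, "duration_s": dur / max(f, 1e-9),
                    "duration_periods": dur, "bandwidth_hz": bw,
                    "rejected_code": ""})
    return pd.DataFrame(rec)


def make_roster(subjects, duration=90.0):
    return pd.DataFrame([{"subject_id": s, "group": g,
                          "valid_duration_s": duration} for s, g in subjects])


@pytest.fixture
def event_helpers():
    return make_event_frame, make_roster
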