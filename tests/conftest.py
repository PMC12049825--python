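import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vocseq import CallRecord, CallSequence

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_sequence(
    maxfreq=None,
    duration=None,
    freqslope=None,
    acentropy=None,
    subject="S1",
    session="sess1",
):
    """Build a CallSequence from parallel parameter arrays; unspecified
    parameters default to valid constants."""
    arrays = {
        "maxfreq": maxfreq,
        "duration": duration,
        "freqslope": freqslope,
        "acentropy": acentropy,
    }
    n = max(len(v) for v in arrays.values() if v is not None)
    defaults = {"maxfreq": 800.0, "duration": 0.5, "freqslope": 1.0, "acentropy": 2.0}
    for key, val in arrays.items():
        arrays[key] = (
            np.full(n, defaults[key]) if val is None else np.asarray(val, float)
        )
    records = [
        CallRecord(
            subject=subject,
            session=session,
            order=i + 1,
            maxfreq=float(arrays["maxfreq"][i]),
            duration=float(arrays["duration"][i]),
            freqslope=float(arrays["freqslope"][i]),
            acentropy=float(arrays["acentropy"][i]),
        )
        for i in range(n)
    ]
    return CallSequence(subject, session, records)


@pytest.fixture
def toy_csv(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(
        "subject,session,order,maxfreq_hz,duration_s,freqslope_hz,entropy_bits\n"
        "A,s1,1,800,0.5,1.5,2.0\n"
        "A,s1,2,900,0.6,-1.0,2.5\n"
        "B,s1,1,700,0.4,0.5,1.8\n"
        "B,s1,2,750,0.45,0.7,1.9\n"
    )
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
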