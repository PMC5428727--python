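import numpy as np
import pytest

from ecgdecim import EcgRecord, ResampleSpec, SyntheticEcgSpec, generate

OPTIMUM = dict(fs_in=360.0, B=390.0, K=80.0)


@pytest.fixture(scope="session")
def optimum_spec() -> ResampleSpec:
    """The published operating point: 360 Hz compressed to 80 Hz via 390 Hz."""
    return ResampleSpec.create(**OPTIMUM)


@pytest.fixture(scope="session")
def clean_record() -> EcgRecord:
    """60 s clean synthetic ECG at 360 Hz, HR 60, no jitter."""
    return generate(SyntheticEcgSpec(duration_s=60, fs=360, heart_rate_bpm=60,
                                     seed=7))


@pytest.fixture(scope="session")
def jittered_record() -> EcgRecord:
    """120 s synthetic ECG with physiological RR jitter."""
    return generate(SyntheticEcgSpec(duration_s=120, fs=360,
                                     heart_rate_bpm=72, rr_jitter_sd_s=0.04,
                                     seed=13))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
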