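import numpy as np
import pytest

from ppgfilt import PPGRecord
from ppgfilt.synth import generate_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_labeled_records():
    """Six tiny records, two per grade, deterministic."""
    recs = []
    for grade, seeds in (("G1", (11, 12)), ("G2", (21, 22)), ("G3", (31, 32))):
        for s in seeds:
            recs.append(
                generate_record(grade, seed=s, subject_id=f"{grade.lower()}x{s}")
            )
    return recs


@pytest.fixture
def clean_record():
    """A single noise-free beat train (all noise amplitudes zero)."""
    from ppgfilt.synth import NoiseModel

    return generate_record("G1", seed=7, noise=NoiseModel())


def make_record(samples, fs=1000.0, label="unlabeled", **kw):
    return PPGRecord(samples=np.asarray(samples, float), fs=fs, label=label, **kw)
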