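import numpy as np
import pytest

from dysarthria_ssm.preprocess import SegmentRecord
from dysarthria_ssm.synth import ClassParams, SpeakerProfile, make_corpus

FORMANTS = (700.0, 1200.0, 2600.0, 3500.0)
BANDWIDTHS = (120.0, 160.0, 220.0, 300.0)


def profile(f0=150.0, seed=0, **kw):
    return SpeakerProfile("test", f0, FORMANTS, BANDWIDTHS, 0.1, seed, **kw)


def params(label="Moderate", jitter=0.0, shimmer=0.0, hnr=100.0,
           tremor_rate=0.0, tremor_depth=0.0, monotonicity=1.0):
    return ClassParams(label, jitter, shimmer, hnr, tremor_rate,
                       tremor_depth, monotonicity)


def as_segment(x, fs=16000, scale="long_4s"):
    sd = np.std(x)
    return SegmentRecord(x / sd if sd > 0 else x, fs, "spk", "Normal",
                         scale, 0.0)


@pytest.fixture(scope="session")
def default_corpus(tmp_path_factory):
    """The default synthetic study corpus: 20 speakers/class, 2 x 4 s each,
    features extracted at the 32x32 tensor size used for CPU-scale runs."""
    from dysarthria_ssm.data import extract_corpus

    d = tmp_path_factory.mktemp("corpus")
    manifest = make_corpus(d, n_speakers_per_class=20,
                           recordings_per_speaker=2, duration_s=4.0, seed=11)
    corpus = extract_corpus(manifest, d, size=32)
    return manifest, corpus


@pytest.fixture(scope="session")
def tiny_corpus(tmp_path_factory):
    d = tmp_path_factory.mktemp("tiny")
    manifest = make_corpus(d, n_speakers_per_class=3,
                           recordings_per_speaker=2, duration_s=4.0, seed=3)
    return d, manifest
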