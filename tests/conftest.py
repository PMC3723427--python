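import numpy as np
import pytest
from hypothesis import settings

from stresschip.signal_io import SignalTrack

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_track(chrom="chr1", positions=(), values=(), species="", condition=""):
    t = SignalTrack(species, condition)
    t.add_chrom(chrom, np.asarray(positions, dtype=np.int64), np.asarray(values, float))
    return t


def ramp_track(chrom="chr1", start=0, end=100, spacing=1):
    pos = np.arange(start, end, spacing)
    return make_track(chrom, pos, pos.astype(float))


def constant_track(value, chrom="chr1", start=0, end=100, spacing=5):
    pos = np.arange(start, end, spacing)
    return make_track(chrom, pos, np.full(pos.size, float(value)))


@pytest.fixture(scope="session")
def small_dataset():
    """A modest effect-bearing synthetic dataset shared by integration tests."""
    from stresschip.synthetic_data import default_config, simulate

    return simulate(default_config(n_genes=250, seed=11))
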