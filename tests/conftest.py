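import numpy as np
import pytest

from cnamcr.types import ArrayProfile, ProbeDesign


def make_design(n=100, chrom="chr1", spacing=1000, probe_len=60, platform="test"):
    starts = np.arange(n, dtype=np.int64) * spacing
    return ProbeDesign(
        platform_id=platform,
        chrom=np.array([chrom] * n, dtype=object),
        start=starts,
        end=starts + probe_len,
        genome={chrom: int(starts[-1] + spacing)},
    )


def make_profile(log2, design=None, sample_id="s0", centralized=True, **kw):
    log2 = np.asarray(log2, dtype=float)
    if design is None:
        design = make_design(n=len(log2))
    p = ArrayProfile(sample_id=sample_id, design=design, log2=log2, **kw)
    if centralized:
        p.state["centralized"] = True
    return p


@pytest.fixture
def design100():
    return make_design(100)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
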