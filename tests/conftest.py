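import numpy as np
import pandas as pd
import pytest

from kataseg import VariantCollection


@pytest.fixture
def two_rate_observations():
    """The canonical two-rate fixture: ten IMDs of 1000 then ten of 10."""
    return np.array([1000.0] * 10 + [10.0] * 10)


@pytest.fixture
def two_segment_collection():
    """20 variants whose IMDs are the two-rate fixture; last variant at the
    chromosome end so the pseudo-IMD is the boundary case."""
    imds = [1000] * 10 + [10] * 10
    positions = np.cumsum(imds)
    df = pd.DataFrame(
        {
            "chromosome": "chr1",
            "start": positions,
            "end": positions,
            "ref": "C",
            "alt": "T",
            "sample_id": "s1",
        }
    )
    return VariantCollection(df, {"chr1": int(positions[-1])})


def make_collection(positions, length, chromosome="chr1", ref="C", alt="T"):
    positions = np.asarray(positions, dtype=np.int64)
    df = pd.DataFrame(
        {
            "chromosome": chromosome,
            "start": positions,
            "end": positions,
            "ref": ref,
            "alt": alt,
            "sample_id": "s1",
        }
    )
    return VariantCollection(df, {chromosome: int(length)})


@pytest.fixture
def clustered_collection():
    """A sparse background plus one 6-variant cluster with 100 bp spacing."""
    cluster = 2_000_000 + np.arange(6) * 100
    positions = np.concatenate(([1_000, 900_000], cluster, [3_500_000]))
    return make_collection(positions, 4_000_000)
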