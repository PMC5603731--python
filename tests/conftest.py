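import numpy as np
import pandas as pd
import pytest

from cgireader.calibration import SignalTrack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(values, bin_size=100, chrom="chr1", origin=0):
    """Uniform-bin SignalTrack from a value vector."""
    values = np.asarray(values, dtype=float)
    starts = origin + bin_size * np.arange(values.size)
    df = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + bin_size,
         "value": values}
    )
    return SignalTrack(data=df, bin_size=bin_size)


def random_interval_set(rng, n, span=10_000, max_len=400, chroms=("chr1", "chr2")):
    """Sorted random intervals for overlap stress tests (may touch/overlap)."""
    rows = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        end = start + int(rng.integers(1, max_len))
        rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
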