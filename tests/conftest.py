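import numpy as np
import pandas as pd
import pytest

from spermepi.genome_io import Interval, Peak, SignalTrack


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


def random_peaks(rng, n, chroms=("chr1", "chr2"), max_start=100_000, max_width=3_000):
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_start))
        width = int(rng.integers(1, max_width))
        peaks.append(Peak(Interval(chrom, start, start + width), float(rng.uniform(0, 10)), f"p{i}"))
    return peaks


def random_track(rng, chrom="chr1", n_segments=50, span=100_000):
    cuts = np.sort(rng.choice(np.arange(1, span), size=2 * n_segments, replace=False))
    starts, ends = cuts[0::2], cuts[1::2]
    values = rng.uniform(0, 5, size=n_segments)
    return SignalTrack({chrom: (starts, ends, values)})


def tss_frame(rows):
    """rows: (gene_id, chrom, strand, tss, tes)"""
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"])
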