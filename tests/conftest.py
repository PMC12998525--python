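"""Shared fixtures and brute-force oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from enhancerhub.intervals import PeakSet

CHROM_LEN = 100_000  # toy chromosome used by random interval instances


def random_peakset(rng, n, sample_id="s", n_chroms=2, chrom_len=CHROM_LEN, max_len=500):
    """A random sorted PeakSet on `n_chroms` toy chromosomes."""
    chroms = [f"chr{i + 1}" for i in rng.integers(0, n_chroms, n)]
    starts = rng.integers(0, chrom_len - max_len, n)
    lengths = rng.integers(1, max_len, n)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + lengths})
    return PeakSet(sample_id, df)


def coverage(peakset, n_chroms=2, chrom_len=CHROM_LEN):
    """Per-base boolean coverage arrays, one per chromosome."""
    cov = {f"chr{i + 1}": np.zeros(chrom_len, dtype=bool) for i in range(n_chroms)}
    for r in peakset.df.itertuples(index=False):
        cov[r.chrom][r.start : r.end] = True
    return cov


def brute_overlap_mask(a, b, n_chroms=2, chrom_len=CHROM_LEN):
    """Per-base oracle: does each interval of `a` share >= 1 covered base with `b`?"""
    cov = coverage(b, n_chroms, chrom_len)
    return np.array(
        [cov[r.chrom][r.start : r.end].any() for r in a.df.itertuples(index=False)]
    )


def frame_key_set(peakset):
    return set(zip(peakset.df["chrom"], peakset.df["start"], peakset.df["end"]))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
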