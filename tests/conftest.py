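import numpy as np
import pytest

from freqdiv.table import FrequencyTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_table():
    """Six loci, two chromosomes, two timepoints, with depths."""
    return FrequencyTable(
        chrom=np.array(["2L", "2L", "2L", "2R", "2R", "2R"], dtype=object),
        pos=np.array([100, 5000, 9000, 250, 700, 1200]),
        freq=np.array(
            [
                [0.10, 0.20],
                [0.55, 0.50],
                [0.90, 0.95],
                [0.30, 0.25],
                [0.50, 0.60],
                [0.75, 0.80],
            ]
        ),
        t_labels=("t0", "t10"),
        depth=np.full((6, 2), 100.0),
    )


def random_table(rng, n_loci=50, n_tp=2, with_depth=False):
    """A valid random FrequencyTable for property tests."""
    chrom = np.repeat("chr1", n_loci).astype(object)
    pos = np.sort(rng.choice(np.arange(1, 10 * n_loci + 1), n_loci, replace=False))
    freq = rng.uniform(0, 1, size=(n_loci, n_tp))
    depth = rng.integers(10, 200, size=(n_loci, n_tp)).astype(float) if with_depth else None
    labels = tuple(f"t{i}" for i in range(n_tp))
    return FrequencyTable(chrom=chrom, pos=pos, freq=freq, t_labels=labels, depth=depth)
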