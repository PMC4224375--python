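import numpy as np
import pytest

from ctrlpool.read_io import GenomeLayout, ReadSet


def make_reads(records, label="test"):
    """Build a ReadSet from (chrom, pos5, strand_char) tuples."""
    if not records:
        return ReadSet.empty(label)
    chrom, pos5, strand = zip(*records)
    return ReadSet(
        np.array(chrom),
        np.array(pos5, dtype=np.int64),
        np.array([1 if s == "+" else -1 for s in strand], dtype=np.int8),
        source_label=label,
    )


def random_reads(rng, n, layout, label="rand"):
    ci = rng.integers(0, len(layout.chrom_names), size=n)
    lengths = np.asarray(layout.chrom_lengths)
    return ReadSet(
        np.asarray(layout.chrom_names, dtype=object)[ci].astype(str),
        rng.integers(0, lengths[ci]),
        (rng.integers(0, 2, size=n) * 2 - 1).astype(np.int8),
        source_label=label,
    )


@pytest.fixture
def small_layout():
    return GenomeLayout(("chr1", "chr2"), (1000, 600), bin_width=200)


@pytest.fixture
def flat_layout():
    """1000 bins on one chromosome for p-value fixtures."""
    return GenomeLayout(("chr1",), (200_000,), bin_width=200)


@pytest.fixture
def rng():
    return np.random.default_rng(20140919)
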