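"""Mapped-read I/O, genome binning, seeded subsampling and in-silico pooling.

The unit of analysis is a :class:`ReadSet` — a multiset of uniquely mapped
single-end reads, each reduced to (chromosome, 0-based 5' coordinate,
strand).  Reads are loaded from tagAlign or BED6 files (plain or gzip),
extended to an average fragment length, and tallied into fixed-width genome
bins to produce the :class:`BinCounts` vectors on which sample-to-sample
correlation and peak calling operate.

Coordinates are 0-based half-open throughout; the 5' end of a minus-strand
record spanning ``[start, end)`` is ``end - 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "ReadSet",
    "BinCounts",
    "ReadParseError",
    "load_reads",
    "write_reads",
    "bin_counts",
    "subsample_reads",
    "take_reads",
    "pool_reads",
    "reads_equal",
]

_STRAND_CODES = {"+": 1, "-": -1}


class ReadParseError(ValueError):
    """A mapped-read file could not be parsed."""


@dataclass(frozen=True)
class GenomeLayout:
    """Tiling of a genome into contiguous, non-overlapping fixed-width bins.

    Parameters
    ----------
    chrom_names
        Ordered chromosome identifiers; this order defines the
        concatenation order of per-chromosome count vectors.
    chrom_lengths
        Chromosome lengths in base pairs, parallel to ``chrom_names``.
    bin_width
        Bin width in base pairs (default 200).  The last bin of each
        chromosome may be shorter than ``bin_width``.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_width: int = 200

    def __post_init__(self):
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(x) for x in self.chrom_lengths))
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths must be parallel")
        if len(self.chrom_names) == 0:
            raise ValueError("layout needs at least one chromosome")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def chrom_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.chrom_names)}

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_lengths[self.chrom_index[chrom]] / self.bin_width)

    @property
    def bins_per_chrom(self) -> np.ndarray:
        return np.array(
            [math.ceil(l / self.bin_width) for l in self.chrom_lengths], dtype=np.int64
        )

    @property
    def bin_offsets(self) -> np.ndarray:
        """Offset of each chromosome's first bin in the concatenated vector."""
        return np.concatenate([[0], np.cumsum(self.bins_per_chrom)[:-1]])

    @property
    def total_bins(self) -> int:
        return int(self.bins_per_chrom.sum())

    @classmethod
    def from_chrom_sizes(cls, path, bin_width: int = 200) -> "GenomeLayout":
        """Build a layout from a UCSC-style two-column chrom.sizes file."""
        df = pd.read_csv(path, sep=r"\s+", header=None, usecols=[0, 1],
                         names=["chrom", "length"])
        return cls(tuple(df["chrom"].astype(str)), tuple(df["length"].astype(int)),
                   bin_width=bin_width)

    def to_chrom_sizes(self, path) -> None:
        pd.DataFrame({"chrom": self.chrom_names, "length": self.chrom_lengths}).to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass(eq=False)
class ReadSet:
    """A multiset of uniquely mapped single-end reads.

    Reads are stored column-wise as parallel numpy arrays; ``strand`` is
    ``+1`` for the forward and ``-1`` for the reverse strand.  A ReadSet is
    the unit of subsampling and pooling: operations treat it as a multiset
    and never deduplicate.
    """

    chrom: np.ndarray
    pos5: np.ndarray
    strand: np.ndarray
    source_label: str = ""

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom).astype(str)
        self.pos5 = np.asarray(self.pos5, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype=np.int8)
        if not (len(self.chrom) == len(self.pos5) == len(self.strand)):
            raise ValueError("read columns must be parallel")

    @property
    def depth(self) -> int:
        """Number of reads (multiset cardinality)."""
        return len(self.pos5)

    def take(self, idx: np.ndarray) -> "ReadSet":
        return ReadSet(self.chrom[idx], self.pos5[idx], self.strand[idx],
                       source_label=self.source_label)

    @classmethod
    def empty(cls, source_label: str = "") -> "ReadSet":
        return cls(np.array([], dtype=str), np.array([], dtype=np.int64),
                   np.array([], dtype=np.int8), source_label=source_label)

    def _canonical_order(self) -> np.ndarray:
        return np.lexsort((self.strand, self.pos5, self.chrom))


def reads_equal(a: ReadSet, b: ReadSet) -> bool:
    """True iff the two read sets are equal as multisets."""
    if a.depth != b.depth:
        return False
    ia, ib = a._canonical_order(), b._canonical_order()
    return (
        bool(np.array_equal(a.chrom[ia], b.chrom[ib]))
        and bool(np.array_equal(a.pos5[ia], b.pos5[ib]))
        and bool(np.array_equal(a.strand[ia], b.strand[ib]))
    )


def load_reads(path, fmt: str = "tagalign") -> ReadSet:
    """Load a mapped-read file (tagAlign or BED6, plain or gzip).

    Both formats are six tab-separated columns ``chrom start end name score
    strand`` with 0-based half-open coordinates.  Plus-strand reads get
    ``pos5 = start``; minus-strand reads get ``pos5 = end - 1``.
    """
    fmt = fmt.lower()
    if fmt not in ("tagalign", "bed6", "bed"):
        raise ValueError(f"unknown read format: {fmt!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         compression="infer")
    except pd.errors.EmptyDataError:
        return ReadSet.empty(source_label=str(path))
    except pd.errors.ParserError as exc:
        raise ReadParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 6:
        raise ReadParseError(f"{path}: expected 6 columns, found {df.shape[1]}")
    strand_raw = df.iloc[:, 5].astype(str).to_numpy()
    bad = ~np.isin(strand_raw, list(_STRAND_CODES))
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 1
        raise ReadParseError(f"{path}: line {line}: bad strand {strand_raw[bad][0]!r}")
    try:
        start = df.iloc[:, 1].astype(np.int64).to_numpy()
        end = df.iloc[:, 2].astype(np.int64).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ReadParseError(f"{path}: non-integer coordinates: {exc}") from exc
    if (end <= start).any():
        line = int(np.flatnonzero(end <= start)[0]) + 1
        raise ReadParseError(f"{path}: line {line}: end <= start")
    strand = np.where(strand_raw == "+", 1, -1).astype(np.int8)
    pos5 = np.where(strand == 1, start, end - 1)
    return ReadSet(df.iloc[:, 0].astype(str).to_numpy(), pos5, strand,
                   source_label=str(path))


def write_reads(rs: ReadSet, path, fmt: str = "tagalign", read_length: int = 36) -> None:
    """Write a ReadSet as tagAlign or BED6 (gzip if the path ends in .gz).

    Records are written with a nominal ``read_length`` span anchored at the
    5' end, so a round trip through :func:`load_reads` preserves the read
    multiset exactly.
    """
    fmt = fmt.lower()
    plus = rs.strand == 1
    start = np.where(plus, rs.pos5, np.maximum(rs.pos5 + 1 - read_length, 0))
    end = np.where(plus, rs.pos5 + read_length, rs.pos5 + 1)
    strand = np.where(plus, "+", "-")
    if fmt == "tagalign":
        df = pd.DataFrame({0: rs.chrom, 1: start, 2: end, 3: "N", 4: 1000, 5: strand})
    elif fmt in ("bed6", "bed"):
        df = pd.DataFrame({0: rs.chrom, 1: start, 2: end, 3: "r", 4: 0, 5: strand})
    else:
        raise ValueError(f"unknown read format: {fmt!r}")
    df.to_csv(path, sep="\t", header=False, index=False, compression="infer")


@dataclass(eq=False)
class BinCounts:
    """Per-chromosome integer vectors of fragment-extended read counts.

    ``counts`` maps each layout chromosome to its bin vector; ``skipped``
    counts reads that fell on chromosomes absent from the layout and were
    excluded.  ``total + skipped`` equals the depth of the source ReadSet
    under the midpoint assignment rule.
    """

    layout: GenomeLayout
    counts: dict[str, np.ndarray]
    fragment_length: int
    skipped: int = 0

    @property
    def total(self) -> int:
        return int(sum(v.sum() for v in self.counts.values()))

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in self.layout.chrom_names])

    def same_counts(self, other: "BinCounts") -> bool:
        return self.layout == other.layout and all(
            np.array_equal(self.counts[c], other.counts[c])
            for c in self.layout.chrom_names
        )

    def __add__(self, other: "BinCounts") -> "BinCounts":
        if self.layout != other.layout:
            raise ValueError("cannot add BinCounts on different layouts")
        if self.fragment_length != other.fragment_length:
            raise ValueError("cannot add BinCounts with different fragment lengths")
        return BinCounts(
            self.layout,
            {c: self.counts[c] + other.counts[c] for c in self.layout.chrom_names},
            self.fragment_length,
            skipped=self.skipped + other.skipped,
        )


def bin_counts(
    rs: ReadSet,
    layout: GenomeLayout,
    fragment_length: int = 150,
    mode: str = "midpoint",
) -> BinCounts:
    """Extend reads to the average fragment length and tally them into bins.

    Each read is extended from its 5' end in the strand direction to
    ``fragment_length`` bases.  In the default ``"midpoint"`` mode the
    fragment is assigned to exactly the bin containing its midpoint
    (clamped to chromosome bounds), so reads are conserved:
    ``total + skipped == rs.depth``.  In ``"overlap"`` mode every bin the
    fragment overlaps is incremented (no conservation).

    Reads on chromosomes absent from the layout are excluded and tallied in
    ``skipped``.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    if mode not in ("midpoint", "overlap"):
        raise ValueError(f"unknown binning mode: {mode!r}")
    bw = layout.bin_width
    nbins = layout.bins_per_chrom
    offsets = layout.bin_offsets
    lengths = np.asarray(layout.chrom_lengths, dtype=np.int64)

    if rs.depth == 0:
        counts = {c: np.zeros(layout.n_bins(c), dtype=np.int64) for c in layout.chrom_names}
        return BinCounts(layout, counts, fragment_length, skipped=0)

    uniq, inv = np.unique(rs.chrom, return_inverse=True)
    cidx_map = layout.chrom_index
    uidx = np.array([cidx_map.get(c, -1) for c in uniq], dtype=np.int64)
    ci = uidx[inv]
    valid = ci >= 0
    skipped = int((~valid).sum())

    ci = ci[valid]
    pos5 = rs.pos5[valid]
    plus = rs.strand[valid] == 1
    frag_start = np.where(plus, pos5, pos5 + 1 - fragment_length)
    frag_end = np.where(plus, pos5 + fragment_length, pos5 + 1)

    total_bins = int(nbins.sum())
    if mode == "midpoint":
        mid = (frag_start + frag_end) // 2
        mid = np.clip(mid, 0, lengths[ci] - 1)
        gbin = offsets[ci] + mid // bw
        flat = np.bincount(gbin, minlength=total_bins).astype(np.int64)
    else:
        lo = np.clip(frag_start, 0, lengths[ci] - 1) // bw
        hi = np.clip(frag_end - 1, 0, lengths[ci] - 1) // bw
        reps = (hi - lo + 1).astype(np.int64)
        base = np.repeat(offsets[ci] + lo, reps)
        within = np.concatenate([np.arange(r) for r in reps]) if len(reps) else np.array([], dtype=np.int64)
        flat = np.bincount(base + within, minlength=total_bins).astype(np.int64)

    counts = {
        c: flat[offsets[i]: offsets[i] + nbins[i]]
        for i, c in enumerate(layout.chrom_names)
    }
    return BinCounts(layout, counts, fragment_length, skipped=skipped)


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def subsample_reads(rs: ReadSet, fraction: float, seed: int) -> ReadSet:
    """Sample ``round(fraction * depth)`` reads uniformly without replacement.

    Rounding is half-to-even so repeat counts are deterministic.  The same
    seed on the same input yields an identical output (indices are drawn
    with a PCG64 generator and kept in genomic input order).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if rs.depth == 0:
        raise ValueError("cannot subsample an empty ReadSet")
    n = _round_half_even(fraction * rs.depth)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(rs.depth, size=n, replace=False))
    out = rs.take(idx)
    out.source_label = f"{rs.source_label}|sub{fraction:g}"
    return out


def take_reads(rs: ReadSet, n: int, seed: int) -> ReadSet:
    """Sample exactly ``n`` reads uniformly without replacement."""
    if not 0 <= n <= rs.depth:
        raise ValueError(f"cannot take {n} reads from depth {rs.depth}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(rs.depth, size=n, replace=False))
    out = rs.take(idx)
    out.source_label = f"{rs.source_label}|take{n}"
    return out


def pool_reads(parts: list[ReadSet]) -> ReadSet:
    """Combine the reads of several samples into one multiset (in-silico pooling)."""
    if not parts:
        raise ValueError("pool_reads needs at least one ReadSet")
    out = ReadSet(
        np.concatenate([p.chrom for p in parts]),
        np.concatenate([p.pos5 for p in parts]),
        np.concatenate([p.strand for p in parts]),
        source_label="pool(" + ",".join(p.source_label for p in parts) + ")",
    )
    return out
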