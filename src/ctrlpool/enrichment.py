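"""Ranked ChIP-enriched region lists and master lists.

The built-in baseline caller compares ChIP against control bin counts with
a depth-scaled Poisson background and Benjamini-Hochberg FDR control.  It
is deliberately simple: the only property the pooling framework needs from
a peak caller is a ranked peak list whose quality depends on the depth and
fidelity of the control sample.  Externally produced peak BEDs (e.g. from
MOSAiCS or SPP) plug in through :func:`import_peaks` unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .read_io import BinCounts, GenomeLayout

__all__ = [
    "Region",
    "RegionSet",
    "MasterList",
    "ZeroDepthControlError",
    "call_peaks",
    "import_peaks",
    "build_master_list",
    "master_bin_indices",
    "restrict_counts",
]

_MIN_P = 1e-300  # floor before -log10 so scores stay finite


class ZeroDepthControlError(ValueError):
    """Raised when the control sample has zero mapped reads."""


@dataclass(frozen=True)
class Region:
    """A scored genomic interval; ``rank`` is 1-based, best score first."""

    chrom: str
    start: int
    end: int
    score: float
    rank: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")


@dataclass
class RegionSet:
    """A ranked list of non-overlapping enriched regions (a peak set)."""

    regions: list[Region]
    caller_label: str = "baseline"

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def sorted_by_rank(self) -> list[Region]:
        return sorted(self.regions, key=lambda r: r.rank)

    def top_fraction(self, k_percent: float) -> list[Region]:
        """Top ``ceil(k% * N)`` regions by rank."""
        n = int(np.ceil(k_percent / 100.0 * len(self.regions)))
        return self.sorted_by_rank()[:n]

    def by_chrom(self, regions=None) -> dict[str, np.ndarray]:
        """Per-chromosome (N, 2) start/end arrays sorted by start."""
        out: dict[str, list] = {}
        for r in (self.regions if regions is None else regions):
            out.setdefault(r.chrom, []).append((r.start, r.end))
        return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}

    def to_bed(self, path) -> None:
        rows = [
            (r.chrom, r.start, r.end, f"peak_{r.rank}", r.score)
            for r in self.sorted_by_rank()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class MasterList:
    """Merged union of enriched regions: pairwise disjoint, coordinate sorted."""

    regions: list[tuple[str, int, int]]

    def __len__(self) -> int:
        return len(self.regions)

    def by_chrom(self) -> dict[str, np.ndarray]:
        out: dict[str, list] = {}
        for chrom, s, e in self.regions:
            out.setdefault(chrom, []).append((s, e))
        return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}

    def to_bed3(self, path) -> None:
        pd.DataFrame(self.regions).to_csv(path, sep="\t", header=False, index=False)


def _rank_regions(rows: list[tuple], chrom_order: dict[str, int] | None,
                  caller_label: str) -> RegionSet:
    """rows: (chrom, start, end, score); rank by score desc, ties by coordinate."""
    order = chrom_order or {}
    rows = sorted(rows, key=lambda t: (-t[3], order.get(t[0], 0), t[0], t[1]))
    regions = [
        Region(chrom, int(s), int(e), float(score), rank=i + 1)
        for i, (chrom, s, e, score) in enumerate(rows)
    ]
    return RegionSet(regions, caller_label=caller_label)


def call_peaks(
    chip: BinCounts,
    control: BinCounts,
    fdr: float = 0.05,
    pseudocount: float = 1.0,
    min_gap_bins: int = 1,
) -> RegionSet:
    """Baseline two-sample peak caller on bin counts.

    Per bin, the expected ChIP count under the background model is
    ``(chip.total / control.total) * (control + pseudocount)`` and the
    p-value is the upper-tail Poisson probability of observing at least the
    ChIP count at that expectation.  Benjamini-Hochberg at ``fdr`` selects
    bins; selected bins separated by at most ``min_gap_bins`` non-selected
    bins merge into one region.  The region score is ``-log10`` of the
    minimum constituent bin p-value; regions are ranked by score
    descending, ties broken by genomic coordinate.
    """
    if chip.layout != control.layout:
        raise ValueError("chip and control must share a genome layout")
    if chip.fragment_length != control.fragment_length:
        raise ValueError("chip and control must share a fragment length")
    if control.total == 0:
        raise ZeroDepthControlError(
            "control has zero depth; supply reads or use a pseudocount-only background"
        )
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")

    layout = chip.layout
    c = chip.concatenated().astype(np.float64)
    b = control.concatenated().astype(np.float64)
    if c.sum() == 0:
        return RegionSet([], caller_label="baseline")
    ratio = chip.total / control.total
    mu = ratio * (b + pseudocount)
    logp = stats.poisson.logsf(c - 1, mu)  # log P(X >= c), no underflow
    pvals = np.exp(logp)
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")

    rows: list[tuple] = []
    offsets = layout.bin_offsets
    nbins = layout.bins_per_chrom
    bw = layout.bin_width
    for i, chrom in enumerate(layout.chrom_names):
        sel = np.flatnonzero(reject[offsets[i]: offsets[i] + nbins[i]])
        if sel.size == 0:
            continue
        lp_chrom = logp[offsets[i]: offsets[i] + nbins[i]]
        breaks = np.flatnonzero(np.diff(sel) - 1 > min_gap_bins) + 1
        for grp in np.split(sel, breaks):
            start = int(grp[0]) * bw
            end = min((int(grp[-1]) + 1) * bw, layout.chrom_lengths[i])
            # -log10 of the minimum constituent bin p-value, via logsf so
            # strong peaks keep distinct scores instead of saturating
            score = -float(lp_chrom[grp].min()) / np.log(10)
            rows.append((chrom, start, end, score))
    return _rank_regions(rows, layout.chrom_index, "baseline")


def _merge_scored(rows: list[tuple], bookended: bool) -> list[tuple]:
    """Merge overlapping (and optionally book-ended) scored intervals, keeping max score."""
    rows = sorted(rows, key=lambda t: (t[0], t[1], t[2]))
    merged: list[list] = []
    for chrom, s, e, score in rows:
        if merged and merged[-1][0] == chrom and (
            s < merged[-1][2] or (bookended and s <= merged[-1][2])
        ):
            merged[-1][2] = max(merged[-1][2], e)
            merged[-1][3] = max(merged[-1][3], score)
        else:
            merged.append([chrom, s, e, score])
    return [tuple(m) for m in merged]


def import_peaks(path, score_column: int = 4) -> RegionSet:
    """Load an externally produced peak BED, merge overlaps, rank by score.

    ``score_column`` is the 0-based column index of the enrichment score
    (4 for the standard BED score field).  Overlapping records are merged
    keeping the maximum score.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return RegionSet([], caller_label="imported")
    if df.shape[1] <= max(score_column, 2):
        raise ValueError(
            f"{path}: needs a score in column {score_column} "
            f"(file has {df.shape[1]} columns)"
        )
    rows = list(
        zip(
            df.iloc[:, 0].astype(str),
            df.iloc[:, 1].astype(int),
            df.iloc[:, 2].astype(int),
            df.iloc[:, score_column].astype(float),
        )
    )
    return _rank_regions(_merge_scored(rows, bookended=False), None, "imported")


def build_master_list(sets: list[RegionSet | MasterList]) -> MasterList:
    """Union of all intervals with overlapping or book-ended intervals merged."""
    rows: list[tuple] = []
    for s in sets:
        if isinstance(s, MasterList):
            rows.extend((c, st, en, 0.0) for c, st, en in s.regions)
        else:
            rows.extend((r.chrom, r.start, r.end, 0.0) for r in s.regions)
    merged = _merge_scored(rows, bookended=True)
    return MasterList([(c, s, e) for c, s, e, _ in merged])


def master_bin_indices(layout: GenomeLayout, master: MasterList) -> dict[str, np.ndarray]:
    """Sorted unique local bin indices overlapping (>= 1 bp) a master region.

    Depends only on the layout and master list, so every sample sharing a
    layout gets an identically aligned restricted vector.
    """
    bw = layout.bin_width
    out: dict[str, np.ndarray] = {}
    by_chrom = master.by_chrom()
    for chrom in layout.chrom_names:
        if chrom not in by_chrom:
            out[chrom] = np.array([], dtype=np.int64)
            continue
        nb = layout.n_bins(chrom)
        pieces = []
        for s, e in by_chrom[chrom]:
            first = max(int(s) // bw, 0)
            last = min((int(e) - 1) // bw, nb - 1)
            if last >= first:
                pieces.append(np.arange(first, last + 1))
        out[chrom] = (
            np.unique(np.concatenate(pieces)) if pieces else np.array([], dtype=np.int64)
        )
    return out


def restrict_counts(bins: BinCounts, master: MasterList) -> np.ndarray:
    """Concatenated counts of every bin overlapping a master region, in genome order."""
    idx = master_bin_indices(bins.layout, master)
    vec = np.concatenate(
        [bins.counts[c][idx[c]] for c in bins.layout.chrom_names]
    ) if any(len(v) for v in idx.values()) else np.array([], dtype=np.int64)
    if vec.size == 0:
        warnings.warn("master list selects no bins; restricted vector is empty")
    return vec
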