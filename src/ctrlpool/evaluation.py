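"""Peak-set evaluation against gold standards.

Candidate peak sets (low-depth matching or pooled controls) are scored
against the gold standard — the peak set obtained with the full-depth
matching control — three ways:

* top-k% overlap sensitivity: both sets are truncated to their top
  ``ceil(k% * N)`` peaks by rank and the sensitivity is the fraction of
  truncated gold peaks overlapped (>= 1 bp) by a truncated candidate peak.
  Plotted over a grid of k this measures how faithfully the candidate
  reproduces the gold standard's peak *ranking*, not just its peak calls.
* positive predictive value: the fraction of candidate peaks overlapping
  any gold peak.
* PWM motif occurrence rate: the fraction of peaks containing at least one
  match to a position weight matrix at a score whose p-value under a
  zero-order background model is below a threshold (default 0.01), the
  threshold score being computed exactly by dynamic programming over the
  discretized score distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import Region, RegionSet

__all__ = [
    "OverlapCurve",
    "PWM",
    "MotifScanResult",
    "default_k_grid",
    "overlap_sensitivity",
    "ppv",
    "average_curves",
    "scan_motif",
    "summarize_experiment",
]


def default_k_grid() -> np.ndarray:
    """Rank cutoffs 5, 10, ..., 100 percent."""
    return np.arange(5, 101, 5, dtype=float)


@dataclass
class OverlapCurve:
    """Sensitivity as a function of the top-k% rank cutoff."""

    k_grid: np.ndarray
    sensitivity: np.ndarray
    n_repeats: int = 1
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.k_grid = np.asarray(self.k_grid, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if self.k_grid.shape != self.sensitivity.shape:
            raise ValueError("k_grid and sensitivity must be parallel")


def _region_hit(region: Region, targets: dict[str, np.ndarray], min_overlap: int) -> bool:
    """Does `region` overlap any target interval by >= min_overlap bp?"""
    arr = targets.get(region.chrom)
    if arr is None or len(arr) == 0:
        return False
    starts, ends = arr[:, 0], arr[:, 1]
    i = int(np.searchsorted(ends, region.start, side="right"))
    while i < len(starts) and starts[i] < region.end:
        if min(int(ends[i]), region.end) - max(int(starts[i]), region.start) >= min_overlap:
            return True
        i += 1
    return False


def _interval_index(regions: list[Region]) -> dict[str, np.ndarray]:
    out: dict[str, list] = {}
    for r in regions:
        out.setdefault(r.chrom, []).append((r.start, r.end))
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}


def overlap_sensitivity(
    candidate: RegionSet,
    gold: RegionSet,
    k_grid: np.ndarray | None = None,
    mode: str = "symmetric",
    min_overlap: int = 1,
) -> OverlapCurve:
    """Top-k% rank-ordered overlap sensitivity of a candidate peak set.

    In the default symmetric mode both sets are truncated to their top
    ``ceil(k% * N)`` peaks (each relative to its own size) before
    computing the fraction of (truncated) gold peaks hit;
    ``mode="candidate_only"`` keeps the full gold set and truncates only
    the candidate; ``mode="equal_depth"`` truncates both lists to the same
    number of peaks, ``ceil(k% * N_gold)`` — a pure ranking-agreement
    measure that does not reward a candidate for calling more peaks.
    """
    if k_grid is None:
        k_grid = default_k_grid()
    k_grid = np.asarray(k_grid, dtype=float)
    if mode not in ("symmetric", "candidate_only", "equal_depth"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(gold) == 0:
        raise ValueError("sensitivity is undefined against an empty gold standard")
    if len(candidate) == 0:
        return OverlapCurve(k_grid, np.zeros_like(k_grid))
    gold_ranked = gold.sorted_by_rank()
    cand_ranked = candidate.sorted_by_rank()
    sens = np.empty_like(k_grid)
    for a, k in enumerate(k_grid):
        if mode == "symmetric":
            ng = int(np.ceil(k / 100.0 * len(gold_ranked)))
            nc = int(np.ceil(k / 100.0 * len(cand_ranked)))
        elif mode == "equal_depth":
            ng = int(np.ceil(k / 100.0 * len(gold_ranked)))
            nc = ng
        else:  # candidate_only
            ng = len(gold_ranked)
            nc = int(np.ceil(k / 100.0 * len(cand_ranked)))
        g_top = gold_ranked[:ng]
        c_idx = _interval_index(cand_ranked[:nc])
        hits = sum(_region_hit(g, c_idx, min_overlap) for g in g_top)
        sens[a] = hits / len(g_top)
    return OverlapCurve(k_grid, sens)


def ppv(candidate: RegionSet, gold: RegionSet, min_overlap: int = 1) -> float:
    """Fraction of candidate peaks overlapping at least one gold peak."""
    if len(gold) == 0:
        raise ValueError("PPV is undefined against an empty gold standard")
    if len(candidate) == 0:
        warnings.warn("empty candidate peak set; PPV undefined (NaN)")
        return float("nan")
    g_idx = _interval_index(gold.regions)
    hits = sum(_region_hit(c, g_idx, min_overlap) for c in candidate.regions)
    return hits / len(candidate)


def average_curves(curves: list[OverlapCurve]) -> OverlapCurve:
    """Pointwise mean and sample standard deviation over curves."""
    if not curves:
        raise ValueError("nothing to average")
    grid = curves[0].k_grid
    for c in curves[1:]:
        if not np.array_equal(c.k_grid, grid):
            raise ValueError("curves are defined on different k grids")
    M = np.vstack([c.sensitivity for c in curves])
    sd = M.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(grid.shape)
    return OverlapCurve(grid, M.mean(axis=0), n_repeats=len(curves), sd=sd)


_BASES = "ACGT"
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass
class PWM:
    """A position weight matrix over {A, C, G, T} with a background model.

    ``matrix`` is (width, 4) per-position probabilities (rows sum to 1);
    ``background`` the zero-order background nucleotide distribution.
    Scores are log2 odds of the motif versus the background.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be (width, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("matrix rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray, pseudocount: float = 1e-4,
                    background: np.ndarray | None = None) -> "PWM":
        counts = np.asarray(counts, dtype=np.float64) + pseudocount
        matrix = counts / counts.sum(axis=1, keepdims=True)
        kw = {} if background is None else {"background": np.asarray(background)}
        return cls(motif_id, matrix, **kw)

    @classmethod
    def from_jaspar(cls, path, pseudocount: float = 1e-4) -> "PWM":
        """Load a JASPAR-format count matrix (via Biopython's motif parser)."""
        from Bio import motifs as bio_motifs

        with open(path) as fh:
            m = bio_motifs.read(fh, "jaspar")
        counts = np.array([[m.counts[b][i] for b in _BASES] for i in range(m.length)])
        return cls.from_counts(m.matrix_id or m.name or "motif", counts, pseudocount)

    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    def score_threshold(self, p_threshold: float = 0.01, precision: float = 1e-3) -> float:
        """Smallest score with background p-value <= p_threshold.

        The exact null score distribution is computed by dynamic
        programming over per-position scores discretized to ``precision``
        bits: positions are convolved one at a time, each base weighted by
        its background probability.  Per-position scores are rounded up to
        the grid, which makes the threshold conservative (the realized
        false-positive rate never exceeds ``p_threshold``) with error at
        most ``width * precision`` bits.
        """
        lo = np.ceil(self.log_odds() / precision).astype(np.int64)
        dist = np.array([1.0])
        offset = 0  # score (in precision units) of dist[0]
        for i in range(self.width):
            smin, smax = int(lo[i].min()), int(lo[i].max())
            new = np.zeros(len(dist) + (smax - smin))
            for b in range(4):
                s = int(lo[i, b]) - smin
                new[s: s + len(dist)] += self.background[b] * dist
            dist = new
            offset += smin
        tail = np.cumsum(dist[::-1])[::-1]
        ok = np.flatnonzero(tail <= p_threshold)
        if ok.size == 0:
            return float((offset + len(dist)) * precision)  # unattainable
        return float((offset + ok[0]) * precision)

    def scan(self, seq: str, both_strands: bool = True) -> np.ndarray:
        """Best-strand log-odds score at every start position of ``seq``.

        Windows containing an ambiguous base score -inf.  With
        ``both_strands=False`` only the forward strand is scored (useful
        for calibrating the score threshold against its p-value).
        """
        code = _encode(seq)
        w = self.width
        L = len(code) - w + 1
        if L <= 0:
            return np.array([])
        lo = self.log_odds()
        lo_rc = lo[::-1, ::-1]  # reverse complement strand
        fwd = np.zeros(L)
        rev = np.zeros(L)
        valid = np.ones(L, dtype=bool)
        for i in range(w):
            c = code[i: i + L]
            good = c >= 0
            valid &= good
            cc = np.where(good, c, 0)
            fwd += lo[i, cc]
            if both_strands:
                rev += lo_rc[i, cc]
        best = np.maximum(fwd, rev) if both_strands else fwd
        best[~valid] = -np.inf
        return best


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class MotifScanResult:
    """Per-peak motif hit flags and the overall occurrence rate."""

    hits: list[bool | None]  # None = peak excluded (> 50% N)
    occurrence_rate: float
    threshold: float
    n_excluded: int

    def to_frame(self, peaks: RegionSet) -> pd.DataFrame:
        ranked = peaks.sorted_by_rank()
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in ranked],
                "start": [r.start for r in ranked],
                "end": [r.end for r in ranked],
                "rank": [r.rank for r in ranked],
                "motif_hit": self.hits,
            }
        )


def scan_motif(
    peaks: RegionSet,
    genome: dict[str, str],
    pwm: PWM,
    p_threshold: float = 0.01,
) -> MotifScanResult:
    """Fraction of peaks with at least one PWM match at the p-value threshold.

    ``genome`` maps chromosome names to sequences (load a FASTA with
    :func:`ctrlpool.synthetic_data.load_fasta` or Biopython).  Both strands
    are scanned; a peak whose sequence is more than 50% ambiguous (N) is
    excluded from the denominator.
    """
    if len(peaks) == 0:
        raise ValueError("cannot scan an empty peak set")
    thr = pwm.score_threshold(p_threshold)
    hits: list[bool | None] = []
    n_excluded = 0
    for r in peaks.sorted_by_rank():
        seq = genome[r.chrom][r.start: r.end]
        if len(seq) == 0 or sum(1 for ch in seq.upper() if ch == "N") > 0.5 * len(seq):
            hits.append(None)
            n_excluded += 1
            continue
        scores = pwm.scan(seq)
        hits.append(bool(scores.size and np.nanmax(scores) >= thr))
    included = [h for h in hits if h is not None]
    if not included:
        raise ValueError("all peaks excluded from motif scan (ambiguous sequence)")
    return MotifScanResult(
        hits=hits,
        occurrence_rate=sum(included) / len(included),
        threshold=thr,
        n_excluded=n_excluded,
    )


def summarize_experiment(result, k_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Tidy mean/sd sensitivity and PPV per (design, fraction, k).

    Curves and PPVs are computed for every (ChIP sample x repeat) against
    that sample's gold standard and averaged, mirroring how repeated
    pooling experiments are reported.
    """
    if k_grid is None:
        k_grid = default_k_grid()
    rows = []
    for f in result.fractions:
        for design in ("M", "P"):
            curves, ppvs = [], []
            for rep in range(result.repeats):
                for i in range(result.n_chips):
                    rs = result.peaks[(rep, f, design, i)]
                    curves.append(overlap_sensitivity(rs, result.gold[i], k_grid))
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        ppvs.append(ppv(rs, result.gold[i]))
            avg = average_curves(curves)
            mean_ppv = float(np.nanmean(ppvs)) if not all(np.isnan(ppvs)) else float("nan")
            for a, k in enumerate(avg.k_grid):
                rows.append(
                    {
                        "design": design,
                        "fraction": f,
                        "k_percent": float(k),
                        "mean_sensitivity": float(avg.sensitivity[a]),
                        "sd_sensitivity": float(avg.sd[a]),
                        "mean_ppv": mean_ppv,
                        "n_curves": avg.n_repeats,
                    }
                )
    return pd.DataFrame(rows)
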