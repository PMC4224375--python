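"""Matched-cost pooling designs, unequal-depth schemes and the experiment runner.

Two designs are compared at identical sequencing cost.  In Design M
(matching), each biological replicate's ChIP sample is analysed against its
own control, subsampled to a per-replicate fraction of full depth.  In
Design P (pooled), the very same subsampled controls are combined in
silico into one deeper control shared by every ChIP sample.  Because
Design P pools exactly the reads Design M would have sequenced, the two
designs consume identical totals of control reads.

When the two replicate controls have very different depths (n1 <= n2),
three pooling schemes with their own gold standards apply:

========  ============  ============  =========================
scheme    from R1       from R2       gold standard (from R2)
========  ============  ============  =========================
pool_1    n1/2          n2/2          n1/2 + n2/2   (GS_1)
pool_2    n1/2          n1/2          n1            (GS_2)
pool_3    n1            n1            2*n1          (GS_3)
========  ============  ============  =========================

Gold standards are always drawn from the deeper replicate; scheme 3
requires 2*n1 <= n2.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .enrichment import RegionSet, call_peaks
from .read_io import BinCounts, GenomeLayout, ReadSet, bin_counts, pool_reads, subsample_reads

__all__ = [
    "DesignSpec",
    "UnequalScheme",
    "ExperimentResult",
    "derive_seed",
    "make_matching_design",
    "make_pooled_design",
    "build_unequal_schemes",
    "run_experiment",
    "design_cost_ratio",
]


def derive_seed(base_seed: int, *keys) -> int:
    """Derive a reproducible child seed from a base seed and context keys.

    Keys (repeat index, replicate label, role, fraction, ...) are hashed
    with CRC32 and fed into a SeedSequence, so draws in different contexts
    are independent but every context is exactly reproducible.
    """
    ints = [zlib.crc32(repr(k).encode()) for k in keys]
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, *ints])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class DesignSpec:
    """One arm of a matched-cost comparison.

    ``kind`` is "M" (per-replicate matching controls) or "P" (one pooled
    control); ``per_replicate_fraction`` is the fraction of each full
    control's depth that the design sequences.
    """

    kind: str
    per_replicate_fraction: float
    replicate_ids: tuple[str, ...]
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("M", "P"):
            raise ValueError("kind must be 'M' or 'P'")
        if not 0 < self.per_replicate_fraction <= 1:
            raise ValueError("per_replicate_fraction must be in (0, 1]")


def design_cost_ratio(
    full_design: DesignSpec,
    reduced_design: DesignSpec,
    depths: list[int] | None = None,
) -> float:
    """Fold decrease in total control reads between two designs.

    With equal replicate depths this is the ratio of the per-replicate
    fractions; with explicit ``depths`` the realized (rounded) read totals
    are compared.
    """
    if depths is not None:
        if len(depths) != len(full_design.replicate_ids):
            raise ValueError("depths must be parallel to replicate_ids")
        full_total = sum(int(np.rint(full_design.per_replicate_fraction * d)) for d in depths)
        red_total = sum(int(np.rint(reduced_design.per_replicate_fraction * d)) for d in depths)
    else:
        full_total = full_design.per_replicate_fraction * len(full_design.replicate_ids)
        red_total = reduced_design.per_replicate_fraction * len(reduced_design.replicate_ids)
    if red_total == 0:
        raise ValueError("reduced design consumes zero reads")
    return float(full_total / red_total)


def make_matching_design(
    controls: list[ReadSet],
    fraction: float,
    seed: int,
    repeat: int = 0,
    labels: list[str] | None = None,
) -> list[ReadSet]:
    """Design M: subsample each replicate control to ``fraction`` of its depth.

    Per-replicate seeds are derived from ``seed`` and the context
    (repeat, replicate, fraction) so the draws are independent yet exactly
    reproducible.
    """
    if not controls:
        raise ValueError("need at least one control")
    labels = labels or [str(i) for i in range(len(controls))]
    return [
        subsample_reads(c, fraction, derive_seed(seed, "M", repeat, fraction, lab))
        for c, lab in zip(controls, labels)
    ]


def make_pooled_design(
    controls: list[ReadSet],
    fraction: float,
    seed: int,
    repeat: int = 0,
    labels: list[str] | None = None,
) -> ReadSet:
    """Design P: pool the Design-M subsamples into one control.

    Uses exactly the same seed derivation (hence exactly the same reads) as
    :func:`make_matching_design`, which is what makes the two designs
    strictly cost-identical.
    """
    return pool_reads(make_matching_design(controls, fraction, seed, repeat, labels))


@dataclass
class UnequalScheme:
    """One unequal-depth pooling scheme with its realized read sets."""

    scheme_id: str
    pooled: ReadSet
    gold: ReadSet
    reads_from_r1: int
    reads_from_r2: int
    gs_reads: int
    gs_source: str = "R2"
    shared_r2_reads: int = 0


def build_unequal_schemes(r1: ReadSet, r2: ReadSet, seed: int) -> list[UnequalScheme]:
    """Construct the three unequal-depth pooling schemes and their gold standards.

    Requires ``depth(r1) <= depth(r2)``.  All draws are without
    replacement; within a scheme, the gold standard and the pooled
    contribution from R2 are drawn disjointly whenever R2 is deep enough,
    otherwise the unavoidable overlap is recorded in ``shared_r2_reads``
    (at the scheme-3 boundary ``n2 == 2*n1`` the gold standard uses all of
    R2).  Scheme 3 is skipped with a warning when ``2*n1 > n2``.
    """
    n1, n2 = r1.depth, r2.depth
    if n1 > n2:
        raise ValueError(f"requires depth(r1) <= depth(r2), got {n1} > {n2}")
    h1 = int(np.rint(n1 / 2))
    h2 = int(np.rint(n2 / 2))
    plans = [
        ("pool_1", h1, h2, h1 + h2),
        ("pool_2", h1, h1, n1),
        ("pool_3", n1, n1, 2 * n1),
    ]
    out = []
    for sid, m1, m2, g in plans:
        if sid == "pool_3" and 2 * n1 > n2:
            warnings.warn(f"skipping pool_3: 2*n1 = {2 * n1} exceeds n2 = {n2}")
            continue
        rng1 = np.random.default_rng(derive_seed(seed, sid, "R1"))
        rng2 = np.random.default_rng(derive_seed(seed, sid, "R2"))
        part1 = r1.take(np.sort(rng1.permutation(n1)[:m1]))
        perm2 = rng2.permutation(n2)
        pooled_part2 = r2.take(np.sort(perm2[:m2]))
        gold = r2.take(np.sort(perm2[n2 - g:]))
        shared = max(0, m2 + g - n2)
        pooled = pool_reads([part1, pooled_part2])
        pooled.source_label = f"{sid}(pooled)"
        gold.source_label = f"GS_{sid.split('_')[1]}"
        out.append(
            UnequalScheme(sid, pooled, gold, m1, m2, g, shared_r2_reads=shared)
        )
    return out


@dataclass
class ExperimentResult:
    """Peak sets from a repeated matched-cost pooling experiment.

    ``gold[i]`` is the gold-standard peak set of ChIP sample ``i`` (called
    against its full matching control).  ``peaks[(repeat, fraction,
    design, chip)]`` holds the Design-M / Design-P peak sets; ``design`` is
    "M" or "P".
    """

    gold: list[RegionSet]
    peaks: dict[tuple[int, float, str, int], RegionSet]
    fractions: tuple[float, ...]
    repeats: int
    base_seed: int
    n_chips: int
    control_depths: tuple[int, ...]
    control_m_depths: dict[tuple[int, float, int], int] = field(default_factory=dict)


def run_experiment(
    chips: list[ReadSet],
    controls: list[ReadSet],
    layout: GenomeLayout,
    fractions: tuple[float, ...] = (0.005, 0.05, 0.25, 0.5),
    repeats: int = 5,
    base_seed: int = 0,
    fragment_length: int = 150,
    fdr: float = 0.05,
    pseudocount: float = 1.0,
    min_gap_bins: int = 1,
) -> ExperimentResult:
    """Run the full matched-cost comparison, repeated with fresh subsamples.

    For every repeat and fraction the runner builds the Design-M controls
    (one subsample per replicate), the Design-P pooled control (the same
    reads combined), and calls peaks for each ChIP sample against (a) its
    full matching control — once, giving the gold standard, (b) its
    Design-M control, and (c) the shared Design-P control.  Everything is
    deterministic given ``base_seed``.
    """
    if len(controls) < len(chips):
        raise ValueError("need at least one control per ChIP sample")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    min_depth = min(c.depth for c in controls)
    for f in fractions:
        if int(np.rint(f * min_depth)) < 1000:
            warnings.warn(
                f"fraction {f} yields < 1000 control reads; correlations and "
                "peak calls at this depth are unreliable"
            )

    chip_bins = [bin_counts(c, layout, fragment_length) for c in chips]
    ctrl_bins = [bin_counts(c, layout, fragment_length) for c in controls]
    gold = [
        call_peaks(chip_bins[i], ctrl_bins[i], fdr, pseudocount, min_gap_bins)
        for i in range(len(chips))
    ]

    peaks: dict[tuple[int, float, str, int], RegionSet] = {}
    m_depths: dict[tuple[int, float, int], int] = {}
    for rep in range(repeats):
        for f in fractions:
            m_controls = make_matching_design(controls, f, base_seed, repeat=rep)
            pooled = pool_reads(m_controls)
            pooled_bins = bin_counts(pooled, layout, fragment_length)
            for i in range(len(chips)):
                mb = bin_counts(m_controls[i], layout, fragment_length)
                m_depths[(rep, f, i)] = m_controls[i].depth
                peaks[(rep, f, "M", i)] = call_peaks(
                    chip_bins[i], mb, fdr, pseudocount, min_gap_bins
                )
                peaks[(rep, f, "P", i)] = call_peaks(
                    chip_bins[i], pooled_bins, fdr, pseudocount, min_gap_bins
                )
    return ExperimentResult(
        gold=gold,
        peaks=peaks,
        fractions=tuple(fractions),
        repeats=repeats,
        base_seed=base_seed,
        n_chips=len(chips),
        control_depths=tuple(c.depth for c in controls),
        control_m_depths=m_depths,
    )
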