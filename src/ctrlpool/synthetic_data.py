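"""Read-level synthetic ChIP-seq scenarios with a controllable correlation dial.

The generator emulates the observable structure that drives pooling
decisions in real multiplexed control samples, without modelling
sequence-level biology:

* Per-bin background intensities are log-normal.  Each sample's log-rate
  is a Gaussian mixture ``sqrt(rho) * Z + sqrt(1 - rho) * E_i`` of a
  shared field ``Z`` and an independent field ``E_i``, so the pairwise
  correlation of log-rates between any two samples equals ``rho`` exactly
  — one interpretable dial reproducing the empirical high/low correlation
  classes.
* ChIP samples share their replicate's background and multiply planted,
  disjoint enrichment regions by per-region fold changes.
* Reads are drawn multinomially over bins at a chosen depth (correlation
  between samples attenuates as depth falls, as observed in real data),
  positioned uniformly within their bin with fair-coin strands.
* Optional treatment perturbation (a fraction of bins shifted per
  condition) and a smooth multiplicative lab bias reproduce the
  multiple-treatment and cross-lab settings.

Presets mirror the sample groups of multiplexed control studies: multiple
biological replicates (MBRG) with high or low background sharing, unequal
replicate depths, multiple treatments (MTG), multiple cell lines (MCG),
and a lab-bias scenario.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .enrichment import MasterList
from .read_io import GenomeLayout, ReadSet, write_reads

__all__ = [
    "ScenarioConfig",
    "TruthTable",
    "Scenario",
    "PRESETS",
    "draw_background",
    "plant_enrichment",
    "sample_reads",
    "generate_scenario",
    "random_genome",
    "load_fasta",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    ``rho`` is the target pairwise correlation of log background rates
    between control samples (the dial behind the high/low classes).
    Depths are reads per sample; ``chip_for_control[i]`` names the control
    whose background ChIP sample ``i`` shares.
    """

    name: str = "custom"
    chrom_name: str = "chrS"
    chrom_length: int = 10_000_000
    bin_width: int = 200
    control_depths: tuple[int, ...] = (1_000_000, 1_000_000)
    chip_depths: tuple[int, ...] = (1_000_000, 1_000_000)
    chip_for_control: tuple[int, ...] = (0, 1)
    rho: float = 0.97
    mean_log: float = 0.0
    sd_log: float = 1.0
    n_regions: int = 200
    region_width_bins: tuple[int, int] = (3, 7)
    fold_range: tuple[float, float] = (8.0, 15.0)
    treatment_frac: float = 0.0
    treatment_sd: float = 1.0
    condition_of_control: tuple[int, ...] | None = None
    lab_bias_samples: tuple[int, ...] = ()
    lab_bias_amplitude: float = 1.0
    lab_bias_cycles: int = 200
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if any(d < 1 for d in self.control_depths + self.chip_depths):
            raise ValueError("depths must be >= 1")
        if max(self.chip_for_control, default=-1) >= len(self.control_depths):
            raise ValueError("chip_for_control references a missing control")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout((self.chrom_name,), (self.chrom_length,), self.bin_width)

    @property
    def n_controls(self) -> int:
        return len(self.control_depths)

    @property
    def n_chips(self) -> int:
        return len(self.chip_depths)


@dataclass
class TruthTable:
    """Latent state of a generated scenario: rates, planted regions, seeds."""

    control_rates: np.ndarray  # (n_controls, n_bins)
    chip_rates: np.ndarray  # (n_chips, n_bins)
    regions: pd.DataFrame  # chrom, start, end, fold
    rho: float
    seed: int

    def master_list(self) -> MasterList:
        return MasterList(
            [(r.chrom, int(r.start), int(r.end)) for r in self.regions.itertuples()]
        )


@dataclass
class Scenario:
    config: ScenarioConfig
    layout: GenomeLayout
    controls: list[ReadSet]
    chips: list[ReadSet]
    truth: TruthTable


def draw_background(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-control bin rate vectors with pairwise log-rate correlation rho.

    ``log rate_i = mean_log + sqrt(rho) * Z + sqrt(1 - rho) * E_i`` with
    ``Z`` shared and ``E_i`` independent N(0, sd_log) fields; the square
    roots make corr(log rate_i, log rate_j) = rho for every pair.
    Treatment perturbation and lab bias are applied on the log scale.
    """
    n_bins = config.layout.total_bins
    z = rng.normal(0.0, config.sd_log, size=n_bins)
    logr = np.empty((config.n_controls, n_bins))
    for i in range(config.n_controls):
        e = rng.normal(0.0, config.sd_log, size=n_bins)
        logr[i] = config.mean_log + np.sqrt(config.rho) * z + np.sqrt(1.0 - config.rho) * e
    if config.treatment_frac > 0:
        conditions = config.condition_of_control or tuple([0] * config.n_controls)
        n_pert = int(round(config.treatment_frac * n_bins))
        pert_bins = rng.choice(n_bins, size=n_pert, replace=False)
        for cond in sorted(set(conditions) - {0}):
            shift = rng.normal(0.0, config.treatment_sd, size=n_pert)
            for i, c in enumerate(conditions):
                if c == cond:
                    logr[i, pert_bins] += shift
    for i in config.lab_bias_samples:
        phase = 2 * np.pi * config.lab_bias_cycles * np.arange(n_bins) / n_bins
        logr[i] += config.lab_bias_amplitude * np.sin(phase)
    return np.exp(logr)


def plant_enrichment(
    control_rates: np.ndarray, config: ScenarioConfig, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """ChIP rate vectors with disjoint planted enrichment regions.

    The genome is divided into ``n_regions`` equal slots and one region of
    random width is placed at a random offset within each slot, which
    guarantees disjointness.  Each region's rate is multiplied by a fold
    drawn uniformly from ``fold_range`` in ChIP samples only.
    """
    n_bins = control_rates.shape[1]
    bw = config.bin_width
    chip_rates = control_rates[list(config.chip_for_control)].copy()
    rows = []
    if config.n_regions > 0:
        slot = n_bins // config.n_regions
        wmin, wmax = config.region_width_bins
        if slot < wmax + 1:
            raise ValueError("too many regions for the genome size")
        mask_fold = np.ones(n_bins)
        for r in range(config.n_regions):
            w = int(rng.integers(wmin, wmax + 1))
            off = int(rng.integers(0, slot - w))
            first = r * slot + off
            fold = float(rng.uniform(*config.fold_range))
            mask_fold[first: first + w] = fold
            start = first * bw
            end = min((first + w) * bw, config.chrom_length)
            rows.append((config.chrom_name, start, end, fold))
        chip_rates *= mask_fold
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "fold"])
    return chip_rates, regions


def sample_reads(
    rates: np.ndarray,
    depth: int,
    seed: int | np.random.Generator,
    layout: GenomeLayout,
    source_label: str = "",
) -> ReadSet:
    """Draw exactly ``depth`` reads multinomially over bins.

    Read 5' positions are uniform within their bin and strands are fair
    coins, so at high depth the binned counts recover the rate vector up
    to multinomial noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = np.asarray(rates, dtype=np.float64)
    if rates.ndim != 1 or len(rates) != layout.total_bins:
        raise ValueError("rates must be one value per layout bin")
    if depth == 0:
        return ReadSet.empty(source_label)
    counts = rng.multinomial(depth, rates / rates.sum())
    gbin = np.repeat(np.arange(len(counts)), counts)
    offsets = layout.bin_offsets
    nbins = layout.bins_per_chrom
    lengths = np.asarray(layout.chrom_lengths)
    ci = np.searchsorted(offsets, gbin, side="right") - 1
    local = gbin - offsets[ci]
    bin_start = local * layout.bin_width
    bin_end = np.minimum(bin_start + layout.bin_width, lengths[ci])
    pos5 = bin_start + rng.integers(0, bin_end - bin_start)
    strand = (rng.integers(0, 2, size=depth) * 2 - 1).astype(np.int8)
    chrom = np.asarray(layout.chrom_names, dtype=object)[ci].astype(str)
    return ReadSet(chrom, pos5, strand, source_label=source_label)


def _preset(name: str, **kw) -> ScenarioConfig:
    return ScenarioConfig(name=name, **kw)


PRESETS: dict[str, ScenarioConfig] = {
    # Biological replicates sharing background (high class, rho >= 0.95).
    "mbrg_high": _preset("mbrg_high", rho=0.97),
    # Biological replicates with largely distinct backgrounds (low class).
    "mbrg_low": _preset("mbrg_low", rho=0.3),
    # Replicates at ~1:3 depth, the unequal-depth scheme setting.
    "mbrg_unequal_depth": _preset(
        "mbrg_unequal_depth",
        rho=0.97,
        control_depths=(600_000, 1_800_000),
        chip_depths=(600_000, 1_800_000),
    ),
    # One cell type, three treatments, four multiplexed controls.
    "mtg": _preset(
        "mtg",
        rho=0.92,
        control_depths=(1_000_000,) * 4,
        chip_depths=(1_000_000,) * 3,
        chip_for_control=(0, 2, 3),
        condition_of_control=(0, 0, 1, 2),
        treatment_frac=0.05,
    ),
    # Different cell lines that nonetheless share background (high class).
    "mcg_high": _preset("mcg_high", rho=0.93),
    # Different cell lines with independent backgrounds.
    "mcg_low": _preset("mcg_low", rho=0.0),
    # Two labs: the second control carries a smooth multiplicative bias.
    "lab_effect": _preset(
        "lab_effect",
        rho=0.95,
        chip_depths=(1_000_000,),
        chip_for_control=(0,),
        lab_bias_samples=(1,),
    ),
}


def generate_scenario(
    preset: str | ScenarioConfig,
    seed: int,
    out_dir: str | None = None,
    overrides: dict | None = None,
    force: bool = False,
) -> Scenario:
    """Generate a full scenario (controls, ChIPs, truth) from a preset.

    With ``out_dir``, writes gzip tagAlign files per sample, a chrom.sizes
    file, the planted-region truth table (TSV) and a manifest (YAML);
    refuses a non-empty directory unless ``force``.
    """
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        config = PRESETS[preset]
    else:
        config = preset
    if overrides:
        config = replace(config, **overrides)
    config = replace(config, seed=int(seed))

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC7B1]))
    layout = config.layout
    control_rates = draw_background(config, rng)
    chip_rates, regions = plant_enrichment(control_rates, config, rng)

    controls = [
        sample_reads(control_rates[i], d, rng, layout, source_label=f"control_{i}")
        for i, d in enumerate(config.control_depths)
    ]
    chips = [
        sample_reads(chip_rates[i], d, rng, layout, source_label=f"chip_{i}")
        for i, d in enumerate(config.chip_depths)
    ]
    truth = TruthTable(control_rates, chip_rates, regions, config.rho, int(seed))
    scenario = Scenario(config, layout, controls, chips, truth)
    if out_dir is not None:
        _write_scenario(scenario, out_dir, force=force)
    return scenario


def _write_scenario(scenario: Scenario, out_dir: str, force: bool = False) -> None:
    os.makedirs(out_dir, exist_ok=True)
    if os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} is not empty; pass force=True to overwrite")
    layout = scenario.layout
    layout.to_chrom_sizes(os.path.join(out_dir, "chrom.sizes"))
    files = {}
    for rs in scenario.controls + scenario.chips:
        fname = f"{rs.source_label}.tagAlign.gz"
        write_reads(rs, os.path.join(out_dir, fname), fmt="tagalign")
        files[rs.source_label] = fname
    scenario.truth.regions.to_csv(
        os.path.join(out_dir, "truth_regions.tsv"), sep="\t", index=False
    )
    manifest = {
        "scenario": asdict(scenario.config),
        "seed": scenario.truth.seed,
        "files": files,
        "truth_regions": "truth_regions.tsv",
        "chrom_sizes": "chrom.sizes",
    }
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def random_genome(layout: GenomeLayout, seed: int, gc: float = 0.5) -> dict[str, str]:
    """An i.i.d. random genome matching a layout (for motif-scan testing)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    return {
        c: "".join(bases[rng.choice(4, size=l, p=p)])
        for c, l in zip(layout.chrom_names, layout.chrom_lengths)
    }


def load_fasta(path) -> dict[str, str]:
    """Load a FASTA file into a dict of upper-case sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
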