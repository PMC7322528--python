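"""Seeded synthetic multi-omics generators with planted ground truth.

Every generator is a pure function of ``(config, seed)``; re-runs with the
same configuration are byte-identical. The generators emulate, at toy
scale, the inputs of an ESC-to-neuron differentiation time course:

* a toy genome with tiled genes, promoter and distal accessibility peaks;
* negative-binomial ATAC/RNA count matrices and log-normal protein
  intensities over the time grid, with planted direction labels and
  cross-layer coupling at a configurable lag;
* ChIP peak sets drawn from regulatory archetypes with bedGraph mark
  tracks, jittered replicate sets, and a co-bound subset with elevated
  marks and nearest-gene expression;
* iBAQ-like pull-down tables with a top-ranked bait, exclusive and
  fold-enriched interactors over an IgG background.

The planted truth is returned alongside the data so every downstream
stage can be scored without re-deriving ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .chromstate import SignalTrack
from .intervals import (
    GeneModel,
    GenomicInterval,
    Peak,
    TSSRecord,
    assign_peaks_to_genes,
)
from .interactome import PulldownTable, RunMeta
from .tfactivity import PWM

__all__ = [
    "SimConfig",
    "GenomeBundle",
    "generate_genome",
    "generate_multiomics",
    "generate_chip",
    "generate_pulldown",
    "simulate_coupled_directions",
    "simulate_tf_sites",
    "simulate_rate_expression",
    "random_pwm",
]


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults at toy scale.

    The defaults mirror the modelled study design: RNA/ATAC on days
    0/4/8/12 with 4 replicates, proteomics every 2 days to day 10 with 2
    replicates, negative-binomial dispersion 0.1 and log-normal library
    sizes (CV 0.2). Planted cross-layer coupling uses conditional
    direction probabilities (0.8 coupled vs 0.2 base, odds ratio 16)
    with a default lag of one grid step (4 days).
    """

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 200_000
    n_genes: int = 100
    n_peaks: int = 400
    promoter_fraction: float = 0.8
    promoter_max_dist: int = 1500
    peak_width: int = 400
    gene_region_frac: float = 0.5
    # design
    rna_days: tuple[int, ...] = (0, 4, 8, 12)
    atac_days: tuple[int, ...] = (0, 4, 8, 12)
    protein_days: tuple[int, ...] = (0, 2, 4, 6, 8, 10)
    rna_reps: int = 4
    atac_reps: int = 4
    protein_reps: int = 2
    # noise model
    dispersion: float = 0.1
    libsize_cv: float = 0.2
    base_log2_mean: float = 7.0
    base_log2_sd: float = 1.5
    protein_noise_sd: float = 0.25
    # planted effects
    frac_changed: float = 0.3
    effect_min: float = 1.0
    effect_max: float = 2.0
    p_couple: float = 0.8
    p_base: float = 0.2
    lag_days: int = 4
    # ChIP layer
    n_chip_peaks: int = 100
    n_chip_replicates: int = 3
    replicate_presence: float = 0.9
    replicate_jitter: int = 30
    chip_group_sd: float = 0.1
    cobound_fraction: float = 0.3
    cobound_mark_shift: float = 2.0
    cobound_expression_shift: float = 2.0
    # pull-down layer
    n_exclusive: int = 30
    n_enriched: int = 30
    n_background: int = 140
    min_fold: float = 4.0
    bait_id: str = "BAIT"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("rna_days", "atac_days", "protein_days"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        for key in ("rna_days", "atac_days", "protein_days"):
            raw[key] = list(raw[key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class GenomeBundle:
    sequences: dict[str, str]
    tss: list[TSSRecord]
    gene_model: GeneModel
    peaks: list[Peak]
    peak_gene: dict[str, str]  # peak_id -> intended gene (promoter peaks)
    peak_kind: dict[str, str]  # peak_id -> promoter | promoter_extra | distal

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_tss_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tchrom\ttss\tstrand\n")
            for t in self.tss:
                fh.write(f"{t.gene_id}\t{t.chrom}\t{t.tss}\t{t.strand}\n")


def generate_genome(config: SimConfig) -> GenomeBundle:
    """Toy genome: random sequence, tiled genes, promoter + distal peaks.

    Genes are tiled with even spacing per chromosome; a configured
    fraction of genes gets one promoter accessibility peak whose nearest
    base lies within ``promoter_max_dist`` of the TSS; the remaining
    peaks are placed in intergenic space away from every promoter
    window.
    """
    if config.chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10 kb")
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sequences = {
        c: "".join(rng.choice(list("ACGT"), size=config.chrom_length))
        for c in chroms
    }
    genes_per_chrom = [
        config.n_genes // config.n_chroms
        + (1 if i < config.n_genes % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    # genes are tiled in the first gene_region_frac of each chromosome; the
    # remainder is gene-free space holding the distal peaks
    gene_region = int(config.chrom_length * config.gene_region_frac)
    spacing = [gene_region // (n + 1) for n in genes_per_chrom]
    if any(s < 1800 for s in spacing):
        raise ValueError("gene tiling infeasible: genes too dense for chromosome")
    tss_records: list[TSSRecord] = []
    gene_spans: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    gid = 0
    for ci, chrom in enumerate(chroms):
        for j in range(genes_per_chrom[ci]):
            gene_id = f"gene_{gid:04d}"
            gid += 1
            anchor = spacing[ci] * (j + 1)
            length = int(rng.integers(1000, max(1200, spacing[ci] - 400)))
            strand = "+" if rng.random() < 0.5 else "-"
            start = anchor
            end = min(anchor + length, config.chrom_length - 1)
            gene_spans[gene_id] = GenomicInterval(chrom, start, end, strand)
            tss = start if strand == "+" else end - 1
            tss_records.append(TSSRecord(gene_id, chrom, tss, strand))
            # 2 exons at the span ends, the middle is intronic
            exon_len = max(150, length // 5)
            exons[gene_id] = [
                GenomicInterval(chrom, start, start + exon_len, strand),
                GenomicInterval(chrom, end - exon_len, end, strand),
            ]
    gene_model = GeneModel(tss=tss_records, gene_spans=gene_spans, exons=exons)

    peaks: list[Peak] = []
    peak_gene: dict[str, str] = {}
    peak_kind: dict[str, str] = {}
    half = config.peak_width // 2
    n_prom = int(round(config.promoter_fraction * config.n_genes))
    prom_gene_idx = rng.choice(config.n_genes, size=n_prom, replace=False)
    pid = 0
    for gi in sorted(prom_gene_idx):
        t = tss_records[gi]
        max_off = min(config.promoter_max_dist - half, 600)
        offset = int(rng.integers(-max_off, max_off + 1))
        center = int(np.clip(t.tss + offset, half, config.chrom_length - half - 1))
        peak_id = f"peak_{pid:04d}"
        pid += 1
        peaks.append(
            Peak(GenomicInterval(t.chrom, center - half, center + half), peak_id)
        )
        peak_gene[peak_id] = t.gene_id
        peak_kind[peak_id] = "promoter"
    # distal peaks: slot-tiled with jitter in the gene-free region, clear of
    # every promoter window
    n_distal = config.n_peaks - n_prom
    distal_start = gene_region + config.promoter_max_dist + 500
    free = config.chrom_length - distal_start
    per_chrom_distal = [
        n_distal // config.n_chroms
        + (1 if i < n_distal % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    if any(free // max(1, n) < config.peak_width + 20 for n in per_chrom_distal):
        raise ValueError("infeasible peak tiling: could not place distal peaks")
    for ci, chrom in enumerate(chroms):
        n_here = per_chrom_distal[ci]
        slot = free // max(1, n_here)
        for j in range(n_here):
            jitter = int(rng.integers(0, max(1, slot - config.peak_width)))
            start = distal_start + j * slot + jitter
            peak_id = f"peak_{pid:04d}"
            pid += 1
            peaks.append(
                Peak(GenomicInterval(chrom, start, start + config.peak_width), peak_id)
            )
            peak_kind[peak_id] = "distal"
    # the planted gene of a promoter peak is its actual nearest TSS, so the
    # truth agrees with downstream nearest-gene assignment by construction
    links, _ = assign_peaks_to_genes(peaks, tss_records, config.promoter_max_dist)
    nearest = {lk.peak_id: lk.gene_id for lk in links}
    seen_genes: set[str] = set()
    for peak_id in list(peak_gene):
        gene = nearest[peak_id]
        if gene in seen_genes:  # two promoter peaks collapsing onto one gene
            del peak_gene[peak_id]
            peak_kind[peak_id] = "promoter_extra"
        else:
            peak_gene[peak_id] = gene
            seen_genes.add(gene)
    return GenomeBundle(sequences, tss_records, gene_model, peaks, peak_gene, peak_kind)


# ---------------------------------------------------------------------------
# multi-omics time course


def _adjacent_contrast_days(days: Sequence[int]) -> list[tuple[int, int]]:
    return [(late, early) for early, late in zip(days, days[1:])]


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def generate_multiomics(
    config: SimConfig, genome: GenomeBundle
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """ATAC/RNA count matrices, protein intensities, and planted truth.

    Effects are planted on log2 trajectories. Per gene and adjacent-day
    step, the ATAC (promoter peak) level may shift by a log2 fold change
    of magnitude >= 1; the RNA level copies that direction ``lag_days``
    later with probability ``p_couple`` (and shifts spontaneously at the
    base rate otherwise); the protein level copies the RNA direction one
    lag later with the same probabilities. Counts are negative-binomial
    around the 2^trajectory means with log-normal library sizes;
    proteins are log-normal around their trajectory.

    Returns ``(atac_counts, rna_counts, protein_intensities, truth)``
    where truth holds per-feature direction labels per contrast step.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = [t.gene_id for t in genome.tss]
    n_genes = len(genes)
    gene_to_prom = {g: p for p, g in genome.peak_gene.items()}
    steps = _adjacent_contrast_days(config.rna_days)  # shared ATAC/RNA grid
    grid = list(config.rna_days)

    def draw_effect(size):
        mag = rng.uniform(config.effect_min, config.effect_max, size=size)
        sign = rng.choice([-1.0, 1.0], size=size)
        return mag * sign

    # planted shift per gene per step, source layer = ATAC
    atac_shift = np.zeros((n_genes, len(steps)))
    changed = rng.random((n_genes, len(steps))) < config.frac_changed
    atac_shift[changed] = draw_effect(changed.sum())

    # RNA copies ATAC direction at +lag with p_couple, else base-rate change
    rna_shift = np.zeros((n_genes, len(steps)))
    for si, (late, _early) in enumerate(steps):
        target_day = late + config.lag_days
        ti = next(
            (k for k, (tl, _te) in enumerate(steps) if tl == target_day), None
        )
        for g in range(n_genes):
            if atac_shift[g, si] != 0 and ti is not None:
                if rng.random() < config.p_couple:
                    rna_shift[g, ti] = np.sign(atac_shift[g, si]) * rng.uniform(
                        config.effect_min, config.effect_max
                    )
    spont = (rna_shift == 0) & (rng.random((n_genes, len(steps))) < config.p_base)
    rna_shift[spont] = draw_effect(spont.sum())

    # protein copies RNA at +lag
    prot_shift = np.zeros((n_genes, len(steps)))
    for si, (late, _early) in enumerate(steps):
        target_day = late + config.lag_days
        ti = next((k for k, (tl, _te) in enumerate(steps) if tl == target_day), None)
        for g in range(n_genes):
            if rna_shift[g, si] != 0 and ti is not None:
                if rng.random() < config.p_couple:
                    prot_shift[g, ti] = np.sign(rna_shift[g, si]) * rng.uniform(
                        config.effect_min, config.effect_max
                    )
    spont = (prot_shift == 0) & (rng.random((n_genes, len(steps))) < config.p_base)
    prot_shift[spont] = draw_effect(spont.sum())

    def trajectory(baseline: np.ndarray, shifts: np.ndarray) -> np.ndarray:
        # level at grid day d = baseline + sum of shifts at steps with late <= d
        levels = np.tile(baseline[:, None], (1, len(grid)))
        for si, (late, _early) in enumerate(steps):
            for di, day in enumerate(grid):
                if day >= late:
                    levels[:, di] += shifts[:, si]
        return levels

    base_rna = rng.normal(config.base_log2_mean, config.base_log2_sd, n_genes)
    base_atac = rng.normal(config.base_log2_mean, config.base_log2_sd, n_genes)
    rna_levels = trajectory(base_rna, rna_shift)
    atac_levels = trajectory(base_atac, atac_shift)

    def count_matrix(levels: np.ndarray, days, reps, index, tag) -> tuple[pd.DataFrame, dict]:
        cols, design = [], {}
        data = []
        for day in days:
            di = grid.index(day) if day in grid else None
            for rep in range(1, reps + 1):
                name = f"{tag}_d{day}_r{rep}"
                cols.append(name)
                design[name] = (day, rep)
                mu = 2.0 ** levels[:, di]
                lib = rng.lognormal(0.0, config.libsize_cv)
                data.append(_nb_counts(rng, mu * lib, config.dispersion))
        return pd.DataFrame(np.column_stack(data), index=index, columns=cols), design

    rna_counts, rna_design = count_matrix(
        rna_levels, config.rna_days, config.rna_reps, genes, "rna"
    )
    prom_peaks = [gene_to_prom.get(g) for g in genes]
    atac_rows = [p is not None for p in prom_peaks]
    atac_index = [p for p in prom_peaks if p is not None]
    atac_counts, atac_design = count_matrix(
        atac_levels[atac_rows], config.atac_days, config.atac_reps, atac_index, "atac"
    )

    # protein: log-normal intensities following the RNA-lagged trajectory,
    # mapped onto the denser protein day grid (level held between grid days)
    prot_levels_grid = trajectory(base_rna + rng.normal(0, 0.5, n_genes), prot_shift)
    prot_cols, prot_design, prot_data = [], {}, []
    for day in config.protein_days:
        di = max((i for i, d in enumerate(grid) if d <= day), default=0)
        for rep in range(1, config.protein_reps + 1):
            name = f"protein_d{day}_r{rep}"
            prot_cols.append(name)
            prot_design[name] = (day, rep)
            noise = rng.normal(0, config.protein_noise_sd, n_genes)
            prot_data.append(2.0 ** (prot_levels_grid[:, di] + noise))
    protein = pd.DataFrame(np.column_stack(prot_data), index=genes, columns=prot_cols)

    def labels(shifts: np.ndarray, index) -> pd.DataFrame:
        lab = np.where(shifts > 0, "up", np.where(shifts < 0, "down", "ns"))
        return pd.DataFrame(
            lab, index=index, columns=[f"{late}v{early}" for late, early in steps]
        )

    truth = {
        "atac": labels(atac_shift[atac_rows], atac_index),
        "rna": labels(rna_shift, genes),
        "protein": labels(prot_shift, genes),
    }
    designs = {"rna": rna_design, "atac": atac_design, "protein": prot_design}
    return atac_counts, rna_counts, protein, {"labels": truth, "designs": designs}


def simulate_coupled_directions(
    n_pairs: int,
    p_source: float = 0.5,
    p_coupled: float = 0.8,
    p_base: float = 0.2,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], list[str]]:
    """Direction labels for linked pairs with a planted conditional coupling.

    Each pair's source is 'up' with probability ``p_source`` (else ns);
    the target is 'up' with probability ``p_coupled`` when the source is
    up and ``p_base`` otherwise. The analytic odds ratio of the
    (source up) x (target up) table is
    ``(p_coupled / (1 - p_coupled)) / (p_base / (1 - p_base))``.
    Returns ``(source_dirs, target_dirs, pair_ids)``.
    """
    rng = np.random.default_rng(seed)
    ids = [f"pair_{i}" for i in range(n_pairs)]
    src_up = rng.random(n_pairs) < p_source
    p_tgt = np.where(src_up, p_coupled, p_base)
    tgt_up = rng.random(n_pairs) < p_tgt
    src = {i: ("up" if s else "ns") for i, s in zip(ids, src_up)}
    tgt = {i: ("up" if t else "ns") for i, t in zip(ids, tgt_up)}
    return src, tgt, ids


def simulate_tf_sites(
    n_tf_sites: int = 200,
    pool_size: int = 5000,
    effect: float = 1.0,
    pool_sd: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site log2 fold changes: a planted-effect TF, a null TF, a pool.

    The pool is centred at 0 with SD ``pool_sd``; the planted TF's sites
    carry an extra ``effect`` log2 units; the null TF's sites are drawn
    from the same distribution as the pool.
    """
    rng = np.random.default_rng(seed)
    pool = rng.normal(0.0, pool_sd, pool_size)
    tf_planted = rng.normal(effect, pool_sd, n_tf_sites)
    tf_null = rng.normal(0.0, pool_sd, n_tf_sites)
    return tf_planted, tf_null, pool


def simulate_rate_expression(
    n: int = 57, rho: float = 0.7, seed: int = 0
) -> tuple[dict[str, float], dict[str, float]]:
    """Bivariate-normal association-rate / expression-change cloud.

    Returns ``(log2_rate_by_protein, expression_log2fc_by_protein)`` with
    population correlation ``rho``.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
    ids = [f"prot_{i:03d}" for i in range(n)]
    return dict(zip(ids, y)), dict(zip(ids, x))


def random_pwm(rng: np.random.Generator, tf_name: str, length: int = 8) -> PWM:
    """A random informative motif (Dirichlet columns biased to one base)."""
    alpha = np.full(4, 0.3)
    cols = []
    for _ in range(length):
        a = alpha.copy()
        a[rng.integers(0, 4)] = 8.0
        cols.append(rng.dirichlet(a))
    return PWM(tf_name, np.array(cols).T)


# ---------------------------------------------------------------------------
# ChIP layer


CHIP_TRACKS = ("factor", "atac", "H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3")

# regulatory archetypes: mean signal per track
CHIP_ARCHETYPES: dict[str, dict[str, float]] = {
    "active_promoter": {
        "factor": 5, "atac": 6, "H3K4me3": 6, "H3K4me1": 1, "H3K27ac": 4, "H3K27me3": 0.5,
    },
    "active_enhancer": {
        "factor": 4, "atac": 5, "H3K4me3": 1, "H3K4me1": 5, "H3K27ac": 5, "H3K27me3": 0.5,
    },
    "poised": {
        "factor": 3, "atac": 2, "H3K4me3": 3, "H3K4me1": 2, "H3K27ac": 0.5, "H3K27me3": 5,
    },
    "quiescent": {
        "factor": 2, "atac": 1, "H3K4me3": 0.5, "H3K4me1": 0.5, "H3K27ac": 0.5, "H3K27me3": 1,
    },
}


@dataclass
class ChipData:
    factor_peaks: list[Peak]  # the factor under study (the ChIP bait)
    partner_peaks: list[Peak]  # a co-binding partner factor
    replicate_sets: list[list[Peak]]
    tracks: list[SignalTrack]
    group_truth: pd.Series  # peak_id -> archetype name
    cobound_truth: pd.Series  # peak_id -> bool
    gene_expression: pd.Series  # gene_id -> log2 expression value


def generate_chip(
    config: SimConfig,
    genome: GenomeBundle,
    archetypes: dict[str, dict[str, float]] | None = None,
) -> ChipData:
    """ChIP peak sets with archetype mark signal and a co-bound effect.

    Factor peaks are anchored near distinct gene TSSs (so nearest-gene
    expression analyses see one gene per peak) and never overlap; each
    gets an archetype whose track means (log-normal noise, SD
    ``chip_group_sd``) define its bedGraph signal. A ``cobound_fraction``
    subset receives an overlapping partner peak, a mark shift on
    H3K27ac/H3K4me1, and an elevated nearest-gene expression value; only
    peaks with enough clearance from their neighbours are eligible, so
    the planted co-bound labels coincide exactly with an overlap-based
    partition. Replicate sets jitter peak edges and drop peaks at random
    so a >=2-sample consensus is non-trivial.
    """
    rng = np.random.default_rng(config.seed + 2)
    archetypes = archetypes or CHIP_ARCHETYPES
    names = sorted(archetypes)
    chroms = sorted(genome.sequences)
    width = config.peak_width
    if config.n_chip_peaks > len(genome.tss):
        raise ValueError("n_chip_peaks exceeds the number of genes to anchor at")
    anchor_idx = np.sort(
        rng.choice(len(genome.tss), size=config.n_chip_peaks, replace=False)
    )
    raw: list[tuple[str, int]] = []
    for gi in anchor_idx:
        t = genome.tss[gi]
        start = max(0, t.tss + int(rng.integers(-300, 301)) - width // 2)
        raw.append((t.chrom, start))
    raw.sort()
    peaks: list[Peak] = []
    pid = 0
    prev: dict[str, int] = {}
    for chrom, start in raw:
        start = max(start, prev.get(chrom, -1) + 1)
        if start + width > config.chrom_length:
            continue
        peaks.append(
            Peak(GenomicInterval(chrom, start, start + width), f"fpeak_{pid:04d}")
        )
        prev[chrom] = start + width
        pid += 1
    group = pd.Series(
        [names[i] for i in rng.integers(0, len(names), len(peaks))],
        index=[p.peak_id for p in peaks],
        name="group",
    )
    # co-bound eligibility: partner jitter reaches width//2 beyond the factor
    # peak, so require that much clearance from the flanking factor peaks
    clearance = width // 2 + 1
    eligible = []
    for i, p in enumerate(peaks):
        left_ok = i == 0 or peaks[i - 1].chrom != p.chrom or (
            p.start - peaks[i - 1].end >= clearance
        )
        right_ok = i == len(peaks) - 1 or peaks[i + 1].chrom != p.chrom or (
            peaks[i + 1].start - p.end >= clearance
        )
        eligible.append(left_ok and right_ok)
    cobound = pd.Series(
        (rng.random(len(peaks)) < config.cobound_fraction) & np.array(eligible),
        index=[p.peak_id for p in peaks],
        name="cobound",
    )

    signal: dict[str, dict[str, float]] = {t: {} for t in CHIP_TRACKS}
    for p in peaks:
        arch = archetypes[group[p.peak_id]]
        for t in CHIP_TRACKS:
            val = arch[t] * float(
                np.exp(rng.normal(0, config.chip_group_sd))
            )
            if cobound[p.peak_id] and t in ("H3K27ac", "H3K4me1"):
                val += config.cobound_mark_shift
            signal[t][p.peak_id] = val
    tracks = [
        SignalTrack.from_records(
            t,
            [(p.chrom, p.start, p.end, signal[t][p.peak_id]) for p in peaks],
        )
        for t in CHIP_TRACKS
    ]

    partner: list[Peak] = []
    k = 0
    for p in peaks:
        if cobound[p.peak_id]:
            off = int(rng.integers(-width // 2, width // 2))
            start = max(0, p.start + off)
            partner.append(
                Peak(GenomicInterval(p.chrom, start, start + width), f"ppeak_{k:04d}")
            )
            k += 1
    # a few partner-only peaks in free space between factor peaks
    n_partner_only = max(5, len(partner) // 5)
    occupied = sorted((p.chrom, p.start, p.end) for p in peaks + partner)
    tries = 0
    while n_partner_only > 0 and tries < 10_000:
        tries += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, config.chrom_length - width))
        if any(
            c == chrom and min(e, start + width) - max(s, start) > 0
            for c, s, e in occupied
        ):
            continue
        partner.append(
            Peak(GenomicInterval(chrom, start, start + width), f"ppeak_{k:04d}")
        )
        occupied.append((chrom, start, start + width))
        k += 1
        n_partner_only -= 1

    replicate_sets: list[list[Peak]] = []
    for r in range(config.n_chip_replicates):
        rep: list[Peak] = []
        for p in peaks:
            if rng.random() > config.replicate_presence:
                continue
            j1 = int(rng.integers(-config.replicate_jitter, config.replicate_jitter + 1))
            j2 = int(rng.integers(-config.replicate_jitter, config.replicate_jitter + 1))
            start = max(0, p.start + j1)
            end = max(start + 1, p.end + j2)
            rep.append(Peak(GenomicInterval(p.chrom, start, end), f"{p.peak_id}_r{r}"))
        replicate_sets.append(rep)

    # nearest-gene expression: baseline log2, elevated near co-bound peaks
    expr = pd.Series(
        rng.normal(config.base_log2_mean, 1.0, len(genome.tss)),
        index=[t.gene_id for t in genome.tss],
        name="log2_expression",
    )
    tss_by_chrom: dict[str, list[TSSRecord]] = {}
    for t in genome.tss:
        tss_by_chrom.setdefault(t.chrom, []).append(t)
    for p in peaks:
        if cobound[p.peak_id]:
            cands = tss_by_chrom.get(p.chrom, [])
            if cands:
                nearest = min(
                    cands,
                    key=lambda t: (p.interval.distance_to_point(t.tss), t.gene_id),
                )
                expr[nearest.gene_id] += config.cobound_expression_shift
    return ChipData(peaks, partner, replicate_sets, tracks, group, cobound, expr)


# ---------------------------------------------------------------------------
# pull-down layer


def generate_pulldown(
    config: SimConfig, igg_noise: float = 0.0, intensity_noise: float = 0.1
) -> tuple[PulldownTable, pd.DataFrame]:
    """iBAQ-like pull-down table with planted interactor statuses.

    The bait sits above the interactor intensity distribution; exclusive
    interactors have IgG identically 0, enriched interactors have per-
    replicate folds >= ``min_fold``, background proteins have folds below
    it. ``igg_noise`` is the probability that one IgG replicate of an
    exclusive protein picks up a contaminating signal (used to stress
    precision). Returns ``(table, truth)`` with truth columns
    ``status_escs``/``status_neurons`` and the planted ``log2_rate``.
    """
    rng = np.random.default_rng(config.seed + 3)
    statuses = (
        ["exclusive"] * config.n_exclusive
        + ["enriched"] * config.n_enriched
        + ["background"] * config.n_background
    )
    n = len(statuses)
    ids = [f"prot_{i:03d}" for i in range(n)]
    cell_types = ("escs", "neurons")
    reps = ("1", "2")
    base = rng.lognormal(np.log(1e6), 1.0, n)
    log2_rate = rng.normal(0, 1, n)
    bait_int = {ct: 1e9 * float(rng.lognormal(0, 0.1)) for ct in cell_types}
    cols: dict[str, np.ndarray] = {}
    meta: dict[str, RunMeta] = {}
    rep_noise = {
        (ct, r): rng.lognormal(0, intensity_noise, n) for ct in cell_types for r in reps
    }
    for ct in cell_types:
        ct_scale = (np.ones(n) if ct == "escs" else 2.0 ** log2_rate) * (
            bait_int[ct] / 1e9
        )
        for r in reps:
            tname = f"{ct}_target_r{r}"
            target = base * ct_scale * rep_noise[(ct, r)]
            igg = np.zeros(n)
            for i, st in enumerate(statuses):
                if st == "enriched":
                    fold = rng.uniform(config.min_fold * 1.25, config.min_fold * 4)
                    igg[i] = target[i] / fold
                elif st == "background":
                    fold = rng.uniform(0.5, config.min_fold * 0.75)
                    igg[i] = target[i] / fold
                elif st == "exclusive" and igg_noise > 0 and rng.random() < igg_noise:
                    igg[i] = target[i] / rng.uniform(1, config.min_fold)
            cols[tname] = target
            meta[tname] = RunMeta("target", r, ct)
            gname = f"{ct}_igg_r{r}"
            cols[gname] = igg
            meta[gname] = RunMeta("igg", r, ct)
    intensities = pd.DataFrame(cols, index=ids)
    bait_row = {}
    for ct in cell_types:
        for r in reps:
            bait_row[f"{ct}_target_r{r}"] = bait_int[ct] * float(
                rng.lognormal(0, intensity_noise / 2) if intensity_noise > 0 else 1.0
            )
            bait_row[f"{ct}_igg_r{r}"] = 0.0
    intensities.loc[config.bait_id] = pd.Series(bait_row)
    table = PulldownTable(intensities, meta)
    truth = pd.DataFrame(
        {
            "status": statuses,
            "log2_rate": log2_rate,
        },
        index=ids,
    )
    return table, truth
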