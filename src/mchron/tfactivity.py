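"""Differential TF activity from chromatin accessibility at binding sites.

A TF's activity change between two conditions is the mean log2 accessibility
fold change over its motif sites that fall inside ATAC peaks (sites extended
50 bp each side before overlap). Significance is a Cohen's D between the
bootstrap distribution of that mean and the distribution of means of
same-size random site draws from the pooled in-peak site set (the permuted-
site null); |D| > 1 is called significant. TFs are then grouped jointly on
activity and expression trajectories, and groups where the two
anticorrelate are flagged as candidate repressors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import Contrast
from .intervals import GenomicInterval, Peak
from .stats import cohens_d, kmeans_cluster, pearson_r

__all__ = [
    "PWM",
    "BindingSite",
    "TFActivityResult",
    "read_jaspar",
    "scan_pwm",
    "select_sites_in_peaks",
    "site_log2fc",
    "tf_activity",
    "permutation_significance",
    "cluster_tf_groups",
]

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class PWM:
    """Position probability matrix for one TF motif (rows A, C, G, T)."""

    tf_name: str
    probs: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape[0] != 4 or p.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.allclose(p.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def log_odds(self) -> np.ndarray:
        """log2 odds vs a uniform 0.25 background, with pseudocount."""
        p = (self.probs + self.pseudocount) / (1 + 4 * self.pseudocount)
        return np.log2(p / 0.25)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.tf_name, self.probs[::-1, ::-1], self.pseudocount)


@dataclass(frozen=True)
class BindingSite:
    interval: GenomicInterval
    tf_name: str
    match_score: float
    peak_id: str | None = None


@dataclass(frozen=True)
class TFActivityResult:
    tf_name: str
    contrast: Contrast
    n_sites: int
    mean_diff: float
    cohens_d: float
    significant: bool


def read_jaspar(path: str | Path) -> list[PWM]:
    """Read JASPAR-style PFM text (``>MA0001.1 NAME`` then A/C/G/T rows).

    Count matrices are normalised per column to probabilities.
    """
    pwms: list[PWM] = []
    name: str | None = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    lines.append(">")  # sentinel to flush the last record

    def _flush() -> None:
        if name is None:
            return
        mat = np.array([rows[b] for b in _BASES], dtype=float)
        col_sums = mat.sum(axis=0)
        if np.any(col_sums <= 0):
            raise ValueError(f"PWM {name}: empty column")
        pwms.append(PWM(name, mat / col_sums))

    for ln in lines:
        if ln.startswith(">"):
            _flush()
            fields = ln[1:].split()
            name = fields[-1] if fields else None
            rows = {}
        else:
            base = ln[0].upper()
            nums = ln[1:].replace("[", " ").replace("]", " ").split()
            rows[base] = [float(x) for x in nums]
    return pwms


def write_jaspar(pwms: Sequence[PWM], path: str | Path, scale: int = 100) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_name} {pwm.tf_name}\n")
            counts = np.round(pwm.probs * scale).astype(int)
            for i, base in enumerate(_BASES):
                fh.write(f"{base} [ " + " ".join(map(str, counts[i])) + " ]\n")


def _encode(seq: str) -> np.ndarray:
    idx = np.full(len(seq), -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return idx


def scan_pwm(
    genome: Mapping[str, str],
    pwm: PWM,
    min_score_frac: float = 0.8,
) -> list[BindingSite]:
    """Scan both strands for motif hits above a fraction of the max score.

    A window is a hit when its log-odds score (vs uniform background) is
    >= ``min_score_frac`` x the maximum attainable score. Windows
    containing non-ACGT bases are skipped. Hits are reported in forward
    coordinates regardless of strand.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    if not (0 < min_score_frac <= 1):
        raise ValueError("min_score_frac must be in (0, 1]")
    L = pwm.length
    threshold = min_score_frac * pwm.max_score()
    lo_fwd = pwm.log_odds()
    lo_rev = pwm.reverse_complement().log_odds()
    sites: list[BindingSite] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        if len(seq) < L:
            continue
        idx = _encode(seq)
        n_win = len(seq) - L + 1
        # sliding-window score via an offset sum over the encoded sequence
        valid = np.ones(n_win, dtype=bool)
        score_f = np.zeros(n_win)
        score_r = np.zeros(n_win)
        for j in range(L):
            col = idx[j : j + n_win]
            ok = col >= 0
            valid &= ok
            safe = np.where(ok, col, 0)
            score_f += lo_fwd[safe, j]
            score_r += lo_rev[safe, j]
        for pos in np.nonzero(valid & ((score_f >= threshold) | (score_r >= threshold)))[0]:
            best = max(score_f[pos], score_r[pos])
            strand = "+" if score_f[pos] >= score_r[pos] else "-"
            sites.append(
                BindingSite(
                    GenomicInterval(chrom, int(pos), int(pos) + L, strand),
                    pwm.tf_name,
                    float(best),
                )
            )
    return sites


def select_sites_in_peaks(
    sites: Sequence[BindingSite],
    atac_peaks: Sequence[Peak],
    flank: int = 50,
) -> list[BindingSite]:
    """Extend sites by ``flank`` bp each side; keep those overlapping a peak.

    Each kept site is annotated with the overlapping peak's id; ties go
    to the larger overlap, then the lexicographically smaller peak_id.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    peaks_by_chrom: dict[str, list[Peak]] = {}
    for p in atac_peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    for ps in peaks_by_chrom.values():
        ps.sort(key=lambda p: p.start)
    out: list[BindingSite] = []
    for site in sites:
        iv = site.interval
        ext = GenomicInterval(
            iv.chrom, max(0, iv.start - flank), iv.end + flank, iv.strand
        )
        best: tuple[int, str] | None = None
        for p in peaks_by_chrom.get(ext.chrom, ()):
            if p.start >= ext.end:
                break
            ov = ext.overlap_bp(p.interval)
            if ov >= 1 and (best is None or (-ov, p.peak_id) < best):
                best = (-ov, p.peak_id)
        if best is not None:
            out.append(replace(site, interval=ext, peak_id=best[1]))
    return out


def site_log2fc(
    site_counts: pd.DataFrame,
    design: Mapping[str, tuple[int, int]],
    contrast: Contrast,
) -> pd.Series:
    """Per-site log2 accessibility change, late over early condition.

    Counts are CPM-normalised per sample, shifted by +1, and the log2
    ratio of condition means taken.
    """
    lib = site_counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    cpm = site_counts / lib * 1e6
    late = [s for s in cpm.columns if design[s][0] == contrast.day_late]
    early = [s for s in cpm.columns if design[s][0] == contrast.day_early]
    if not late or not early:
        raise ValueError(f"contrast {contrast}: missing condition samples")
    return np.log2(cpm[late].mean(axis=1) + 1) - np.log2(cpm[early].mean(axis=1) + 1)


def tf_activity(
    site_fcs: Sequence[float] | np.ndarray, min_sites: int = 50
) -> float | None:
    """Mean per-site log2 fold change; ``None`` (with warning) below min_sites."""
    fcs = np.asarray(site_fcs, dtype=float)
    if fcs.size < min_sites:
        warnings.warn(f"only {fcs.size} sites (< {min_sites}); TF skipped")
        return None
    return float(fcs.mean())


def permutation_significance(
    tf_site_fcs: np.ndarray,
    pool_fcs: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    d_threshold: float = 1.0,
) -> tuple[float, bool]:
    """Cohen's D of the TF's fold changes against a permuted-site null.

    The null is built from ``n_perm`` permuted binding-site sets: random
    same-size draws from ``pool_fcs`` (the other TFs' in-peak sites; the
    TF's own sites are excluded by the caller). Cohen's D is computed
    between the TF's per-site fold-change distribution and the pooled
    per-site distribution of the permuted sets, so D measures the TF's
    accessibility shift in units of the per-site spread — a planted
    shift of one pooled SD gives D near 1 regardless of site count,
    while a TF whose sites are a random pool subset stays near 0.
    Draws are without replacement within each permuted set when the pool
    allows, otherwise with replacement (warned).
    """
    rng = np.random.default_rng(seed)
    tf_site_fcs = np.asarray(tf_site_fcs, dtype=float)
    pool_fcs = np.asarray(pool_fcs, dtype=float)
    n = tf_site_fcs.size
    if n == 0:
        raise ValueError("TF has no sites")
    if pool_fcs.size >= n:
        null_sets = np.stack(
            [
                pool_fcs[rng.choice(pool_fcs.size, size=n, replace=False)]
                for _ in range(n_perm)
            ]
        )
    else:
        warnings.warn("site pool smaller than TF site count; sampling with replacement")
        null_sets = pool_fcs[rng.integers(0, pool_fcs.size, size=(n_perm, n))]
    d = cohens_d(tf_site_fcs, null_sets.ravel())
    return d, bool(abs(d) > d_threshold)


def cluster_tf_groups(
    activity: pd.DataFrame,
    expression: pd.DataFrame,
    k: int = 8,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Group TFs by joint k-means on activity and expression trajectories.

    Returns (tf -> group, group summary with mean signatures and an
    ``anticorrelated`` flag marking candidate repressors, i.e. groups
    whose mean activity and mean expression trajectories have negative
    Pearson correlation).
    """
    shared = activity.index.intersection(expression.index)
    joined = pd.concat(
        [
            activity.loc[shared].add_prefix("act_"),
            expression.loc[shared].add_prefix("expr_"),
        ],
        axis=1,
    )
    if k > len(joined):
        raise ValueError(f"k={k} exceeds {len(joined)} TFs")
    labels, _ = kmeans_cluster(joined.to_numpy(), k=k, seed=seed)
    groups = pd.Series(labels, index=joined.index, name="group")
    n_act = activity.shape[1]
    rows = []
    for g in range(k):
        members = joined[groups == g]
        mean_vec = members.mean(axis=0).to_numpy()
        act_vec, expr_vec = mean_vec[:n_act], mean_vec[n_act:]
        try:
            with np.errstate(invalid="ignore"):
                r = (
                    pearson_r(act_vec, expr_vec)
                    if len(act_vec) >= 3
                    else float(np.corrcoef(act_vec, expr_vec)[0, 1])
                )
        except ValueError:
            r = math.nan
        rows.append(
            {
                "group": g,
                "n_tfs": len(members),
                "activity_expression_r": r,
                "anticorrelated": bool(r < 0) if not math.isnan(r) else False,
            }
        )
    return groups, pd.DataFrame(rows).set_index("group")
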