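"""ChIP peak co-occupancy, regulatory grouping, and co-bound comparisons.

Covers the peak-centric analyses around a factor of interest: mean histone
mark signal over peaks (bedGraph semantics, uncovered bases count as 0),
k-means regulatory groups on z-scored signal, co-occupancy fractions
against other factors' merged peak sets (>= 1 bp overlap), the three-way
partition of two factors' binding (co-bound / A-only / B-only), and
group-wise comparisons of signal or nearest-gene expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, TSSRecord, overlap_flags
from .stats import kmeans_cluster, two_group_test

__all__ = [
    "SignalTrack",
    "CooccupancyResult",
    "read_bedgraph",
    "write_bedgraph",
    "mean_signal_matrix",
    "regulatory_groups",
    "cooccupancy_fractions",
    "partition_cobound",
    "compare_groups",
    "nearest_gene_values",
]


@dataclass
class SignalTrack:
    """Piecewise-constant coverage: non-overlapping intervals with values."""

    name: str
    intervals: dict[str, np.ndarray]  # chrom -> (n, 2) int array of [start, end)
    values: dict[str, np.ndarray]  # chrom -> (n,) float array

    @classmethod
    def from_records(
        cls, name: str, records: Sequence[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        intervals, values = {}, {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            arr = np.array(rows, dtype=float)
            starts, ends = arr[:, 0].astype(int), arr[:, 1].astype(int)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"track {name}: overlapping intervals on {chrom}")
            if not np.all(np.isfinite(arr[:, 2])):
                raise ValueError(f"track {name}: non-finite value on {chrom}")
            intervals[chrom] = np.column_stack([starts, ends])
            values[chrom] = arr[:, 2]
        return cls(name, intervals, values)

    def mean_over(self, iv: GenomicInterval) -> float:
        """Length-weighted mean over ``iv``; uncovered bases contribute 0."""
        segs = self.intervals.get(iv.chrom)
        if segs is None:
            return 0.0
        vals = self.values[iv.chrom]
        ov = np.minimum(segs[:, 1], iv.end) - np.maximum(segs[:, 0], iv.start)
        ov = np.clip(ov, 0, None)
        return float((ov * vals).sum() / iv.width)


def read_bedgraph(path: str | Path, name: str | None = None) -> SignalTrack:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            try:
                chrom, start, end, value = line.split("\t")
                records.append((chrom, int(start), int(end), float(value)))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line") from exc
    return SignalTrack.from_records(name or Path(path).stem, records)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            for (start, end), value in zip(track.intervals[chrom], track.values[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


@dataclass(frozen=True)
class CooccupancyResult:
    factor: str
    n_target: int
    n_overlapping: int

    @property
    def fraction(self) -> float:
        return self.n_overlapping / self.n_target


def mean_signal_matrix(
    peaks: Sequence[Peak], tracks: Sequence[SignalTrack]
) -> pd.DataFrame:
    """peaks x tracks matrix of length-weighted mean signal."""
    data = {
        t.name: [t.mean_over(p.interval) for p in peaks] for t in tracks
    }
    return pd.DataFrame(data, index=[p.peak_id for p in peaks])


def regulatory_groups(
    signal_matrix: pd.DataFrame, k: int, seed: int = 0
) -> tuple[pd.Series, pd.DataFrame]:
    """k-means regulatory grouping on per-track z-scored signal.

    Returns (peak -> group, group x track mean z-score signatures).
    Tracks with zero variance are dropped from the z-scoring (constant
    columns carry no grouping information).
    """
    if k > len(signal_matrix):
        raise ValueError(f"k={k} exceeds {len(signal_matrix)} peaks")
    sd = signal_matrix.std(axis=0, ddof=0)
    keep = sd[sd > 0].index
    z = (signal_matrix[keep] - signal_matrix[keep].mean(axis=0)) / sd[keep]
    labels, _ = kmeans_cluster(z.to_numpy(), k=k, seed=seed)
    groups = pd.Series(labels, index=signal_matrix.index, name="group")
    signatures = z.groupby(groups).mean()
    signatures.index.name = "group"
    return groups, signatures


def cooccupancy_fractions(
    target_peaks: Sequence[Peak],
    factor_sets: Mapping[str, Sequence[Peak | GenomicInterval]],
    min_overlap: int = 1,
) -> list[CooccupancyResult]:
    """Per factor, the fraction of target peaks with >= 1 bp overlap."""
    if not target_peaks:
        raise ValueError("empty target peak set")
    out = []
    for factor in sorted(factor_sets):
        flags, _ = overlap_flags(target_peaks, factor_sets[factor], min_overlap)
        out.append(
            CooccupancyResult(factor, len(target_peaks), sum(flags.values()))
        )
    return out


def partition_cobound(
    peaks_A: Sequence[Peak], peaks_B: Sequence[Peak]
) -> dict[str, list[Peak]]:
    """Three-way partition of two factors' peaks by >= 1 bp overlap.

    ``co_bound`` holds A's peaks that overlap B (reported at A's
    coordinates, the factor under study); ``A_only`` / ``B_only`` the
    rest of each side. The three groups are disjoint and cover every
    input peak: a B peak overlapping A is represented by its A partner.
    """
    if not peaks_A and not peaks_B:
        return {"co_bound": [], "A_only": [], "B_only": []}
    flags_A = (
        overlap_flags(peaks_A, peaks_B)[0] if peaks_A and peaks_B
        else {p.peak_id: False for p in peaks_A}
    )
    flags_B = (
        overlap_flags(peaks_B, peaks_A)[0] if peaks_A and peaks_B
        else {p.peak_id: False for p in peaks_B}
    )
    return {
        "co_bound": [p for p in peaks_A if flags_A[p.peak_id]],
        "A_only": [p for p in peaks_A if not flags_A[p.peak_id]],
        "B_only": [p for p in peaks_B if not flags_B[p.peak_id]],
    }


def nearest_gene_values(
    peaks: Sequence[Peak],
    tss: Sequence[TSSRecord],
    gene_values: Mapping[str, float],
) -> dict[str, float]:
    """Attach a per-gene value (e.g. expression) to peaks by nearest TSS."""
    tss_by_chrom: dict[str, list[TSSRecord]] = {}
    for t in tss:
        tss_by_chrom.setdefault(t.chrom, []).append(t)
    out: dict[str, float] = {}
    for p in peaks:
        cands = tss_by_chrom.get(p.chrom)
        if not cands:
            continue
        best = min(
            cands, key=lambda t: (p.interval.distance_to_point(t.tss), t.gene_id)
        )
        if best.gene_id in gene_values:
            out[p.peak_id] = gene_values[best.gene_id]
    return out


def compare_groups(
    values: Mapping[str, float],
    groups: Mapping[str, Sequence[Peak]],
    test: str = "student_t",
) -> pd.DataFrame:
    """Pairwise two-sided p values between peak groups.

    ``values`` maps peak_id to a signal or nearest-gene expression value;
    peaks without a value are ignored. Groups with fewer than two valued
    peaks are skipped with a warning.
    """
    group_values: dict[str, np.ndarray] = {}
    for name, peaks in groups.items():
        v = np.array([values[p.peak_id] for p in peaks if p.peak_id in values])
        if v.size < 2:
            warnings.warn(f"group {name!r} has <2 values; skipped")
            continue
        group_values[name] = v
    names = sorted(group_values)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for i, gi in enumerate(names):
        mat.loc[gi, gi] = 1.0
        for gj in names[i + 1 :]:
            p = two_group_test(group_values[gi], group_values[gj], kind=test)
            mat.loc[gi, gj] = p
            mat.loc[gj, gi] = p
    return mat
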