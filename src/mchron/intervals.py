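"""Genomic interval model, BED/narrowPeak/TSV I/O, and peak geometry.

Coordinates are 0-based half-open throughout, matching BED. Distances to an
interval are measured to the nearest *included* base (``end - 1``), never to
the exclusive end, so a TSS sitting exactly at ``end`` is 1 bp away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "TSSRecord",
    "GeneLink",
    "GeneModel",
    "read_intervals",
    "write_bed6",
    "write_narrowpeak",
    "extend_around_midpoint",
    "merge_consensus",
    "overlap_flags",
    "assign_peaks_to_genes",
    "annotate_peak_category",
]

Strand = Literal["+", "-", "."]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to_point(self, pos: int) -> int:
        """bp from ``pos`` to the nearest included base; 0 if inside."""
        if self.start <= pos < self.end:
            return 0
        return min(abs(pos - self.start), abs(pos - (self.end - 1)))


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus identifier, optional summit and score."""

    interval: GenomicInterval
    peak_id: str
    summit: int | None = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside [{self.interval.start}, "
                f"{self.interval.end}) for peak {self.peak_id}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def width(self) -> int:
        return self.interval.width

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site, one per gene."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")


@dataclass(frozen=True)
class GeneLink:
    """Assignment of one peak to its nearest gene."""

    peak_id: str
    gene_id: str
    link_type: Literal["promoter", "distal"]
    distance: int


@dataclass
class GeneModel:
    """Minimal gene model: gene spans, exon spans, and TSS records.

    For a minus-strand gene derived from a span, the TSS is ``end - 1``
    (the last included base), keeping half-open consistency.
    """

    tss: list[TSSRecord] = field(default_factory=list)
    gene_spans: dict[str, GenomicInterval] = field(default_factory=dict)
    exons: dict[str, list[GenomicInterval]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# I/O


def _parse_bed6_line(parts: list[str], lineno: int, default_id: str) -> Peak:
    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
    name = parts[3] if len(parts) > 3 and parts[3] != "." else default_id
    score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
    strand = parts[5] if len(parts) > 5 else "."
    return Peak(GenomicInterval(chrom, start, end, strand), name, score=score)


def read_intervals(
    path: str | Path, format: Literal["bed6", "narrowPeak", "tss_tsv"]
):
    """Read a peak set (BED6/narrowPeak) or a TSS table.

    Returns a list of :class:`Peak` for the BED dialects, a list of
    :class:`TSSRecord` for ``tss_tsv``. narrowPeak summits are converted
    from the column-10 relative offset to absolute coordinates; an offset
    of -1 means "no summit".
    """
    path = Path(path)
    out: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if format == "tss_tsv":
                    if lineno == 1 and parts[0] == "gene_id":
                        continue
                    gene_id, chrom, tss, strand = parts[:4]
                    out.append(TSSRecord(gene_id, chrom, int(tss), strand))
                elif format == "bed6":
                    out.append(_parse_bed6_line(parts, lineno, f"peak_{lineno}"))
                elif format == "narrowPeak":
                    if len(parts) < 10:
                        raise ValueError("narrowPeak needs 10 columns")
                    peak = _parse_bed6_line(parts, lineno, f"peak_{lineno}")
                    offset = int(parts[9])
                    summit = peak.start + offset if offset >= 0 else None
                    score = float(parts[6])  # signalValue
                    out.append(replace(peak, summit=summit, score=score))
                else:
                    raise ValueError(f"unknown format {format!r}")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from exc
    if format in ("bed6", "narrowPeak"):
        ids = [p.peak_id for p in out]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{path}: duplicate peak_id")
    return out


def write_bed6(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t"
                f"{p.score:g}\t{p.interval.strand}\n"
            )


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            offset = p.summit - p.start if p.summit is not None else -1
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t"
                f"{p.interval.strand}\t{p.score:g}\t-1\t-1\t{offset}\n"
            )


# ---------------------------------------------------------------------------
# Peak geometry


def extend_around_midpoint(peaks: Sequence[Peak], flank: int = 250) -> list[Peak]:
    """Re-centre each peak on its midpoint and extend ``flank`` bp both ways.

    Output width is exactly ``2 * flank`` except where the left edge is
    clipped at position 0 near a chromosome start.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = []
    for p in peaks:
        mid = p.interval.midpoint
        start = max(0, mid - flank)
        end = mid + flank
        out.append(
            Peak(
                GenomicInterval(p.chrom, start, end, p.interval.strand),
                p.peak_id,
                summit=p.summit if p.summit is not None and start <= p.summit < end else None,
                score=p.score,
            )
        )
    return out


def merge_consensus(
    peak_sets: Sequence[Sequence[Peak | GenomicInterval]], min_sets: int = 2
) -> list[GenomicInterval]:
    """Consensus regions covered by at least ``min_sets`` distinct input sets.

    Returns maximal intervals where the number of distinct sets with
    coverage is >= ``min_sets``, computed by a sweep over per-set-merged
    breakpoints (a sample contributes at most 1 to the depth at any base).
    """
    if min_sets > len(peak_sets):
        raise ValueError(f"min_sets={min_sets} exceeds {len(peak_sets)} sets")
    if min_sets < 1:
        raise ValueError("min_sets must be >= 1")
    events: dict[str, list[tuple[int, int]]] = {}
    for pset in peak_sets:
        # merge within a set first so depth counts distinct sets
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in pset:
            iv = p.interval if isinstance(p, Peak) else p
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            ev = events.setdefault(chrom, [])
            for s, e in merged:
                ev.append((s, +1))
                ev.append((e, -1))
    out: list[GenomicInterval] = []
    for chrom in sorted(events):
        # starts before ends at equal positions, so abutting coverage from
        # different sets forms one maximal run
        ev = sorted(events[chrom], key=lambda t: (t[0], -t[1]))
        depth = 0
        run_start: int | None = None
        for pos, delta in ev:
            new_depth = depth + delta
            if depth < min_sets <= new_depth and run_start is None:
                run_start = pos
            elif run_start is not None and new_depth < min_sets <= depth:
                if pos > run_start:
                    out.append(GenomicInterval(chrom, run_start, pos))
                run_start = None
            depth = new_depth
        assert run_start is None
    return out


def overlap_flags(
    A: Sequence[Peak],
    B: Sequence[Peak | GenomicInterval],
    min_overlap: int = 1,
) -> tuple[dict[str, bool], float]:
    """Per-peak flag: does the peak share >= ``min_overlap`` bp with B?

    Returns ``(flags_by_peak_id, fraction_flagged)``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(A) == 0:
        raise ValueError("empty peak set A: overlap fraction undefined")
    b_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in B:
        iv = b.interval if isinstance(b, Peak) else b
        b_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for ivs in b_by_chrom.values():
        ivs.sort()
    flags: dict[str, bool] = {}
    for p in A:
        hit = False
        for s, e in b_by_chrom.get(p.chrom, ()):
            if s >= p.end:
                break
            if min(e, p.end) - max(s, p.start) >= min_overlap:
                hit = True
                break
        flags[p.peak_id] = hit
    frac = sum(flags.values()) / len(A)
    return flags, frac


def _peak_tss_distance(peak: Peak, tss: int) -> int:
    return peak.interval.distance_to_point(tss)


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    tss: Sequence[TSSRecord],
    promoter_window: int = 1500,
) -> tuple[list[GeneLink], dict[str, str]]:
    """Assign each peak to its nearest TSS; pick one promoter peak per gene.

    A peak is a *promoter* peak when the distance to its nearest TSS is
    at most ``promoter_window`` bp (default 1.5 kb), else *distal*. Ties
    between equidistant TSS break to the lexicographically smaller
    gene_id. Per gene, the promoter peak is the single closest peak
    within the window (ties again by id); the second return value maps
    gene_id -> peak_id for genes that have one.

    Peaks on chromosomes absent from the TSS table get no link (warning).
    """
    if not tss:
        raise ValueError("empty TSS table")
    tss_by_chrom: dict[str, list[TSSRecord]] = {}
    for t in tss:
        tss_by_chrom.setdefault(t.chrom, []).append(t)
    links: list[GeneLink] = []
    for p in peaks:
        cands = tss_by_chrom.get(p.chrom)
        if not cands:
            warnings.warn(
                f"peak {p.peak_id} on {p.chrom}: no TSS on chromosome, link skipped"
            )
            continue
        best = min(
            cands, key=lambda t: (_peak_tss_distance(p, t.tss), t.gene_id)
        )
        d = _peak_tss_distance(p, best.tss)
        links.append(
            GeneLink(
                p.peak_id,
                best.gene_id,
                "promoter" if d <= promoter_window else "distal",
                d,
            )
        )
    promoter_peak: dict[str, str] = {}
    best_d: dict[str, tuple[int, str]] = {}
    for lk in links:
        if lk.link_type != "promoter":
            continue
        key = (lk.distance, lk.peak_id)
        if lk.gene_id not in best_d or key < best_d[lk.gene_id]:
            best_d[lk.gene_id] = key
            promoter_peak[lk.gene_id] = lk.peak_id
    return links, promoter_peak


def annotate_peak_category(
    peaks: Sequence[Peak],
    gene_model: GeneModel,
    promoter_window: int = 1000,
) -> dict[str, str]:
    """Classify peaks as promoter / exon / intron / distal_intergenic.

    Precedence promoter > exon > intron > distal_intergenic. Promoter =
    within +/- ``promoter_window`` bp of any TSS (default 1 kb); intron =
    overlapping a gene span but no exon.
    """
    exon_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for exons in gene_model.exons.values():
        for iv in exons:
            exon_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    gene_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in gene_model.gene_spans.values():
        gene_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    tss_by_chrom: dict[str, list[int]] = {}
    for t in gene_model.tss:
        tss_by_chrom.setdefault(t.chrom, []).append(t.tss)

    def _hits(ivs: list[tuple[int, int]], p: Peak) -> bool:
        return any(min(e, p.end) - max(s, p.start) >= 1 for s, e in ivs)

    out: dict[str, str] = {}
    for p in peaks:
        near_tss = any(
            p.interval.distance_to_point(t) <= promoter_window
            for t in tss_by_chrom.get(p.chrom, ())
        )
        if near_tss:
            out[p.peak_id] = "promoter"
        elif _hits(exon_by_chrom.get(p.chrom, []), p):
            out[p.peak_id] = "exon"
        elif _hits(gene_by_chrom.get(p.chrom, []), p):
            out[p.peak_id] = "intron"
        else:
            out[p.peak_id] = "distal_intergenic"
    return out
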