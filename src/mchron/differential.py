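"""Per-contrast differential records and fold-change matrices.

The pipeline's value lies downstream of differential testing, so the
internal test is deliberately simple: a Welch t test on log2 CPM (counts)
or log2 intensities, BH-adjusted within each contrast. Differential tables
computed externally (e.g. by a negative-binomial model) are first-class
inputs via :func:`load_differential`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, kmeans_cluster

__all__ = [
    "Contrast",
    "DifferentialRecord",
    "simple_differential",
    "load_differential",
    "fold_change_to_baseline",
    "cluster_expression_profiles",
    "records_to_frame",
]

Layer = Literal["atac", "rna", "protein"]


@dataclass(frozen=True, order=True)
class Contrast:
    """A late-vs-early comparison within one molecular layer."""

    layer: str
    day_late: int
    day_early: int

    def __post_init__(self) -> None:
        if self.day_late <= self.day_early:
            raise ValueError("day_late must exceed day_early")

    def __str__(self) -> str:
        return f"{self.layer}:{self.day_late}v{self.day_early}"


@dataclass(frozen=True)
class DifferentialRecord:
    feature_id: str
    contrast: Contrast
    log2fc: float
    p: float
    adj_p: float
    direction: Literal["up", "down", "ns"]


def _direction(log2fc: float, adj_p: float, alpha: float) -> str:
    # strict inequality at the alpha boundary, and a zero effect is never called
    if adj_p < alpha and log2fc > 0:
        return "up"
    if adj_p < alpha and log2fc < 0:
        return "down"
    return "ns"


def _log2_values(
    matrix: pd.DataFrame, scale: str
) -> pd.DataFrame:
    if scale == "log_counts":
        lib = matrix.sum(axis=0)
        if (lib == 0).any():
            raise ValueError("zero library size")
        cpm = matrix / lib * 1e6
        return np.log2(cpm + 1)
    if scale == "log_intensity":
        return np.log2(matrix.where(matrix > 0, np.nan)).fillna(0.0)
    raise ValueError(f"unknown scale {scale!r}")


def simple_differential(
    matrix: pd.DataFrame,
    design: Mapping[str, tuple[int, int]],
    contrast: Contrast,
    scale: str = "log_counts",
    alpha: float = 0.05,
    welch: bool = False,
) -> list[DifferentialRecord]:
    """Per-feature t test on log2 values for one contrast.

    ``matrix`` is features x samples; ``design`` maps sample name to
    ``(day, replicate)``. Counts are CPM-normalised and shifted by +1
    before log2. log2fc = mean(late) - mean(early). BH is applied across
    features within the contrast. The default is the pooled-variance
    Student t (well calibrated at the study's 4-replicate scale, where
    the Welch degrees-of-freedom estimate is conservative); pass
    ``welch=True`` for unequal variances.
    """
    late = [s for s in matrix.columns if design[s][0] == contrast.day_late]
    early = [s for s in matrix.columns if design[s][0] == contrast.day_early]
    if len(late) < 2 or len(early) < 2:
        raise ValueError(
            f"contrast {contrast} needs >=2 replicates per condition "
            f"(got {len(late)} late, {len(early)} early)"
        )
    log2m = _log2_values(matrix, scale)
    xl = log2m[late].to_numpy()
    xe = log2m[early].to_numpy()
    log2fc = xl.mean(axis=1) - xe.mean(axis=1)
    res = sps.ttest_ind(xl, xe, axis=1, equal_var=not welch)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    adj = bh_adjust(p)
    return [
        DifferentialRecord(
            fid, contrast, float(fc), float(pv), float(ap), _direction(fc, ap, alpha)
        )
        for fid, fc, pv, ap in zip(matrix.index, log2fc, p, adj)
    ]


def load_differential(path: str | Path, alpha: float = 0.05) -> list[DifferentialRecord]:
    """Read an externally computed differential table (TSV).

    Required columns: feature_id, layer, day_late, day_early, log2fc, p,
    adj_p. Direction is derived from adj_p/log2fc at ``alpha``.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["feature_id", "layer", "day_late", "day_early", "log2fc", "p", "adj_p"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    out = []
    for row in df.itertuples(index=False):
        contrast = Contrast(row.layer, int(row.day_late), int(row.day_early))
        out.append(
            DifferentialRecord(
                str(row.feature_id),
                contrast,
                float(row.log2fc),
                float(row.p),
                float(row.adj_p),
                _direction(float(row.log2fc), float(row.adj_p), alpha),
            )
        )
    return out


def records_to_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "layer": [r.contrast.layer for r in records],
            "day_late": [r.contrast.day_late for r in records],
            "day_early": [r.contrast.day_early for r in records],
            "log2fc": [r.log2fc for r in records],
            "p": [r.p for r in records],
            "adj_p": [r.adj_p for r in records],
            "direction": [r.direction for r in records],
        }
    )


def fold_change_to_baseline(
    matrix: pd.DataFrame,
    design: Mapping[str, tuple[int, int]],
    baseline_day: int = 0,
    scale: str = "log_counts",
) -> pd.DataFrame:
    """features x days matrix of mean log2 fold changes vs the baseline day.

    The baseline column is identically zero and is dropped. A day with a
    single replicate contributes its own mean.
    """
    days = sorted({day for day, _rep in design.values()})
    if baseline_day not in days:
        raise ValueError(f"baseline day {baseline_day} absent from design")
    log2m = _log2_values(matrix, scale)
    day_means = {
        day: log2m[[s for s in matrix.columns if design[s][0] == day]].mean(axis=1)
        for day in days
    }
    base = day_means[baseline_day]
    out = pd.DataFrame(
        {f"day{day}": day_means[day] - base for day in days if day != baseline_day}
    )
    out.index = matrix.index
    return out


def cluster_expression_profiles(
    rna_fc: pd.DataFrame,
    protein_fc: pd.DataFrame,
    k: int = 7,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """k-means on joined RNA and protein fold-change profiles.

    Genes present in both matrices (inner join) are clustered on the
    concatenated columns; returns (gene -> cluster label, cluster x
    column mean-profile matrix).
    """
    shared = rna_fc.index.intersection(protein_fc.index)
    joined = pd.concat(
        [
            rna_fc.loc[shared].add_prefix("rna_"),
            protein_fc.loc[shared].add_prefix("protein_"),
        ],
        axis=1,
    )
    if k > len(joined):
        raise ValueError(f"k={k} exceeds {len(joined)} joined genes")
    labels, centroids = kmeans_cluster(joined.to_numpy(), k=k, seed=seed)
    assignment = pd.Series(labels, index=joined.index, name="cluster")
    profiles = pd.DataFrame(centroids, columns=joined.columns)
    profiles.index.name = "cluster"
    return assignment, profiles
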