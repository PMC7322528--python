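"""Chromatin-bound interactome scoring from bait/IgG pull-down intensities.

A pull-down table holds iBAQ-like intensities (0 = not detected) for
proteins across runs; run metadata gives bait (target vs IgG control),
replicate pairing and cell type. Interactors are proteins either
exclusively detected in the bait pull-downs (IgG zero in every replicate)
or at least ``min_fold`` enriched over the paired IgG run in every
replicate. Between cell types, an interactor's bait-normalised association
rate is the ratio of its (protein/bait) intensity ratios, log2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import ContingencyTable2x2, FisherResult, fisher_2x2, pearson_r

__all__ = [
    "PulldownTable",
    "InteractorCall",
    "AssociationRateScore",
    "rank_ibaq",
    "call_interactors",
    "association_rate",
    "score_expression_correlation",
    "category_enrichment",
]


@dataclass(frozen=True)
class RunMeta:
    bait: str  # "target" or "igg"
    replicate: str
    cell_type: str


@dataclass
class PulldownTable:
    """protein x run intensity matrix plus per-run metadata."""

    intensities: pd.DataFrame
    meta: dict[str, RunMeta]

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensity")
        for ct in self.cell_types():
            for bait in ("target", "igg"):
                if len(self.runs(ct, bait)) < 2:
                    raise ValueError(f"need >=2 {bait} runs for cell type {ct!r}")

    def cell_types(self) -> list[str]:
        return sorted({m.cell_type for m in self.meta.values()})

    def runs(self, cell_type: str, bait: str) -> list[str]:
        return sorted(
            run
            for run, m in self.meta.items()
            if m.cell_type == cell_type and m.bait == bait
        )

    def replicate_pairs(self, cell_type: str) -> list[tuple[str, str]]:
        """(target_run, igg_run) pairs matched by replicate id."""
        targets = {
            self.meta[r].replicate: r for r in self.runs(cell_type, "target")
        }
        iggs = {self.meta[r].replicate: r for r in self.runs(cell_type, "igg")}
        if set(targets) != set(iggs):
            raise ValueError(
                f"unpaired replicates for {cell_type!r}: "
                f"target {sorted(targets)} vs igg {sorted(iggs)}"
            )
        return [(targets[rep], iggs[rep]) for rep in sorted(targets)]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PulldownTable":
        """Read a TSV with three metadata header rows (bait, replicate,
        cell_type) above the intensity matrix; first column = protein_id."""
        raw = pd.read_csv(path, sep="\t", header=None, index_col=0)
        bait, replicate, cell_type = raw.iloc[0], raw.iloc[1], raw.iloc[2]
        run_names = raw.iloc[3]
        body = raw.iloc[4:].astype(float)
        body.columns = list(run_names)
        meta = {
            str(run): RunMeta(str(b), str(r), str(ct))
            for run, b, r, ct in zip(run_names, bait, replicate, cell_type)
        }
        body.index.name = "protein_id"
        return cls(body, meta)

    def write_tsv(self, path: str | Path) -> None:
        runs = list(self.intensities.columns)
        with open(path, "w") as fh:
            fh.write("bait\t" + "\t".join(self.meta[r].bait for r in runs) + "\n")
            fh.write(
                "replicate\t" + "\t".join(self.meta[r].replicate for r in runs) + "\n"
            )
            fh.write(
                "cell_type\t" + "\t".join(self.meta[r].cell_type for r in runs) + "\n"
            )
            fh.write("run\t" + "\t".join(runs) + "\n")
            for pid, row in self.intensities.iterrows():
                fh.write(pid + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


@dataclass(frozen=True)
class InteractorCall:
    protein_id: str
    cell_type: str
    status: str  # exclusive | enriched | rejected
    fold_per_replicate: tuple[float, ...]


@dataclass(frozen=True)
class AssociationRateScore:
    protein_id: str
    log2_rate: float


def rank_ibaq(table: PulldownTable, cell_type: str) -> pd.DataFrame:
    """Proteins sorted by mean target-run intensity (descending, ties by id).

    Returns a DataFrame with columns mean_intensity and rank (1-based).
    """
    targets = table.runs(cell_type, "target")
    mean_int = table.intensities[targets].mean(axis=1)
    order = sorted(mean_int.index, key=lambda pid: (-mean_int[pid], pid))
    out = pd.DataFrame({"mean_intensity": mean_int.loc[order]})
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def call_interactors(
    table: PulldownTable, min_fold: float = 4.0
) -> list[InteractorCall]:
    """Call interactors per cell type against the paired IgG controls.

    exclusive: detected in every target replicate, IgG zero in every
    replicate. enriched: fold = target/IgG >= ``min_fold`` in every
    replicate (IgG zero in only some replicates does not qualify for
    either branch). Everything else, including proteins undetected in
    any target replicate, is rejected.
    """
    calls: list[InteractorCall] = []
    for ct in table.cell_types():
        pairs = table.replicate_pairs(ct)
        tgt = table.intensities[[t for t, _ in pairs]].to_numpy()
        igg = table.intensities[[g for _, g in pairs]].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            folds = np.where(igg > 0, tgt / np.where(igg > 0, igg, 1), np.inf)
        detected_all = (tgt > 0).all(axis=1)
        igg_zero_all = (igg == 0).all(axis=1)
        igg_pos_all = (igg > 0).all(axis=1)
        enriched = igg_pos_all & (folds >= min_fold).all(axis=1)
        for i, pid in enumerate(table.intensities.index):
            if not detected_all[i]:
                status = "rejected"
            elif igg_zero_all[i]:
                status = "exclusive"
            elif enriched[i]:
                status = "enriched"
            else:
                status = "rejected"
            calls.append(
                InteractorCall(str(pid), ct, status, tuple(folds[i].tolist()))
            )
    return calls


def _mean_target_intensity(table: PulldownTable, cell_type: str) -> pd.Series:
    return table.intensities[table.runs(cell_type, "target")].mean(axis=1)


def association_rate(
    table: PulldownTable,
    bait_id: str,
    cell_types: tuple[str, str] = ("neurons", "escs"),
) -> list[AssociationRateScore]:
    """Bait-normalised association-rate change between two cell types.

    For each protein, r_ct = mean target intensity / bait intensity per
    cell type; log2_rate = log2(r_first / r_second), by default neurons
    over ESCs. Proteins (or the bait) undetected in a cell type get no
    score.
    """
    first, second = cell_types
    m1 = _mean_target_intensity(table, first)
    m2 = _mean_target_intensity(table, second)
    if bait_id not in m1.index or m1[bait_id] <= 0 or m2[bait_id] <= 0:
        raise ValueError(f"bait {bait_id!r} undetected in a cell type")
    scores = []
    for pid in table.intensities.index:
        if m1[pid] <= 0 or m2[pid] <= 0:
            continue
        r1 = m1[pid] / m1[bait_id]
        r2 = m2[pid] / m2[bait_id]
        scores.append(AssociationRateScore(str(pid), float(np.log2(r1 / r2))))
    return scores


def score_expression_correlation(
    scores: Sequence[AssociationRateScore],
    protein_fc: Mapping[str, float],
) -> tuple[float, pd.DataFrame]:
    """Pearson r between association-rate change and expression change.

    Residuals from the least-squares line of rate on expression flag
    candidates whose change in bait association is not explained by
    abundance (recruitment-regulated).
    """
    shared = [s for s in scores if s.protein_id in protein_fc]
    if len(shared) < 3:
        raise ValueError("need >=3 proteins shared between scores and fold changes")
    x = np.array([protein_fc[s.protein_id] for s in shared])
    y = np.array([s.log2_rate for s in shared])
    r = pearson_r(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    df = pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in shared],
            "log2_rate": y,
            "expression_log2fc": x,
            "residual": resid,
        }
    ).set_index("protein_id")
    return r, df


def category_enrichment(
    called: set[str],
    annotation: Mapping[str, set[str]],
    background: set[str],
) -> dict[str, FisherResult]:
    """Fisher enrichment of each category among called proteins.

    ``annotation`` maps category name -> member proteins. The 2x2 table
    per category is (called & cat, called & not cat, not called & cat,
    not called & not cat) over ``background``; cells sum to |background|.
    """
    if not called <= background:
        raise ValueError("called proteins must be a subset of the background")
    out = {}
    for cat, members in annotation.items():
        members = members & background
        if not members:
            raise ValueError(f"category {cat!r} absent from background")
        a = len(called & members)
        b = len(called - members)
        c = len(members - called)
        d = len(background) - a - b - c
        out[cat] = fisher_2x2(ContingencyTable2x2(a, b, c, d))
    return out
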