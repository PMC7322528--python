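"""Directional cross-layer association testing across time points.

Linked feature pairs (RNA-protein by gene id; promoter or distal ATAC
peak-RNA by nearest-gene assignment) are tested for association of
differential direction between a source contrast and a target contrast at
the same or a later time point, with a 2x2 Fisher test per direction
combination. Flows contradicting the central dogma (protein -> RNA,
RNA -> chromatin) and backwards-in-time cells are never produced. BH
correction is applied across all tests within one pair group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from .differential import Contrast, DifferentialRecord
from .intervals import GeneLink
from .stats import ContingencyTable2x2, FisherResult, bh_adjust, fisher_2x2

__all__ = [
    "LinkedPair",
    "AssociationResult",
    "link_layers",
    "build_contingency",
    "association_scan",
    "map_to_grid",
]

PairGroup = Literal["rna_protein", "atac_tss_rna", "atac_distal_rna"]

# direction of information flow for each pair group: source layer -> target layer
GROUP_LAYERS: dict[str, tuple[str, str]] = {
    "rna_protein": ("rna", "protein"),
    "atac_tss_rna": ("atac", "rna"),
    "atac_distal_rna": ("atac", "rna"),
}


@dataclass(frozen=True)
class LinkedPair:
    source_feature: str
    target_feature: str
    pair_group: str


@dataclass(frozen=True)
class AssociationResult:
    pair_group: str
    contrast_source: Contrast
    contrast_target: Contrast
    dir_source: str
    dir_target: str
    table: ContingencyTable2x2
    log2_or: float
    p: float
    adj_p: float

    @property
    def significant(self) -> bool:
        return self.adj_p < 0.05


def link_layers(
    rna_features: set[str],
    protein_features: set[str],
    gene_links: Sequence[GeneLink],
    promoter_peak: Mapping[str, str] | None = None,
) -> list[LinkedPair]:
    """Build the three pair universes.

    rna_protein: genes measured in both RNA and protein layers.
    atac_tss_rna: per expressed gene, the single closest promoter peak
    (<= 1.5 kb), via ``promoter_peak`` (gene_id -> peak_id).
    atac_distal_rna: every distal peak whose nearest gene is expressed;
    several peaks may point at one gene.
    """
    pairs: list[LinkedPair] = []
    for gene in sorted(rna_features & protein_features):
        pairs.append(LinkedPair(gene, gene, "rna_protein"))
    if promoter_peak is None:
        promoter_peak = {}
        best: dict[str, tuple[int, str]] = {}
        for lk in gene_links:
            if lk.link_type == "promoter":
                key = (lk.distance, lk.peak_id)
                if lk.gene_id not in best or key < best[lk.gene_id]:
                    best[lk.gene_id] = key
                    promoter_peak[lk.gene_id] = lk.peak_id
    for gene in sorted(promoter_peak):
        if gene in rna_features:
            pairs.append(LinkedPair(promoter_peak[gene], gene, "atac_tss_rna"))
    for lk in gene_links:
        if lk.link_type == "distal" and lk.gene_id in rna_features:
            pairs.append(LinkedPair(lk.peak_id, lk.gene_id, "atac_distal_rna"))
    return pairs


def build_contingency(
    pairs: Sequence[LinkedPair],
    source_records: Mapping[str, str],
    target_records: Mapping[str, str],
    dir_source: str,
    dir_target: str,
) -> ContingencyTable2x2:
    """2x2 table over the full pair universe for one direction combination.

    ``source_records`` / ``target_records`` map feature id -> direction
    label (up/down/ns) at the source / target contrast. a = both in
    class; b = source only; c = target only; d = neither. Features
    missing from a record map count as ns.
    """
    if not pairs:
        raise ValueError("empty pair universe")
    a = b = c = d = 0
    for pair in pairs:
        s = source_records.get(pair.source_feature, "ns") == dir_source
        t = target_records.get(pair.target_feature, "ns") == dir_target
        if s and t:
            a += 1
        elif s:
            b += 1
        elif t:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def map_to_grid(day: int, grid: Sequence[int]) -> int:
    """Map a day onto a reference time grid: nearest day, ties to the later."""
    return min(sorted(grid, reverse=True), key=lambda g: abs(g - day))


def admissible_cells(
    contrasts: Sequence[Contrast],
    groups: Sequence[str] = ("rna_protein", "atac_tss_rna", "atac_distal_rna"),
    reference_grid: Sequence[int] | None = None,
    directions: Sequence[str] = ("up", "down"),
) -> list[tuple[str, Contrast, Contrast, str, str]]:
    """Enumerate the admissible (group, source, target, dirs) test grid.

    A cell is admissible iff the source contrast lives in the group's
    source layer, the target contrast in its target layer, and the
    target's late day (mapped onto ``reference_grid`` when layers are
    sampled on different grids) is the same or later than the source's.
    """
    cells = []
    for group in groups:
        src_layer, tgt_layer = GROUP_LAYERS[group]
        src_contrasts = [c for c in contrasts if c.layer == src_layer]
        tgt_contrasts = [c for c in contrasts if c.layer == tgt_layer]
        grid = reference_grid or sorted(
            {c.day_late for c in src_contrasts} | {c.day_early for c in src_contrasts}
        )
        for cs, ct in itertools.product(src_contrasts, tgt_contrasts):
            if map_to_grid(ct.day_late, grid) < cs.day_late:
                continue
            for ds, dt in itertools.product(directions, directions):
                cells.append((group, cs, ct, ds, dt))
    return cells


def association_scan(
    pairs: Sequence[LinkedPair],
    all_records: Sequence[DifferentialRecord],
    contrasts: Sequence[Contrast],
    directions: Sequence[str] = ("up", "down"),
    alpha: float = 0.05,
    reference_grid: Sequence[int] | None = None,
) -> list[AssociationResult]:
    """Fisher-test every admissible directional cell; BH within pair group.

    One result per (pair_group, contrast_source, contrast_target,
    dir_source, dir_target) with the target contrast not earlier than the
    source. p values are adjusted across all tests of one pair group.
    """
    by_contrast: dict[Contrast, dict[str, str]] = {}
    for rec in all_records:
        by_contrast.setdefault(rec.contrast, {})[rec.feature_id] = rec.direction
    pairs_by_group: dict[str, list[LinkedPair]] = {}
    for p in pairs:
        pairs_by_group.setdefault(p.pair_group, []).append(p)

    cells = admissible_cells(
        contrasts,
        groups=[g for g in GROUP_LAYERS if g in pairs_by_group],
        reference_grid=reference_grid,
        directions=directions,
    )
    raw: list[tuple[tuple, ContingencyTable2x2, FisherResult]] = []
    for group, cs, ct, ds, dt in cells:
        table = build_contingency(
            pairs_by_group[group],
            by_contrast.get(cs, {}),
            by_contrast.get(ct, {}),
            ds,
            dt,
        )
        raw.append(((group, cs, ct, ds, dt), table, fisher_2x2(table)))

    results: list[AssociationResult] = []
    for group in pairs_by_group:
        in_group = [r for r in raw if r[0][0] == group]
        adj = bh_adjust([fr.p for _, _, fr in in_group])
        for ((g, cs, ct, ds, dt), table, fr), ap in zip(in_group, adj):
            results.append(
                AssociationResult(
                    g, cs, ct, ds, dt, table, fr.log2_or, fr.p, float(ap)
                )
            )
    return results
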