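"""Generate the synthetic multi-omics study and write it to disk.

Produces, under results/synthetic/: the toy genome (FASTA + TSS table +
peak BED), ATAC/RNA count and protein intensity matrices over the
differentiation time grid, ChIP peak sets with bedGraph mark tracks, the
pull-down intensity table, and every planted-truth table the later stages
are scored against.
"""

from pathlib import Path

import pandas as pd

from mchron.intervals import write_bed6
from mchron.chromstate import write_bedgraph
from mchron.simulate import (
    SimConfig,
    generate_chip,
    generate_genome,
    generate_multiomics,
    generate_pulldown,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    cfg.to_yaml(OUT / "config.yaml")

    bundle = generate_genome(cfg)
    bundle.write_fasta(OUT / "genome.fa")
    bundle.write_tss_tsv(OUT / "tss.tsv")
    write_bed6(bundle.peaks, OUT / "atac_peaks.bed")
    pd.Series(bundle.peak_kind, name="kind").rename_axis("peak_id").to_csv(
        OUT / "truth_peak_kind.tsv", sep="\t"
    )

    atac, rna, prot, truth = generate_multiomics(cfg, bundle)
    atac.rename_axis("peak_id").to_csv(OUT / "atac_counts.tsv", sep="\t")
    rna.rename_axis("gene_id").to_csv(OUT / "rna_counts.tsv", sep="\t")
    prot.rename_axis("gene_id").to_csv(OUT / "protein_intensity.tsv", sep="\t")
    for layer, frame in truth["labels"].items():
        frame.rename_axis("feature_id").to_csv(
            OUT / f"truth_directions_{layer}.tsv", sep="\t"
        )

    chip = generate_chip(cfg, bundle)
    write_bed6(chip.factor_peaks, OUT / "chip_factor_peaks.bed")
    write_bed6(chip.partner_peaks, OUT / "chip_partner_peaks.bed")
    for i, rep in enumerate(chip.replicate_sets, start=1):
        write_bed6(rep, OUT / f"chip_factor_rep{i}.bed")
    for track in chip.tracks:
        write_bedgraph(track, OUT / f"track_{track.name}.bedGraph")
    chip.group_truth.rename_axis("peak_id").to_csv(OUT / "truth_chip_groups.tsv", sep="\t")
    chip.cobound_truth.rename_axis("peak_id").to_csv(OUT / "truth_cobound.tsv", sep="\t")
    chip.gene_expression.rename_axis("gene_id").to_csv(
        OUT / "chip_gene_expression.tsv", sep="\t"
    )

    table, pd_truth = generate_pulldown(cfg)
    table.write_tsv(OUT / "pulldown.tsv")
    pd_truth.rename_axis("protein_id").to_csv(OUT / "truth_pulldown.tsv", sep="\t")

    n_prom = sum(1 for k in bundle.peak_kind.values() if k == "promoter")
    print(f"genome: {cfg.n_chroms} x {cfg.chrom_length/1000:.0f} kb, "
          f"{cfg.n_genes} genes, {len(bundle.peaks)} peaks ({n_prom} promoter)")
    print(f"matrices: ATAC {atac.shape}, RNA {rna.shape}, protein {prot.shape}")
    print(f"ChIP: {len(chip.factor_peaks)} factor peaks, "
          f"{int(chip.cobound_truth.sum())} co-bound, "
          f"{len(chip.replicate_sets)} jittered replicate sets")
    print(f"pull-down: {table.intensities.shape[0]} proteins x "
          f"{table.intensities.shape[1]} runs")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
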