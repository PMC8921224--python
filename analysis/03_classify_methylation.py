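#!/usr/bin/env python
"""Classify expressed genes into the six methylation categories.

Applies the binomial-test classifier to the WT methylome: FPKM-filters the
gene set (FPKM >= 0.5 in at least one genotype), tests each gene's body
(per context), best promoter bin and best downstream bin against the
cohort-wide backgrounds, and assigns gbM / Intron-teM / Other-teM / pM /
dM / UM. Compares the result with the planted truth.

Requires analysis/01_simulate_study.py to have run first.
"""

import json
from pathlib import Path

import pandas as pd

from methylfree import classify, expression, methylome
from methylfree.genome import derive_gene_regions, read_fasta, read_gff3

STUDY = Path("results/study")
OUT = Path("results")


def main():
    genome = read_fasta(STUDY / "genome.fa", organelle_flags={"ChrC"})
    genes, _ = read_gff3(STUDY / "annotation.gff3", genome)
    ctx_map = methylome.annotate_contexts(genome)
    wt = methylome.filter_coverage(
        methylome.read_methratio(STUDY / "methratio_WT.tsv", ctx_map), 4
    )

    counts = pd.read_csv(STUDY / "counts_gene.tsv", sep="\t", index_col=0)
    design = expression.read_design(STUDY / "design.tsv")
    lengths = pd.Series({g.gene_id: sum(e - s + 1 for s, e in g.exons) for g in genes})
    fpkm = expression.compute_fpkm(counts, lengths)
    expressed = expression.filter_expressed(fpkm, design)
    print(f"expressed genes: {len(expressed)} of {len(genes)} (FPKM >= 0.5 in >= 1 genotype)")

    regions = {g.gene_id: derive_gene_regions(g, genome) for g in genes}
    result = classify.classify_genes(expressed, wt, genes, regions)
    result.to_csv(OUT / "gene_categories.tsv", sep="\t")
    summary = classify.category_summary(result)
    with open(OUT / "category_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print("category counts:", summary["counts"])

    truth = json.load(open(STUDY / "truth.json"))["gene_categories"]
    planted = pd.Series(truth).reindex(result.index)
    recovery = float((result["category"] == planted).mean())
    print(f"planted-category recovery among expressed genes: {recovery:.1%}")


if __name__ == "__main__":
    main()
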