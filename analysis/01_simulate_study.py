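#!/usr/bin/env python
"""Generate the synthetic study: genome, annotation, methylomes, counts, reads.

Writes all fixtures with planted ground truth under results/study/. The
configuration mirrors the study design: a WT / ddcc / met1 / mddcc genotype
panel, six planted gene methylation categories, planted cross-genotype
regulation patterns, intron-teM genes with 3'-depleted transcripts, and
five planted TE insertions with defined TSDs.

Run from the repository root:  python analysis/01_simulate_study.py [seed]
"""

import sys
from pathlib import Path

import yaml

from methylfree import methylome, pipeline, simulate
from methylfree.genome import write_fasta, write_gff3

OUT = Path("results/study")

CONFIG_OVERRIDES = {
    "seed": int(sys.argv[1]) if len(sys.argv) > 1 else 7,
    "n_genes_per_category": {c: 12 for c in ("gbM", "Intron-teM", "Other-teM", "pM", "dM", "UM")},
    "n_per_pattern": {p: 3 for p in simulate.PATTERN_EFFECTS},
    "insertion_zone_len": 60_000,
}


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "config.yaml", "w") as fh:
        yaml.safe_dump(CONFIG_OVERRIDES, fh)
    config = simulate.SimulationConfig.from_dict(CONFIG_OVERRIDES)

    genome, genes, tes, truth = simulate.simulate_genome(config)
    write_fasta(genome, OUT / "genome.fa")
    write_gff3(genes, tes, OUT / "annotation.gff3")
    print(f"genome: {genome.length('Chr1'):,} bp nuclear + {genome.length('ChrC'):,} bp organelle;"
          f" {len(genes)} genes, {len(tes)} TEs")

    tables = simulate.simulate_methylomes(genome, genes, truth, config)
    for genotype, table in tables.items():
        methylome.write_methratio(table, OUT / f"methratio_{genotype}.tsv")
    print(f"methylomes: {len(tables['WT']):,} cytosine records per genotype")

    panel = simulate.simulate_counts(genes, truth, config)
    for cls, counts in panel["counts"].items():
        counts.rename_axis("feature_id").to_csv(OUT / f"counts_{cls}.tsv", sep="\t")
    panel["design"].rename("genotype").to_frame().rename_axis("sample").to_csv(
        OUT / "design.tsv", sep="\t"
    )
    pipeline.write_splits(panel["intron_splits"], OUT / "intron_splits.tsv")
    print(f"counts: {len(panel['counts']['gene'])} genes x {len(panel['design'])} samples,"
          f" {sum(len(v) for k, v in truth.pattern_by_feature.items())} planted patterns")

    simulate.simulate_insertion_readset(genome, tes, truth, config, sam_path=OUT / "reads.sam")
    truth.to_json(OUT / "truth.json")
    print(f"reads.sam with {len(truth.insertions)} planted insertions; truth.json written")


if __name__ == "__main__":
    main()
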