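#!/usr/bin/env python
"""Intron-teM 3'/5' transcript-ratio screen.

Intronic heterochromatic methylation can be required for full-length
transcript accumulation; when it is lost, the 3' part of the transcript
drops relative to the 5' part. For every intron-teM gene this screen keeps
genes with WT 5' counts >= 10 and flags a gene in a mutant when
log2[(3'/5' mutant)/(3'/5' WT)] < -1. Both the mddcc-only tally and the
any-mutant tally are reported, since 3' loss can already appear in the
single mutants.

Requires analysis/01_simulate_study.py to have run first.
"""

import json
from pathlib import Path

from methylfree import expression, pipeline

STUDY = Path("results/study")
OUT = Path("results")


def main():
    splits = pipeline.read_splits(STUDY / "intron_splits.tsv")
    screen = expression.intron_tem_screen(splits)
    screen.to_csv(OUT / "intron_tem_screen.tsv", sep="\t", index=False)
    s = screen.attrs["summary"]
    print(f"intron-teM genes tested: {s['n_genes']}; retained (WT 5' >= 10): {s['n_retained']}")
    print(f"3'-down-regulated: {s['n_flagged_mddcc']} in mddcc, "
          f"{s['n_flagged_any_mutant']} in at least one mutant")
    truth = json.load(open(STUDY / "truth.json"))
    print(f"planted 3'-depleted genes: {sorted(truth['tem3_depleted'])}")
    flagged = sorted(screen[screen["flagged"]]["gene_id"].unique())
    print(f"flagged genes: {flagged}")


if __name__ == "__main__":
    main()
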