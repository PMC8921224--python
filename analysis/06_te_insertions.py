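#!/usr/bin/env python
"""Split-read TE insertion calling with TSD detection.

Runs the full caller on the simulated read set: candidate pair selection,
extremity clip-mapping (>= 20 nt), recursive genomic clipping, mate
validation, breakpoint clustering (>= 4 reads per extremity), TSD calling
(4-19 bp overlap), and the centromere / chromosome-end / N-run / donor-span
filters. Compares calls with the planted insertions.

Requires analysis/01_simulate_study.py to have run first.
"""

import json
from pathlib import Path

from methylfree import simulate
from methylfree.genome import build_mask, read_fasta, read_gff3
from methylfree.insertions import call_insertions, read_sam, write_calls

STUDY = Path("results/study")
OUT = Path("results")


def main():
    genome = read_fasta(STUDY / "genome.fa", organelle_flags={"ChrC"})
    _, tes = read_gff3(STUDY / "annotation.gff3", genome)
    truth = json.load(open(STUDY / "truth.json"))

    # the centromere analog is the genome's long N block: reuse the N-run scan
    n_mask = build_mask(genome)
    cen = {c: spans for c, spans in n_mask.n_run_spans.items() if spans}
    mask = build_mask(genome, centromere_spans=cen)

    alignments = read_sam(STUDY / "reads.sam")
    passed, all_calls = call_insertions(alignments, genome, tes, mask)
    write_calls(all_calls, bed_path=OUT / "insertions.bed", json_path=OUT / "insertions.json")

    expected = {
        (t["chrom"], t["tsd_start"], t["tsd_end"], t["te_id"])
        for t in truth["insertions"]
        if t["expect"] == "called"
    }
    got = {(c.chrom, c.tsd[0], c.tsd[1], c.te_id) for c in passed}
    print(f"calls passing filters: {len(passed)} (of {len(all_calls)} raw)")
    for c in passed:
        print(f"  {c.chrom}:{c.tsd[0]}-{c.tsd[1]} {c.te_id} ({c.family}) TSD {c.tsd_len} bp,"
              f" {c.n_reads_5prime}+{c.n_reads_3prime} reads")
    print(f"planted insertions recovered with exact TSD: {len(got & expected)}/{len(expected)};"
          f" false calls: {len(got - expected)}")


if __name__ == "__main__":
    main()
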