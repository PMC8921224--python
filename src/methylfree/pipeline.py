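"""End-to-end pipeline over synthetic or provided inputs, with a JSON report.

Stages run in dependency order: methylome levels -> backgrounds ->
methylation-category classification -> expression (FPKM filter, DE,
regulation patterns) -> intron-teM 3' screen -> TE insertion calling.
Each stage writes its artifacts plus a small summary JSON under the output
directory; the final report is the merge of the stage summaries, so it can
be regenerated from saved intermediates and compared for equality.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import classify, expression, insertions, methylome, simulate
from .genome import build_mask, derive_gene_regions, write_fasta, write_gff3

logger = logging.getLogger(__name__)

STAGE_FILES = (
    "stage_methylome.json",
    "stage_classification.json",
    "stage_expression.json",
    "stage_intron_tem.json",
    "stage_insertions.json",
)

DEFAULT_THRESHOLDS = {
    "min_coverage": 4,
    "q_threshold": 0.01,
    "fpkm_min": 0.5,
    "fc_gene": 2.0,
    "fc_antisense": 4.0,
    "alpha": 0.01,
    "delta": 1.0,
    "min_wt_5prime": 10,
    "min_clip": 20,
    "min_reads": 4,
    "tsd_min": 4,
    "tsd_max": 19,
    "ext_len": 300,
}


def _dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def write_splits(splits, path) -> None:
    rows = []
    for sp in splits:
        for genotype in sp.counts_5prime:
            rows.append(
                (
                    sp.gene_id,
                    sp.split_intron[0],
                    sp.split_intron[1],
                    genotype,
                    sp.counts_5prime[genotype],
                    sp.counts_3prime.get(genotype, 0),
                )
            )
    pd.DataFrame(
        rows,
        columns=["gene_id", "intron_start", "intron_end", "genotype", "count_5prime", "count_3prime"],
    ).to_csv(path, sep="\t", index=False)


def read_splits(path) -> list:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        sp = out.setdefault(
            row.gene_id,
            expression.IntronSplitCounts(
                gene_id=row.gene_id, split_intron=(int(row.intron_start), int(row.intron_end))
            ),
        )
        sp.counts_5prime[row.genotype] = int(row.count_5prime)
        sp.counts_3prime[row.genotype] = int(row.count_3prime)
    return list(out.values())


def run_pipeline(
    config: simulate.SimulationConfig,
    outdir,
    thresholds: dict | None = None,
    write_methylomes: bool = False,
) -> dict:
    """Simulate the study inputs and run every analysis stage.

    Returns the report dict (also written as ``report.json``); artifact
    files and per-stage summaries land under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    logger.info("pipeline thresholds: %s", thr)

    # --- simulate inputs -------------------------------------------------
    genome, genes, tes, truth = simulate.simulate_genome(config)
    write_fasta(genome, outdir / "genome.fa")
    write_gff3(genes, tes, outdir / "annotation.gff3")
    tables = simulate.simulate_methylomes(genome, genes, truth, config)
    panel = simulate.simulate_counts(genes, truth, config)
    sam_lines = simulate.simulate_insertion_readset(genome, tes, truth, config, sam_path=outdir / "reads.sam")
    truth.to_json(outdir / "truth.json")
    panel["design"].rename("genotype").to_frame().rename_axis("sample").to_csv(
        outdir / "design.tsv", sep="\t"
    )
    for cls, counts in panel["counts"].items():
        counts.rename_axis("feature_id").to_csv(outdir / f"counts_{cls}.tsv", sep="\t")
    write_splits(panel["intron_splits"], outdir / "intron_splits.tsv")

    # --- methylome stage --------------------------------------------------
    filtered = {
        g: methylome.filter_coverage(t, thr["min_coverage"]) for g, t in tables.items()
    }
    if write_methylomes:
        for g, t in filtered.items():
            methylome.write_methratio(t, outdir / f"methratio_{g}.tsv")
    meth_summary = {}
    for g, t in filtered.items():
        levels = methylome.context_level_summary(t, genome)
        meth_summary[g] = {
            "nuclear": levels["nuclear"],
            "organelle": levels["organelle"],
            "nonconversion_estimate": methylome.estimate_nonconversion(t, genome),
        }
    _dump({"methylation_levels": meth_summary}, outdir / "stage_methylome.json")

    # --- expression filter + classification ------------------------------
    lengths = panel["gene_lengths"]
    fpkm = expression.compute_fpkm(panel["counts"]["gene"], lengths)
    expressed = expression.filter_expressed(fpkm, panel["design"], thr["fpkm_min"])
    regions = {g.gene_id: derive_gene_regions(g, genome) for g in genes}
    classified = classify.classify_genes(
        expressed, filtered["WT"], genes, regions, q_threshold=thr["q_threshold"]
    )
    classified.to_csv(outdir / "gene_categories.tsv", sep="\t")
    summary = classify.category_summary(classified)
    if summary["total"] != len(expressed):
        raise RuntimeError("classification does not partition the expressed-gene set")
    _dump(
        {"expressed_genes": len(expressed), "categories": summary},
        outdir / "stage_classification.json",
    )

    # --- differential expression + patterns ------------------------------
    de_summary: dict = {}
    pattern_summary: dict = {}
    for cls, counts in panel["counts"].items():
        de_by_geno = {}
        for genotype in ("ddcc", "met1", "mddcc"):
            res = expression.de_test(counts, panel["design"], (genotype, "WT"))
            res = expression.call_de_features(res, cls, alpha=thr["alpha"])
            res.to_csv(outdir / f"de_{cls}_{genotype}.tsv", sep="\t")
            de_by_geno[genotype] = res
            up, down = expression.de_sets(res)
            de_summary.setdefault(cls, {})[genotype] = {"up": len(up), "down": len(down)}
        patterns = expression.classify_patterns(de_by_geno, delta=thr["delta"])
        patterns.to_csv(outdir / f"patterns_{cls}.tsv", sep="\t")
        counts_by_dir = (
            patterns.groupby(["direction", "pattern"]).size().unstack(fill_value=0)
        )
        pattern_summary[cls] = {
            direction: {k: int(v) for k, v in row.items() if v}
            for direction, row in counts_by_dir.iterrows()
        }
    _dump(
        {"de_counts": de_summary, "pattern_counts": pattern_summary},
        outdir / "stage_expression.json",
    )

    # --- intron-teM screen ------------------------------------------------
    screen = expression.intron_tem_screen(
        panel["intron_splits"], min_wt_5prime=thr["min_wt_5prime"]
    )
    screen.to_csv(outdir / "intron_tem.tsv", sep="\t", index=False)
    _dump({"intron_tem": screen.attrs["summary"]}, outdir / "stage_intron_tem.json")

    # --- insertion calling ------------------------------------------------
    mask = build_mask(genome, centromere_spans=simulate.centromere_spans(truth))
    alignments = insertions.read_sam(outdir / "reads.sam")
    passed, all_calls = insertions.call_insertions(
        alignments,
        genome,
        tes,
        mask,
        ext_len=thr["ext_len"],
        min_match=thr["min_clip"],
        min_reads=thr["min_reads"],
        tsd_min=thr["tsd_min"],
        tsd_max=thr["tsd_max"],
    )
    insertions.write_calls(all_calls, bed_path=outdir / "insertions.bed", json_path=outdir / "insertions.json")
    _dump(
        {
            "insertions": {
                "n_pass": len(passed),
                "n_total": len(all_calls),
                "calls": [
                    {
                        "chrom": c.chrom,
                        "te_id": c.te_id,
                        "tsd": list(c.tsd),
                        "tsd_len": c.tsd_len,
                        "status": c.filter_status,
                    }
                    for c in all_calls
                ],
            }
        },
        outdir / "stage_insertions.json",
    )

    report = regenerate_report(outdir, thresholds=thr, seed=config.seed)
    return report


def regenerate_report(outdir, thresholds: dict | None = None, seed: int | None = None) -> dict:
    """Assemble (or re-assemble) report.json from saved stage summaries."""
    outdir = Path(outdir)
    report: dict = {}
    for name in STAGE_FILES:
        path = outdir / name
        if not path.exists():
            raise FileNotFoundError(f"missing stage output {name}; rerun the pipeline stage")
        with open(path) as fh:
            report.update(json.load(fh))
    if thresholds is not None:
        report["thresholds"] = thresholds
    if seed is not None:
        report["seed"] = seed
    else:
        old = outdir / "report.json"
        if old.exists():
            with open(old) as fh:
                prev = json.load(fh)
            report.setdefault("thresholds", prev.get("thresholds"))
            report.setdefault("seed", prev.get("seed"))
    manifest = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    _dump(manifest, outdir / "manifest.json")
    _dump(report, outdir / "report.json")
    return report
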