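"""Synthetic genomes, methylomes, count panels and read sets with planted truth.

The generator emulates the statistical structure of the study inputs so
that every pipeline stage is testable without sequencing data:

* a random nuclear chromosome laid out with gene slots (two exons, one
  intron, 2-kb flanks), a TE zone, a centromere-like N block and an
  insertion target zone, plus an unmethylated organelle control
  chromosome;
* per-genotype methylomes in which each planted gene category elevates the
  appropriate region/context levels in WT and the mutant genotypes erase
  contexts (ddcc: non-CG; met1: CG, with mildly reduced non-CG; mddcc:
  everything), with a bisulfite non-conversion floor applied everywhere
  including the organelle;
* negative-binomial count matrices (gamma-Poisson) with planted
  cross-genotype regulation patterns for genes, TEs, antisense and
  non-annotated features, and 5'/3' split counts for intron-teM genes with
  planted 3' depletion;
* paired-end read sets spanning planted TE insertions with defined TSDs,
  written as minimal SAM (junction and TE-interior reads unmapped with
  sequence retained, background pairs proper).

Every generator is a pure function of (config, seed): rerunning with the
same configuration reproduces identical bytes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CATEGORIES
from .expression import GENOTYPES, IntronSplitCounts
from .genome import (
    GeneModel,
    GenomeSequence,
    TEAnnotation,
    derive_gene_regions,
)
from .methylome import CONTEXTS, MethylomeTable, annotate_contexts

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: planted log2 fold changes per regulation pattern (ddcc, met1, mddcc)
PATTERN_EFFECTS = {
    "Redundancy": (0.0, 0.0, 3.0),
    "DosageI": (0.0, 1.5, 3.0),
    "DosageII": (1.5, 0.0, 3.0),
    "DosageIII": (1.2, 1.2, 3.0),
    "mCG": (0.0, 3.0, 3.0),
    "non_mCG": (3.0, 0.0, 3.0),
}

#: context scale factors applied by each genotype's methyltransferase losses
GENOTYPE_ERASURE = {
    "WT": {"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
    "ddcc": {"CG": 1.0, "CHG": 0.0, "CHH": 0.0},
    "met1": {"CG": 0.0, "CHG": None, "CHH": None},  # None -> met1_noncg_factor
    "mddcc": {"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
}


@dataclass
class InsertionSpec:
    te_index: int
    tsd_len: int
    target: int | str = "auto"  # 1-based TSD start, or auto / chrom_end / donor_span
    n_reads_5prime: int = 10
    n_reads_3prime: int = 10
    expect: str = "called"  # called | not_called | filtered


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study conditions as defaults."""

    seed: int = 1

    # genome layout
    n_genes_per_category: dict = field(
        default_factory=lambda: {cat: 25 for cat in CATEGORIES}
    )
    exon_len: int = 400
    intron_len: int = 400
    flank_bp: int = 2000
    gene_gap: int = 200
    n_tes: int = 8
    te_len: int = 1000
    te_gap: int = 500
    insertion_zone_len: int = 60000
    centromere_len: int = 2000
    edge_margin: int = 4000
    organelle_len: int = 20000
    max_chrom_len: int | None = None  # optional bound; layout overflow -> error

    # methylome
    background_levels: dict = field(
        default_factory=lambda: {"CG": 0.05, "CHG": 0.02, "CHH": 0.02}
    )
    gbm_body_cg: float = 0.3
    tem_body_noncg: float = 0.3
    hot_bin_level: float = 0.4
    nonconversion: float = 0.004
    coverage_mean: float = 20.0
    met1_noncg_factor: float = 0.7

    # expression counts
    n_replicates: int = 3
    n_per_pattern: dict = field(default_factory=lambda: {p: 6 for p in PATTERN_EFFECTS})
    pattern_mean: float = 500.0
    dispersion: float = 0.05
    null_mean: float = 200.0
    n_unexpressed_genes: int = 5
    n_te_features: int = 60
    n_antisense_features: int = 40
    n_non_annotated_features: int = 40

    # intron-teM 3' depletion
    tem3_part_mean: float = 200.0
    tem3_depletion_factor: float = 5.0
    tem3_n_depleted_mddcc: int = 4
    tem3_n_depleted_met1: int = 1
    tem3_n_low_wt5: int = 2

    # insertion read sets
    insertions: list[InsertionSpec] = field(
        default_factory=lambda: [
            InsertionSpec(te_index=i, tsd_len=t) for i, t in enumerate((5, 7, 9, 12, 15))
        ]
    )
    read_len: int = 100
    pair_gap: int = 150
    n_background_pairs: int = 200

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "insertions" in data:
            data["insertions"] = [
                ins if isinstance(ins, InsertionSpec) else InsertionSpec(**ins)
                for ins in data["insertions"]
            ]
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthSet:
    """Machine-readable planted ground truth accompanying every fixture."""

    gene_categories: dict = field(default_factory=dict)
    pattern_by_feature: dict = field(default_factory=dict)  # feature -> (direction, pattern)
    tem3_depleted: dict = field(default_factory=dict)  # gene -> {genotype: factor}
    tem3_low_wt5: list = field(default_factory=list)
    insertions: list = field(default_factory=list)  # dicts with te_id, tsd, expect
    nonconversion: float = 0.0
    hot_bins: dict = field(default_factory=dict)  # gene -> (region, bin_index)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# Genome


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneModel], list[TEAnnotation], TruthSet]:
    """Build the synthetic genome, annotation, and planted-category truth.

    Gene slots are pitched so that no gene's 2-kb flank overlaps a
    neighbouring gene's flank, keeping planted promoter/downstream signals
    attributable to a single gene. Raises when the requested features
    cannot fit the layout.
    """
    rng = np.random.default_rng([config.seed, 0])
    truth = TruthSet(nonconversion=config.nonconversion)

    gene_len = 2 * config.exon_len + config.intron_len
    pitch = 2 * config.flank_bp + gene_len + config.gene_gap
    categories = [cat for cat, n in config.n_genes_per_category.items() for _ in range(n)]
    if any(cat not in CATEGORIES for cat in categories):
        raise ValueError("unknown planted category")
    rng.shuffle(categories)
    n_genes = len(categories)

    cursor = config.edge_margin + 1
    genes: list[GeneModel] = []
    for i, cat in enumerate(categories):
        start = cursor + config.flank_bp
        end = start + gene_len - 1
        strand = "+" if rng.random() < 0.5 else "-"
        exon1 = (start, start + config.exon_len - 1)
        exon2 = (end - config.exon_len + 1, end)
        gid = f"gene{i + 1:05d}"
        genes.append(
            GeneModel(gene_id=gid, chrom="Chr1", strand=strand, start=start, end=end, exons=(exon1, exon2))
        )
        truth.gene_categories[gid] = cat
        cursor += pitch

    te_zone_start = cursor + 2000
    tes: list[TEAnnotation] = []
    cursor = te_zone_start
    for i in range(config.n_tes):
        tes.append(
            TEAnnotation(
                te_id=f"te{i + 1:03d}",
                family=f"FAM{i % 4 + 1}",
                chrom="Chr1",
                strand="+",
                start=cursor,
                end=cursor + config.te_len - 1,
            )
        )
        cursor += config.te_len + config.te_gap

    cen_start = cursor + 3500
    cen_end = cen_start + config.centromere_len - 1
    ins_zone_start = cen_end + 3500 + 1
    ins_zone_end = ins_zone_start + config.insertion_zone_len - 1
    chr1_len = ins_zone_end + config.edge_margin
    if config.max_chrom_len is not None and chr1_len > config.max_chrom_len:
        raise ValueError(
            f"layout needs {chr1_len} bp but max_chrom_len is {config.max_chrom_len};"
            " too many features for the requested size"
        )

    seq = np.frombuffer(_random_seq(rng, chr1_len).encode(), dtype=np.uint8).copy()
    seq[cen_start - 1 : cen_end] = ord("N")
    chr1 = seq.tobytes().decode()
    chrc = _random_seq(rng, config.organelle_len)
    genome = GenomeSequence({"Chr1": chr1, "ChrC": chrc}, organelle_flags={"ChrC"})

    # resolve insertion targets
    n_auto = sum(1 for ins in config.insertions if ins.target == "auto")
    auto_positions = np.linspace(
        ins_zone_start + 1000, ins_zone_end - 1000, max(n_auto, 1)
    ).astype(int)
    k = 0
    resolved = []
    for ins in config.insertions:
        te = tes[ins.te_index]
        if ins.target == "auto":
            target = int(auto_positions[k])
            k += 1
        elif ins.target == "chrom_end":
            target = chr1_len - 2500
        elif ins.target == "donor_span":
            target = (te.start + te.end) // 2
        else:
            target = int(ins.target)
        resolved.append((ins, te, target))
        truth.insertions.append(
            {
                "te_id": te.te_id,
                "chrom": "Chr1",
                "tsd_start": target,
                "tsd_end": target + ins.tsd_len - 1,
                "tsd_len": ins.tsd_len,
                "expect": ins.expect,
            }
        )
    truth._resolved_insertions = resolved  # type: ignore[attr-defined]
    truth._centromere = ("Chr1", cen_start, cen_end)  # type: ignore[attr-defined]
    return genome, genes, tes, truth


def centromere_spans(truth: TruthSet) -> dict[str, list[tuple[int, int]]]:
    chrom, s, e = truth._centromere  # type: ignore[attr-defined]
    return {chrom: [(s, e)]}


# ---------------------------------------------------------------------------
# Methylomes


def _paint_levels(genome, genes, truth, config):
    """Per-chromosome, per-context WT level arrays from planted categories."""
    rng = np.random.default_rng([config.seed, 1])
    levels = {}
    for chrom in genome.chrom_names:
        L = genome.length(chrom)
        organelle = chrom in genome.organelle_flags
        levels[chrom] = {
            ctx: np.full(L, 0.0 if organelle else config.background_levels[ctx], np.float32)
            for ctx in CONTEXTS
        }
    for gene in genes:
        cat = truth.gene_categories.get(gene.gene_id, "UM")
        arr = levels[gene.chrom]
        regions = derive_gene_regions(gene, genome, flank_bp=config.flank_bp)
        if cat == "gbM":
            arr["CG"][gene.start - 1 : gene.end] = config.gbm_body_cg
        elif cat == "Other-teM":
            for s, e in gene.exons:
                for ctx in CONTEXTS:
                    arr[ctx][s - 1 : e] = config.tem_body_noncg
        elif cat == "Intron-teM":
            for s, e in gene.introns:
                for ctx in CONTEXTS:
                    arr[ctx][s - 1 : e] = config.tem_body_noncg
        elif cat in ("pM", "dM"):
            bins = regions.promoter_bins if cat == "pM" else regions.downstream_bins
            if bins:
                idx = int(rng.integers(0, len(bins)))
                s, e = bins[idx]
                for ctx in CONTEXTS:
                    arr[ctx][s - 1 : e] = config.hot_bin_level
                truth.hot_bins[gene.gene_id] = (cat, idx)
    return levels


def simulate_methylomes(
    genome: GenomeSequence,
    genes: list[GeneModel],
    truth: TruthSet,
    config: SimulationConfig,
    genotypes: tuple[str, ...] = GENOTYPES,
) -> dict[str, MethylomeTable]:
    """Per-genotype per-cytosine methylomes.

    For every assignable cytosine, coverage ~ 1 + Poisson(mean - 1) and the
    methylated-call count ~ Binomial(coverage, p) with
    p = nonconversion + (1 - nonconversion) * level, where the level is the
    planted WT level scaled by the genotype's context-erasure factors
    (zero everywhere on the organelle control).
    """
    ctx_map = annotate_contexts(genome)
    wt_levels = _paint_levels(genome, genes, truth, config)
    out = {}
    for gi, genotype in enumerate(genotypes):
        rng = np.random.default_rng([config.seed, 2, gi])
        frames = []
        erasure = GENOTYPE_ERASURE[genotype]
        for chrom in genome.chrom_names:
            pos, strand_code, ctx_code = ctx_map.sites(chrom)
            level = np.zeros(len(pos), np.float64)
            for ctx, code in zip(CONTEXTS, (1, 2, 3)):
                factor = erasure[ctx]
                if factor is None:
                    factor = config.met1_noncg_factor
                m = ctx_code == code
                level[m] = wt_levels[chrom][ctx][pos[m] - 1] * factor
            p = config.nonconversion + (1.0 - config.nonconversion) * level
            cov = 1 + rng.poisson(config.coverage_mean - 1.0, len(pos))
            c = rng.binomial(cov, p)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": pd.Categorical([chrom] * len(pos)),
                        "pos": pos,
                        "strand": np.where(strand_code == 0, "+", "-"),
                        "context": pd.Categorical.from_codes(ctx_code - 1, list(CONTEXTS)),
                        "c_count": c,
                        "ct_count": cov,
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        df["context"] = df["context"].astype(str)
        out[genotype] = MethylomeTable(df, sample=f"{genotype}_sim", genotype=genotype)
    return out


# ---------------------------------------------------------------------------
# Counts


def _nb_draws(rng, mean, dispersion, size):
    """Gamma-Poisson negative binomial with Var = mu + dispersion * mu^2."""
    mean = np.broadcast_to(np.asarray(mean, float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _pattern_matrix(rng, feature_ids, planted, config, truth, prefix):
    """Count matrix for one feature class with planted patterns."""
    samples = [f"{g}_r{r + 1}" for g in GENOTYPES for r in range(config.n_replicates)]
    lfc = np.zeros((len(feature_ids), len(GENOTYPES)))
    base = np.full(len(feature_ids), config.null_mean)
    for i, fid in enumerate(feature_ids):
        if fid in planted:
            direction, pattern = planted[fid]
            sign = 1.0 if direction == "up" else -1.0
            eff = PATTERN_EFFECTS[pattern]
            lfc[i, 1:] = sign * np.asarray(eff)
            base[i] = config.pattern_mean
            truth.pattern_by_feature[fid] = (direction, pattern)
    counts = np.zeros((len(feature_ids), len(samples)), np.int64)
    for j, g in enumerate(GENOTYPES):
        mu = base * np.exp2(lfc[:, j])
        for r in range(config.n_replicates):
            col = j * config.n_replicates + r
            counts[:, col] = _nb_draws(rng, mu, config.dispersion, (len(feature_ids),))
    return pd.DataFrame(counts, index=feature_ids, columns=samples)


def simulate_counts(
    genes: list[GeneModel], truth: TruthSet, config: SimulationConfig
) -> dict:
    """Count matrices, design, gene lengths and intron-split part counts.

    Planted regulation patterns are assigned to a seed-shuffled subset of
    genes (and to dedicated TE / antisense / non-annotated features);
    remaining features are null. A handful of genes are planted with near
    zero expression to exercise the FPKM filter. Returns a dict with keys
    ``counts`` (per feature class), ``design``, ``gene_lengths`` and
    ``intron_splits``.
    """
    rng = np.random.default_rng([config.seed, 3])
    design = pd.Series(
        {f"{g}_r{r + 1}": g for g in GENOTYPES for r in range(config.n_replicates)},
        name="genotype",
    )

    gene_ids = [g.gene_id for g in genes]
    order = list(rng.permutation(len(gene_ids)))
    planted: dict[str, tuple[str, str]] = {}
    it = iter(order)
    for pattern, n in config.n_per_pattern.items():
        for _ in range(n):
            try:
                planted[gene_ids[next(it)]] = ("up", pattern)
            except StopIteration as exc:
                raise ValueError("more planted patterns than genes") from exc
    unexpressed = []
    for _ in range(config.n_unexpressed_genes):
        try:
            unexpressed.append(gene_ids[next(it)])
        except StopIteration:
            break

    counts_gene = _pattern_matrix(rng, gene_ids, planted, config, truth, "gene")
    for gid in unexpressed:
        counts_gene.loc[gid] = 0
        truth.pattern_by_feature.pop(gid, None)
    truth.unexpressed_genes = unexpressed  # type: ignore[attr-defined]

    def side_panel(prefix, n_features):
        ids = [f"{prefix}{i + 1:04d}" for i in range(n_features)]
        # planted features stay a minority so median-of-ratios normalisation
        # keeps its breakdown margin
        pat = {}
        cyc = list(PATTERN_EFFECTS)
        for i, fid in enumerate(ids[: n_features // 4]):
            pat[fid] = ("up", cyc[i % len(cyc)])
        return _pattern_matrix(rng, ids, pat, config, truth, prefix)

    out_counts = {
        "gene": counts_gene,
        "TE": side_panel("tefeat", config.n_te_features),
        "antisense": side_panel("as", config.n_antisense_features),
        "non_annotated": side_panel("na", config.n_non_annotated_features),
    }
    gene_lengths = pd.Series(
        {g.gene_id: sum(e - s + 1 for s, e in g.exons) for g in genes}, name="length"
    )

    # intron-split part counts for Intron-teM genes
    tem_genes = [gid for gid, cat in truth.gene_categories.items() if cat == "Intron-teM"]
    splits: list[IntronSplitCounts] = []
    dep_mddcc = tem_genes[: config.tem3_n_depleted_mddcc]
    dep_met1 = tem_genes[
        config.tem3_n_depleted_mddcc : config.tem3_n_depleted_mddcc + config.tem3_n_depleted_met1
    ]
    low5 = tem_genes[
        config.tem3_n_depleted_mddcc
        + config.tem3_n_depleted_met1 : config.tem3_n_depleted_mddcc
        + config.tem3_n_depleted_met1
        + config.tem3_n_low_wt5
    ]
    gene_by_id = {g.gene_id: g for g in genes}
    for gid in tem_genes:
        gene = gene_by_id[gid]
        intron = gene.introns[0] if gene.introns else (gene.start, gene.end)
        sp = IntronSplitCounts(gene_id=gid, split_intron=intron)
        mean5 = 1.0 if gid in low5 else config.tem3_part_mean
        for genotype in GENOTYPES:
            factor = 1.0
            if gid in dep_mddcc and genotype == "mddcc":
                factor = config.tem3_depletion_factor
            if gid in dep_met1 and genotype == "met1":
                factor = config.tem3_depletion_factor
            c5 = int(
                _nb_draws(rng, mean5 * config.n_replicates, config.dispersion / config.n_replicates, (1,))[0]
            )
            c3 = int(
                _nb_draws(
                    rng,
                    config.tem3_part_mean * config.n_replicates / factor,
                    config.dispersion / config.n_replicates,
                    (1,),
                )[0]
            )
            sp.counts_5prime[genotype] = c5
            sp.counts_3prime[genotype] = c3
        splits.append(sp)
        if gid in dep_mddcc:
            truth.tem3_depleted[gid] = {"mddcc": config.tem3_depletion_factor}
        if gid in dep_met1:
            truth.tem3_depleted[gid] = {"met1": config.tem3_depletion_factor}
    truth.tem3_low_wt5 = low5

    return {
        "counts": out_counts,
        "design": design,
        "gene_lengths": gene_lengths,
        "intron_splits": splits,
    }


# ---------------------------------------------------------------------------
# Insertion read sets


_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_MATE_UNMAPPED = 0x8
_FLAG_REVERSE = 0x10
_FLAG_MATE_REVERSE = 0x20
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80

from .genome import revcomp  # noqa: E402  (local helper reuse)


def _sam_line(name, flag, chrom, pos, mapq, cigar, rnext, pnext, tlen, seq):
    return f"{name}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t{rnext}\t{pnext}\t{tlen}\t{seq}\t*"


def simulate_insertion_readset(
    genome: GenomeSequence,
    tes: list[TEAnnotation],
    truth: TruthSet,
    config: SimulationConfig,
    sam_path=None,
) -> list[str]:
    """Paired-end reads over planted TE insertions, as SAM text lines.

    For each planted insertion the mutant haplotype duplicates the TSD
    around an inserted copy of the donor TE; junction-spanning reads are
    emitted unmapped (sequence retained) with a properly mapped genomic
    mate nearby, plus uniform background proper pairs. Writes to
    ``sam_path`` when given and returns the lines.
    """
    rng = np.random.default_rng([config.seed, 4])
    rl = config.read_len
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        *[f"@SQ\tSN:{c}\tLN:{genome.length(c)}" for c in genome.chrom_names],
    ]
    records = []
    resolved = getattr(truth, "_resolved_insertions", [])
    for idx, (ins, te, target) in enumerate(resolved):
        te_seq = genome.fetch(te.chrom, te.start, te.end)
        tsd_end = target + ins.tsd_len - 1
        chrom = "Chr1"
        # left junction: ...ref[tsd_end] | TE[0.. ; right junction: TE..-1] | ref[target]...
        for side, n_reads in (("5p", ins.n_reads_5prime), ("3p", ins.n_reads_3prime)):
            for r in range(n_reads):
                g = int(rng.integers(25, rl - 25))  # genomic portion length
                name = f"ins{idx}_{side}_{r}"
                if side == "5p":
                    flank = genome.fetch(chrom, tsd_end - g + 1, tsd_end)
                    jread = flank + te_seq[: rl - g]
                    mate_pos = max(1, tsd_end - g - config.pair_gap - rl + 1)
                    mate_seq = genome.fetch(chrom, mate_pos, mate_pos + rl - 1)
                    # junction read is the reverse member; mate maps forward upstream
                    records.append(
                        _sam_line(
                            name,
                            _FLAG_PAIRED | _FLAG_READ1 | _FLAG_UNMAPPED,
                            "*",
                            0,
                            0,
                            "*",
                            chrom,
                            mate_pos,
                            0,
                            revcomp(jread),
                        )
                    )
                    records.append(
                        _sam_line(
                            name,
                            _FLAG_PAIRED | _FLAG_READ2 | _FLAG_MATE_UNMAPPED,
                            chrom,
                            mate_pos,
                            60,
                            f"{rl}M",
                            "*",
                            0,
                            0,
                            mate_seq,
                        )
                    )
                else:
                    flank = genome.fetch(chrom, target, target + g - 1)
                    jread = te_seq[-(rl - g) :] + flank
                    mate_pos = min(genome.length(chrom) - rl + 1, target + g + config.pair_gap)
                    mate_seq = genome.fetch(chrom, mate_pos, mate_pos + rl - 1)
                    # junction read is the forward member; mate maps reverse downstream
                    records.append(
                        _sam_line(
                            name,
                            _FLAG_PAIRED | _FLAG_READ1 | _FLAG_UNMAPPED | _FLAG_MATE_REVERSE,
                            "*",
                            0,
                            0,
                            "*",
                            chrom,
                            mate_pos,
                            0,
                            jread,
                        )
                    )
                    records.append(
                        _sam_line(
                            name,
                            _FLAG_PAIRED | _FLAG_READ2 | _FLAG_MATE_UNMAPPED | _FLAG_REVERSE,
                            chrom,
                            mate_pos,
                            60,
                            f"{rl}M",
                            "*",
                            0,
                            0,
                            revcomp(mate_seq),
                        )
                    )

    # background proper pairs on the reference
    for b in range(config.n_background_pairs):
        chrom = "Chr1"
        span = 2 * rl + config.pair_gap
        p1 = int(rng.integers(1, genome.length(chrom) - span))
        p2 = p1 + rl + config.pair_gap
        name = f"bg{b}"
        s1 = genome.fetch(chrom, p1, p1 + rl - 1)
        s2 = genome.fetch(chrom, p2, p2 + rl - 1)
        records.append(
            _sam_line(
                name,
                _FLAG_PAIRED | _FLAG_PROPER | _FLAG_READ1 | _FLAG_MATE_REVERSE,
                chrom,
                p1,
                60,
                f"{rl}M",
                "=",
                p2,
                span,
                s1,
            )
        )
        records.append(
            _sam_line(
                name,
                _FLAG_PAIRED | _FLAG_PROPER | _FLAG_READ2 | _FLAG_REVERSE,
                chrom,
                p2,
                60,
                f"{rl}M",
                "=",
                p1,
                -span,
                revcomp(s2),
            )
        )
    lines.extend(records)
    if sam_path is not None:
        with open(sam_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    return lines
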