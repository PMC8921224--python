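"""Gene methylation-category classification by one-tailed binomial tests.

Every expressed gene is assigned to exactly one of six categories from the
wild-type methylome:

* ``gbM``        — gene-body methylation in the CG context only;
* ``Intron-teM`` — TE-like body methylation (CHG/CHH) restricted to introns;
* ``Other-teM``  — TE-like body methylation elsewhere in the body;
* ``pM``         — methylation concentrated in the 2-kb promoter (best 500-bp bin);
* ``dM``         — methylation in the 2-kb downstream region with an
  unmethylated promoter;
* ``UM``         — no significant methylation anywhere tested.

Each region/context pair is tested for enrichment of methylated calls
against the background level pooled over that region class across all
genes, with a one-tailed binomial test; p-values are Benjamini–Hochberg
adjusted within one family per (region class, context) and thresholded at
q < 0.01. For promoter and downstream regions the 500-bp bin with the
maximum pooled-context methylation level is the tested unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GeneModel, GeneRegions
from .methylome import CONTEXTS, CTX_CODE, MethylomeTable

CATEGORIES = ("gbM", "Intron-teM", "Other-teM", "pM", "dM", "UM")

#: clamp for degenerate background estimates
P_BG_MIN = 1e-6


@dataclass(frozen=True)
class RegionCounts:
    gene_id: str
    region_class: str  # body | body_exon | body_intron | promoter_bin | downstream_bin
    context: str  # CG | CHG | CHH | C
    k: int
    n: int

    @property
    def level(self) -> float | None:
        return self.k / self.n if self.n else None


def binomial_tail_p(k: int, n: int, p_bg: float) -> float:
    """Upper-tail binomial probability P(X >= k), X ~ Binomial(n, p_bg).

    The untestable case n = 0 (hence k = 0) returns 1.0: absence of
    informative coverage is read as absence of evidence for methylation.
    """
    if not 0 < p_bg < 1:
        raise ValueError("p_bg must lie strictly in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p_bg))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Count aggregation


def _context_counts(table: MethylomeTable, chrom: str, intervals) -> dict[str, tuple[int, int]]:
    """(k, n) per context plus pooled 'C' over a list of intervals."""
    arr = table.chrom_arrays(chrom)
    pos, ctx, c, ct = arr["pos"], arr["ctx"], arr["c"], arr["ct"]
    k = {ctxname: 0 for ctxname in CONTEXTS}
    n = {ctxname: 0 for ctxname in CONTEXTS}
    for start, end in intervals:
        lo = np.searchsorted(pos, start, "left")
        hi = np.searchsorted(pos, end, "right")
        if lo == hi:
            continue
        sl_ctx = ctx[lo:hi]
        sl_c = c[lo:hi]
        sl_ct = ct[lo:hi]
        for name, code in CTX_CODE.items():
            m = sl_ctx == code
            k[name] += int(sl_c[m].sum())
            n[name] += int(sl_ct[m].sum())
    out = {name: (k[name], n[name]) for name in CONTEXTS}
    out["C"] = (sum(k.values()), sum(n.values()))
    return out


def aggregate_region_counts(
    table: MethylomeTable, regions: GeneRegions, gene: GeneModel
) -> list[RegionCounts]:
    """Per-gene methylation counts for every tested region class.

    Emits per-context body, exon-only and intron-only counts, and per
    500-bp promoter/downstream bin both pooled-context ('C') and
    per-context counts. Bins keep their gene-proximal-first order via the
    region_class suffix ``promoter_bin``/``downstream_bin`` plus list
    position (callers that need bin identity use :func:`gene_count_frame`).
    """
    out: list[RegionCounts] = []
    body = _context_counts(table, gene.chrom, [regions.body])
    exon = _context_counts(table, gene.chrom, gene.exons)
    intron = _context_counts(table, gene.chrom, gene.introns)
    for ctxname in CONTEXTS + ("C",):
        out.append(RegionCounts(gene.gene_id, "body", ctxname, *body[ctxname]))
        out.append(RegionCounts(gene.gene_id, "body_exon", ctxname, *exon[ctxname]))
        out.append(RegionCounts(gene.gene_id, "body_intron", ctxname, *intron[ctxname]))
    for cls, bins in (("promoter_bin", regions.promoter_bins), ("downstream_bin", regions.downstream_bins)):
        for b in bins:
            counts = _context_counts(table, gene.chrom, [b])
            for ctxname in CONTEXTS + ("C",):
                out.append(RegionCounts(gene.gene_id, cls, ctxname, *counts[ctxname]))
    return out


def select_max_bin(bins: list[RegionCounts]) -> RegionCounts:
    """Bin with the maximum pooled-context methylation level.

    Bins with n = 0 rank lowest; ties go to the gene-proximal (earlier)
    bin. With every bin uncovered a sentinel zero-count bin is returned,
    which downstream tests read as p = 1.
    """
    if not bins:
        raise ValueError("no bins supplied")
    best = None
    best_level = -1.0
    for b in bins:
        level = b.level if b.n else -1.0
        if level > best_level:
            best, best_level = b, level
    if best is None or best.n == 0:
        return RegionCounts(bins[0].gene_id, bins[0].region_class, "C", 0, 0)
    return best


# ---------------------------------------------------------------------------
# Whole-cohort machinery (vectorised across genes)


def gene_count_frame(
    table: MethylomeTable, genes: list[GeneModel], regions_by_gene: dict[str, GeneRegions]
) -> pd.DataFrame:
    """Long-format counts for all genes: one row per (gene, region, context, bin)."""
    rows = []
    for gene in genes:
        regions = regions_by_gene[gene.gene_id]
        body = _context_counts(table, gene.chrom, [regions.body])
        exon = _context_counts(table, gene.chrom, gene.exons)
        intron = _context_counts(table, gene.chrom, gene.introns)
        for ctxname in CONTEXTS + ("C",):
            rows.append((gene.gene_id, "body", -1, ctxname, *body[ctxname]))
            rows.append((gene.gene_id, "body_exon", -1, ctxname, *exon[ctxname]))
            rows.append((gene.gene_id, "body_intron", -1, ctxname, *intron[ctxname]))
        for cls, bins in (
            ("promoter_bin", regions.promoter_bins),
            ("downstream_bin", regions.downstream_bins),
        ):
            for i, b in enumerate(bins):
                counts = _context_counts(table, gene.chrom, [b])
                for ctxname in ("C",) + CONTEXTS:
                    rows.append((gene.gene_id, cls, i, ctxname, *counts[ctxname]))
    return pd.DataFrame(rows, columns=["gene_id", "region_class", "bin", "context", "k", "n"])


def compute_backgrounds(counts: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Background methylation level per (region class, context).

    Pools counts over the whole region class across all genes — body counts
    for the body background, all promoter bins for the promoter background,
    all downstream bins for the downstream background — and clamps the
    result into [1e-6, 1 - 1e-6] so degenerate all-zero backgrounds remain
    testable. Raises on a region class without any informative coverage.
    """
    out: dict[tuple[str, str], float] = {}
    class_map = {"body": ["body"], "promoter": ["promoter_bin"], "downstream": ["downstream_bin"]}
    for region_class, classes in class_map.items():
        sub = counts[counts["region_class"].isin(classes)]
        for ctxname in CONTEXTS + ("C",):
            s = sub[sub["context"] == ctxname]
            n = int(s["n"].sum())
            if n == 0:
                raise ValueError(f"no coverage to estimate background for {region_class}/{ctxname}")
            level = float(s["k"].sum()) / n
            out[(region_class, ctxname)] = float(np.clip(level, P_BG_MIN, 1 - P_BG_MIN))
    return out


def _family_test(sub: pd.DataFrame, p_bg: float) -> pd.DataFrame:
    """One-tailed binomial p and BH q for one (region class, context) family."""
    k = sub["k"].to_numpy(np.int64)
    n = sub["n"].to_numpy(np.int64)
    p = np.ones(len(sub))
    nz = n > 0
    p[nz] = stats.binom.sf(k[nz] - 1, n[nz], p_bg)
    p[nz & (k == 0)] = 1.0
    out = sub.copy()
    out["p_bg"] = p_bg
    out["p_value"] = p
    out["q_value"] = bh_adjust(p)
    return out


def classify_genes(
    expressed_gene_ids,
    table: MethylomeTable,
    genes: list[GeneModel],
    regions_by_gene: dict[str, GeneRegions],
    q_threshold: float = 0.01,
    intron_rule: str = "intron_only",
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign every expressed gene to one of the six methylation categories.

    Parameters
    ----------
    expressed_gene_ids:
        Genes passing the expression filter; BH families span exactly this
        set (one family per region class and context).
    intron_rule:
        ``intron_only`` (default): a teM gene is Intron-teM when its
        intron-restricted CHG or CHH counts are significant. The
        alternative ``intron_not_exon`` additionally requires the
        exon-restricted counts to be non-significant.

    Returns a DataFrame indexed by gene_id with the category and the
    supporting q-values.
    """
    if intron_rule not in ("intron_only", "intron_not_exon"):
        raise ValueError(f"unknown intron_rule {intron_rule!r}")
    expressed = [g for g in genes if g.gene_id in set(expressed_gene_ids)]
    missing = set(expressed_gene_ids) - {g.gene_id for g in genes}
    if missing:
        raise ValueError(f"expressed genes without models/regions: {sorted(missing)[:5]}")
    if counts is None:
        counts = gene_count_frame(table, expressed, regions_by_gene)
    else:
        counts = counts[counts["gene_id"].isin({g.gene_id for g in expressed})]
    backgrounds = compute_backgrounds(counts)

    # max-level bin per gene for promoter and downstream (pooled C context)
    tested = []
    for cls, bg_cls in (("promoter_bin", "promoter"), ("downstream_bin", "downstream")):
        sub = counts[(counts["region_class"] == cls) & (counts["context"] == "C")].copy()
        level = np.where(sub["n"] > 0, sub["k"] / sub["n"].replace(0, 1), -1.0)
        sub["level_rank"] = level
        # stable sort keeps gene-proximal bin first among ties
        best = (
            sub.sort_values(["gene_id", "level_rank"], kind="mergesort", ascending=[True, False])
            .groupby("gene_id", sort=False)
            .head(1)
            .copy()
        )
        best["region_class"] = bg_cls + "_max_bin"
        tested.append(_family_test(best, backgrounds[(bg_cls, "C")]))

    for cls in ("body", "body_exon", "body_intron"):
        for ctxname in CONTEXTS:
            sub = counts[(counts["region_class"] == cls) & (counts["context"] == ctxname)]
            tested.append(_family_test(sub, backgrounds[("body", ctxname)]))

    tests = pd.concat(tested, ignore_index=True)

    def qmap(cls, ctxname):
        s = tests[(tests["region_class"] == cls) & (tests["context"] == ctxname)]
        return s.set_index("gene_id")["q_value"]

    q = pd.DataFrame(
        {
            "q_body_CG": qmap("body", "CG"),
            "q_body_CHG": qmap("body", "CHG"),
            "q_body_CHH": qmap("body", "CHH"),
            "q_exon_CHG": qmap("body_exon", "CHG"),
            "q_exon_CHH": qmap("body_exon", "CHH"),
            "q_intron_CHG": qmap("body_intron", "CHG"),
            "q_intron_CHH": qmap("body_intron", "CHH"),
            "q_promoter_C": qmap("promoter_max_bin", "C"),
            "q_downstream_C": qmap("downstream_max_bin", "C"),
        }
    )

    t = q_threshold
    tem = (q["q_body_CHG"] < t) | (q["q_body_CHH"] < t)
    intron_sig = (q["q_intron_CHG"] < t) | (q["q_intron_CHH"] < t)
    if intron_rule == "intron_not_exon":
        exon_sig = (q["q_exon_CHG"] < t) | (q["q_exon_CHH"] < t)
        intron_sig = intron_sig & ~exon_sig
    gbm = (q["q_body_CG"] < t) & (q["q_body_CHG"] >= t) & (q["q_body_CHH"] >= t)
    pm = q["q_promoter_C"] < t
    dm = (q["q_downstream_C"] < t) & (q["q_promoter_C"] >= t)

    category = pd.Series("UM", index=q.index, name="category")
    category[dm] = "dM"
    category[pm] = "pM"
    category[gbm & ~tem] = "gbM"
    category[tem & ~intron_sig] = "Other-teM"
    category[tem & intron_sig] = "Intron-teM"
    out = q.copy()
    out.insert(0, "category", category)
    out.attrs["backgrounds"] = backgrounds
    out.attrs["tests"] = tests
    return out


def category_summary(classified: pd.DataFrame) -> dict:
    """Category counts and proportions (teM reported split and combined)."""
    counts = classified["category"].value_counts().to_dict()
    total = int(len(classified))
    full = {cat: int(counts.get(cat, 0)) for cat in CATEGORIES}
    full["teM"] = full["Intron-teM"] + full["Other-teM"]
    return {
        "total": total,
        "counts": full,
        "proportions": {cat: (full[cat] / total if total else 0.0) for cat in full},
    }


def category_percentages(counts: dict[str, int], decimals: int = 1) -> dict[str, float]:
    """Percentages (rounded to the printed precision) from category counts."""
    total = sum(counts.values())
    return {cat: round(100.0 * n / total, decimals) for cat, n in counts.items()}
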