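"""Per-cytosine bisulfite methylome: contexts, coverage filter, weighted levels.

Plant methylomes are summarised in three sequence contexts — CG, CHG and CHH
(H = A, C or T) — each maintained by a distinct pathway. This module assigns
the context of every genomic cytosine from the reference sequence, parses
methratio-style per-cytosine tables (methylated-call count and effective
C+T coverage per position), applies the minimum-coverage filter, and
computes *weighted* methylation levels: sum of methylated calls over sum of
informative calls in a region, never a mean of per-site ratios. The
unmethylated organelle (chloroplast-like) chromosome provides the bisulfite
non-conversion estimate against which a methylation-free nuclear genome can
be compared.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import GenomeSequence, Interval

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
#: integer codes used internally; 0 = not an assignable cytosine
CTX_CODE = {"CG": 1, "CHG": 2, "CHH": 3}
CODE_CTX = {v: k for k, v in CTX_CODE.items()}

_A, _C, _G, _T, _N = 65, 67, 71, 84, 78


class MethratioParseError(ValueError):
    pass


class ContextMap:
    """Context assignment for every genomic cytosine on both strands.

    Backed by one int8 array per (chromosome, strand); 0 marks positions
    that are not cytosines or whose context is undeterminable (N neighbour
    or chromosome end).
    """

    def __init__(self, plus: dict[str, np.ndarray], minus: dict[str, np.ndarray]):
        self._arr = {"+": plus, "-": minus}

    def context(self, chrom: str, pos: int, strand: str) -> str | None:
        """Context at a 1-based position, or None if unassignable."""
        code = int(self._arr[strand][chrom][pos - 1])
        return CODE_CTX.get(code)

    def codes(self, chrom: str, strand: str) -> np.ndarray:
        return self._arr[strand][chrom]

    def sites(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All assignable cytosines of one chromosome.

        Returns (pos, strand_code, context_code) with pos 1-based and
        strand_code 0 for '+', 1 for '-', ordered by (pos, strand).
        """
        plus = self._arr["+"][chrom]
        minus = self._arr["-"][chrom]
        pp = np.nonzero(plus)[0]
        mp = np.nonzero(minus)[0]
        pos = np.concatenate([pp, mp]) + 1
        strand = np.concatenate([np.zeros(len(pp), np.int8), np.ones(len(mp), np.int8)])
        ctx = np.concatenate([plus[pp], minus[mp]])
        order = np.lexsort((strand, pos))
        return pos[order].astype(np.int64), strand[order], ctx[order]


def annotate_contexts(genome: GenomeSequence) -> ContextMap:
    """Assign CG/CHG/CHH to every unambiguous cytosine on both strands."""
    plus, minus = {}, {}
    for chrom in genome.chrom_names:
        b = np.frombuffer(genome.seq(chrom).encode(), dtype=np.uint8)
        L = len(b)
        n1 = np.full(L, _N, np.uint8)  # base at i+1
        n2 = np.full(L, _N, np.uint8)  # base at i+2
        if L > 1:
            n1[:-1] = b[1:]
        if L > 2:
            n2[:-2] = b[2:]
        p1 = np.full(L, _N, np.uint8)  # base at i-1
        p2 = np.full(L, _N, np.uint8)  # base at i-2
        if L > 1:
            p1[1:] = b[:-1]
        if L > 2:
            p2[2:] = b[:-2]

        def is_h(x):
            return (x == _A) | (x == _C) | (x == _T)

        ctx_p = np.zeros(L, np.int8)
        is_c = b == _C
        ctx_p[is_c & (n1 == _G)] = 1
        ctx_p[is_c & is_h(n1) & (n2 == _G)] = 2
        ctx_p[is_c & is_h(n1) & is_h(n2)] = 3

        # minus-strand cytosines sit at G positions; neighbours read 3'->5'
        # on the forward strand, complemented.
        ctx_m = np.zeros(L, np.int8)
        is_g = b == _G
        mh1 = (p1 == _A) | (p1 == _G) | (p1 == _T)  # complement is H
        mh2 = (p2 == _A) | (p2 == _G) | (p2 == _T)
        ctx_m[is_g & (p1 == _C)] = 1
        ctx_m[is_g & mh1 & (p2 == _C)] = 2
        ctx_m[is_g & mh1 & mh2] = 3

        plus[chrom] = ctx_p
        minus[chrom] = ctx_m
    return ContextMap(plus, minus)


class MethylomeTable:
    """Indexed per-cytosine methylation records for one sample.

    Wraps a DataFrame with columns chrom, pos (1-based), strand, context,
    c_count, ct_count, kept sorted by (chrom, pos, strand); at most one
    record per (chrom, pos, strand).
    """

    def __init__(self, df: pd.DataFrame, sample: str = "", genotype: str = ""):
        required = ["chrom", "pos", "strand", "context", "c_count", "ct_count"]
        df = df[required].copy()
        if (df["c_count"] > df["ct_count"]).any():
            raise ValueError("c_count exceeds ct_count")
        dup = df.duplicated(subset=["chrom", "pos", "strand"])
        if dup.any():
            logger.warning("dropping %d duplicate cytosine records", int(dup.sum()))
            df = df[~dup]
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self.sample = sample
        self.genotype = genotype
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.df)

    def chrom_arrays(self, chrom: str) -> dict[str, np.ndarray]:
        """Position-sorted numpy views for one chromosome (cached)."""
        if chrom not in self._by_chrom:
            sub = self.df[self.df["chrom"] == chrom]
            self._by_chrom[chrom] = {
                "pos": sub["pos"].to_numpy(np.int64),
                "ctx": sub["context"].map(CTX_CODE).to_numpy(np.int8),
                "c": sub["c_count"].to_numpy(np.int64),
                "ct": sub["ct_count"].to_numpy(np.int64),
            }
        return self._by_chrom[chrom]

    def query(self, chrom: str, start: int, end: int, context: str | None = None) -> pd.DataFrame:
        """Records with start <= pos <= end, optionally restricted to one context."""
        arr = self.chrom_arrays(chrom)
        lo = np.searchsorted(arr["pos"], start, "left")
        hi = np.searchsorted(arr["pos"], end, "right")
        sub = self.df[self.df["chrom"] == chrom].iloc[lo:hi]
        if context is not None and context != "C":
            sub = sub[sub["context"] == context]
        return sub

    def region_counts(self, chrom: str, start: int, end: int, context: str = "C") -> tuple[int, int]:
        """(sum c_count, sum ct_count) over a region and context ('C' pools all)."""
        arr = self.chrom_arrays(chrom)
        lo = np.searchsorted(arr["pos"], start, "left")
        hi = np.searchsorted(arr["pos"], end, "right")
        if context == "C":
            return int(arr["c"][lo:hi].sum()), int(arr["ct"][lo:hi].sum())
        code = CTX_CODE[context]
        m = arr["ctx"][lo:hi] == code
        return int(arr["c"][lo:hi][m].sum()), int(arr["ct"][lo:hi][m].sum())


def read_methratio(path, context_map: ContextMap, sample: str = "", genotype: str = "") -> MethylomeTable:
    """Read a methratio-style TSV (chrom, pos, strand, context, ratio,
    eff_CT, C; header line present) and validate it against the genome.

    Records whose stated context disagrees with the genome-derived context
    (or that sit at unassignable positions) are dropped with a logged count.
    Count-field violations raise :class:`MethratioParseError` with the line
    number.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=0,
        names=["chrom", "pos", "strand", "context", "ratio", "eff_CT", "C"],
        dtype={"chrom": str, "strand": str, "context": str},
    )
    if df.empty:
        return MethylomeTable(
            pd.DataFrame(columns=["chrom", "pos", "strand", "context", "c_count", "ct_count"]),
            sample=sample,
            genotype=genotype,
        )
    for col in ("pos", "eff_CT", "C"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            line = int(numeric.index[numeric.isna()][0]) + 2  # header is line 1
            raise MethratioParseError(f"{path}:{line}: non-numeric {col!r} field")
        df[col] = numeric.astype(np.int64)
    bad = df["C"] > df["eff_CT"]
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise MethratioParseError(f"{path}:{line}: C count exceeds effective C+T count")

    expected = np.zeros(len(df), np.int8)
    for (chrom, strand), idx in df.groupby(["chrom", "strand"]).indices.items():
        codes = context_map.codes(chrom, strand)
        p = df["pos"].to_numpy(np.int64)[idx]
        if p.min() < 1 or p.max() > len(codes):
            line = int(df.index[idx[(p < 1) | (p > len(codes))][0]]) + 2
            raise MethratioParseError(f"{path}:{line}: position outside chromosome")
        expected[idx] = codes[p - 1]
    stated = df["context"].map(CTX_CODE).fillna(-1).to_numpy(np.int8)
    ok = (expected == stated) & (expected > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: dropped %d records with genome-inconsistent context", path, n_bad)
    df = df[ok]
    out = df.rename(columns={"C": "c_count", "eff_CT": "ct_count"})
    return MethylomeTable(
        out[["chrom", "pos", "strand", "context", "c_count", "ct_count"]],
        sample=sample,
        genotype=genotype,
    )


def filter_coverage(table: MethylomeTable, min_cov: int = 4) -> MethylomeTable:
    """Retain cytosine positions with effective coverage >= min_cov."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    return MethylomeTable(
        table.df[table.df["ct_count"] >= min_cov], sample=table.sample, genotype=table.genotype
    )


def weighted_level(
    table: MethylomeTable, region: tuple[str, int, int], context: str = "C"
) -> float | None:
    """Weighted methylation level over one region: sum C / sum (C+T).

    Returns None (undefined) when the region holds no informative calls;
    missingness is propagated, never collapsed to 0.
    """
    chrom, start, end = region
    c, ct = table.region_counts(chrom, start, end, context)
    if ct == 0:
        return None
    return c / ct


def pooled_level(table: MethylomeTable, regions, context: str = "C") -> float | None:
    """Pooled-count level over several regions (count-weighted, not a mean)."""
    c_tot = ct_tot = 0
    for chrom, start, end in regions:
        c, ct = table.region_counts(chrom, start, end, context)
        c_tot += c
        ct_tot += ct
    if ct_tot == 0:
        return None
    return c_tot / ct_tot


def window_profile(
    table: MethylomeTable,
    genome: GenomeSequence,
    window_bp: int,
    step_bp: int,
    context: str = "C",
) -> pd.DataFrame:
    """Weighted level in windows tiled across every chromosome.

    Returns a DataFrame (chrom, start, end, level) with NaN for windows
    holding no informative calls.
    """
    if not (window_bp >= step_bp >= 1):
        raise ValueError("require window_bp >= step_bp >= 1")
    rows = []
    for chrom in genome.chrom_names:
        L = genome.length(chrom)
        arr = table.chrom_arrays(chrom)
        pos, c, ct = arr["pos"], arr["c"], arr["ct"]
        if context != "C":
            m = arr["ctx"] == CTX_CODE[context]
            pos, c, ct = pos[m], c[m], ct[m]
        csum_c = np.concatenate([[0], np.cumsum(c)])
        csum_ct = np.concatenate([[0], np.cumsum(ct)])
        for start in range(1, L + 1, step_bp):
            end = min(L, start + window_bp - 1)
            lo = np.searchsorted(pos, start, "left")
            hi = np.searchsorted(pos, end, "right")
            ct_w = csum_ct[hi] - csum_ct[lo]
            level = (csum_c[hi] - csum_c[lo]) / ct_w if ct_w > 0 else np.nan
            rows.append((chrom, start, end, level))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "level"])


def estimate_nonconversion(table: MethylomeTable, genome: GenomeSequence) -> float:
    """Bisulfite non-conversion rate from the organelle control chromosomes.

    The organelle genome carries no DNA methylation, so its pooled
    all-context weighted level estimates the rate at which unmethylated
    cytosines escape conversion.
    """
    if not genome.organelle_flags:
        raise ValueError("genome has no organelle-flagged chromosome")
    regions = [(c, 1, genome.length(c)) for c in sorted(genome.organelle_flags)]
    rate = pooled_level(table, regions, context="C")
    if rate is None:
        raise ValueError("no methylation records on organelle chromosomes")
    return rate


def context_level_summary(table: MethylomeTable, genome: GenomeSequence) -> dict:
    """Per-context weighted levels for nuclear vs organelle chromosomes."""
    nuclear = [(c, 1, genome.length(c)) for c in genome.nuclear_chroms]
    organelle = [(c, 1, genome.length(c)) for c in sorted(genome.organelle_flags)]
    out: dict[str, dict] = {"nuclear": {}, "organelle": {}}
    for ctx in CONTEXTS + ("C",):
        out["nuclear"][ctx] = pooled_level(table, nuclear, ctx)
        if organelle:
            out["organelle"][ctx] = pooled_level(table, organelle, ctx)
    return out


def write_bedgraph(profile: pd.DataFrame, path) -> None:
    """Write a window profile as bedGraph (0-based half-open; 4 decimals);
    undefined windows are omitted."""
    with open(path, "w") as fh:
        for row in profile.itertuples(index=False):
            if pd.isna(row.level):
                continue
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.level:.4f}\n")


def write_methratio(table: MethylomeTable, path) -> None:
    """Write a table back to the methratio TSV dialect."""
    df = table.df
    with open(path, "w") as fh:
        fh.write("chr\tpos\tstrand\tcontext\tratio\teff_CT_count\tC_count\n")
        for row in df.itertuples(index=False):
            ratio = row.c_count / row.ct_count if row.ct_count else 0.0
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.strand}\t{row.context}\t"
                f"{ratio:.4f}\t{row.ct_count}\t{row.c_count}\n"
            )
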