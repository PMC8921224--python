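"""Genome sequence and annotation model.

All coordinates in the data model are 1-based inclusive, matching the GFF3
and methratio dialects this package consumes; any half-open arithmetic is
internal and converted at I/O boundaries (BED/bedGraph writers).

The model deliberately carries only what the downstream analyses need:
chromosome sequences (with a flag marking organelle/control chromosomes such
as the chloroplast, which is devoid of DNA methylation), gene models with
exon/intron structure, transposable-element annotations, and the chromosome
mask (centromere spans, N-runs, end margins) used to filter TE insertion
calls.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger(__name__)

Interval = tuple[int, int]  # 1-based inclusive


class FastaParseError(ValueError):
    """Raised for malformed FASTA records (empty sequence, bad header)."""


class AnnotationError(ValueError):
    """Raised for inconsistent GFF3 annotation."""


_NON_ACGTN = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """Ordered collection of uppercase chromosome sequences.

    Parameters
    ----------
    sequences:
        Mapping chromosome name -> sequence (insertion order preserved).
    organelle_flags:
        Chromosome names designated as unmethylated organelle controls
        (chloroplast-like). Used for the bisulfite non-conversion estimate.
    """

    def __init__(self, sequences: dict[str, str], organelle_flags=()):
        if not sequences:
            raise FastaParseError("genome contains no sequences")
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = _NON_ACGTN.sub("N", seq.upper())
            if not seq:
                raise FastaParseError(f"empty sequence for record {name!r}")
            self._seqs[name] = seq
        unknown = set(organelle_flags) - set(self._seqs)
        if unknown:
            logger.warning("organelle flags for absent chromosomes ignored: %s", sorted(unknown))
        self.organelle_flags = frozenset(organelle_flags) & set(self._seqs)

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    @property
    def nuclear_chroms(self) -> list[str]:
        return [c for c in self._seqs if c not in self.organelle_flags]

    def seq(self, chrom: str) -> str:
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive [start, end]."""
        if start < 1 or end > len(self._seqs[chrom]) or start > end:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        return self._seqs[chrom][start - 1 : end]

    def find_all(self, pattern: str) -> list[tuple[str, int, int, str]]:
        """Exact occurrences of ``pattern`` on either strand.

        Returns (chrom, start, end, strand) with 1-based inclusive
        coordinates on the forward strand; strand '-' means the reverse
        complement of the pattern occurs at that forward-strand interval.
        A palindromic hit is reported once per strand.
        """
        hits = []
        rc = revcomp(pattern)
        for chrom, seq in self._seqs.items():
            for query, strand in ((pattern, "+"), (rc, "-")):
                if strand == "-" and rc == pattern:
                    continue
                i = seq.find(query)
                while i != -1:
                    hits.append((chrom, i + 1, i + len(query), strand))
                    i = seq.find(query, i + 1)
        return hits


@dataclass(frozen=True)
class GeneModel:
    """Gene with exon/intron structure; introns are the within-span complement."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[Interval, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        exons = tuple(sorted(self.exons))
        prev_end = self.start - 1
        for s, e in exons:
            if s > e or s < self.start or e > self.end:
                raise AnnotationError(f"{self.gene_id}: exon {s}-{e} outside span {self.start}-{self.end}")
            if s <= prev_end:
                raise AnnotationError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        if not exons or exons[0][0] != self.start or exons[-1][1] != self.end:
            raise AnnotationError(f"{self.gene_id}: exons do not reach gene span boundaries")
        object.__setattr__(self, "exons", exons)

    @property
    def introns(self) -> tuple[Interval, ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @property
    def span(self) -> Interval:
        return (self.start, self.end)


@dataclass(frozen=True)
class TEAnnotation:
    te_id: str
    family: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if not self.family:
            raise AnnotationError(f"{self.te_id}: empty family")
        if self.start > self.end:
            raise AnnotationError(f"{self.te_id}: bad span")

    @property
    def span(self) -> Interval:
        return (self.start, self.end)


@dataclass
class GeneRegions:
    """Analysis regions derived from a gene: body, 2-kb promoter and 2-kb
    downstream regions (strand-aware, clipped at chromosome edges), and the
    500-bp bins tiling promoter/downstream from the gene-proximal edge
    outward."""

    gene_id: str
    chrom: str
    strand: str
    body: Interval
    promoter: Interval | None
    downstream: Interval | None
    promoter_bins: list[Interval] = field(default_factory=list)
    downstream_bins: list[Interval] = field(default_factory=list)


@dataclass
class ChromosomeMask:
    """Regions excluded from TE insertion calling."""

    centromere_spans: dict[str, list[Interval]] = field(default_factory=dict)
    n_run_spans: dict[str, list[Interval]] = field(default_factory=dict)
    chrom_end_margin: int = 3000


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path, organelle_flags=()) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased and non-ACGTN characters mapped to N; record
    order is preserved. Raises :class:`FastaParseError` naming the record on
    an empty sequence.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"record without identifier in {path}")
        if rec.id in seqs:
            raise FastaParseError(f"duplicate record {rec.id!r} in {path}")
        seq = str(rec.seq)
        if not seq:
            raise FastaParseError(f"empty sequence for record {rec.id!r}")
        seqs[rec.id] = seq
    return GenomeSequence(seqs, organelle_flags=organelle_flags)


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome.seq(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise AnnotationError(f"malformed GFF3 attribute {part!r}")
        key, val = part.split("=", 1)
        out[key] = val
    return out


_TE_TYPES = {"transposable_element", "transposon", "TE"}


def read_gff3(path, genome: GenomeSequence | None = None):
    """Parse gene/exon and transposable-element features from GFF3.

    Exons may point at the gene directly or through an mRNA feature; exons
    of multiple transcripts are merged into their union (overlapping union
    intervals are coalesced), matching the union-exon length convention used
    for FPKM. Returns ``(genes, tes)``.
    """
    raw_genes: dict[str, tuple[str, str, int, int]] = {}
    mrna_parent: dict[str, str] = {}
    exons: dict[str, list[Interval]] = {}
    tes: list[TEAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attr = fields
            start, end = int(start), int(end)
            if genome is not None and chrom not in genome.chrom_names:
                raise AnnotationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            attrs = _parse_attributes(attr)
            if ftype == "gene":
                if "ID" not in attrs:
                    raise AnnotationError(f"{path}:{lineno}: gene without ID")
                raw_genes[attrs["ID"]] = (chrom, strand, start, end)
            elif ftype == "mRNA":
                if "ID" not in attrs or "Parent" not in attrs:
                    raise AnnotationError(f"{path}:{lineno}: mRNA needs ID and Parent")
                mrna_parent[attrs["ID"]] = attrs["Parent"]
            elif ftype == "exon":
                if "Parent" not in attrs:
                    raise AnnotationError(f"{path}:{lineno}: exon without Parent")
                for parent in attrs["Parent"].split(","):
                    exons.setdefault(parent, []).append((start, end))
            elif ftype in _TE_TYPES:
                if "ID" not in attrs:
                    raise AnnotationError(f"{path}:{lineno}: TE without ID")
                tes.append(
                    TEAnnotation(
                        te_id=attrs["ID"],
                        family=attrs.get("family", attrs.get("Alias", "")),
                        chrom=chrom,
                        strand=strand if strand in "+-" else "+",
                        start=start,
                        end=end,
                    )
                )

    # hang mRNA-attached exons on their gene
    gene_exons: dict[str, list[Interval]] = {g: [] for g in raw_genes}
    for parent, ivs in exons.items():
        gene_id = mrna_parent.get(parent, parent)
        if gene_id not in gene_exons:
            raise AnnotationError(f"exon parent {parent!r} not attached to any gene")
        gene_exons[gene_id].extend(ivs)

    genes = []
    for gene_id, (chrom, strand, start, end) in raw_genes.items():
        ivs = gene_exons[gene_id] or [(start, end)]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                exons=tuple(union_intervals(ivs)),
            )
        )
    return genes, tes


def write_gff3(genes, tes, path) -> None:
    """Write gene/exon and TE features (inverse of :func:`read_gff3`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tmethylfree\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tmethylfree\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n"
                )
        for te in tes:
            fh.write(
                f"{te.chrom}\tmethylfree\ttransposable_element\t{te.start}\t{te.end}\t.\t"
                f"{te.strand}\t.\tID={te.te_id};family={te.family}\n"
            )


def union_intervals(intervals) -> list[Interval]:
    """Coalesce overlapping or bookended 1-based inclusive intervals."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


# ---------------------------------------------------------------------------
# Region derivation


def _tile_bins(start: int, end: int, bin_bp: int, from_right: bool) -> list[Interval]:
    """Tile [start, end] with bins of <= bin_bp, starting from one edge."""
    bins = []
    if from_right:
        hi = end
        while hi >= start:
            lo = max(start, hi - bin_bp + 1)
            bins.append((lo, hi))
            hi = lo - 1
    else:
        lo = start
        while lo <= end:
            hi = min(end, lo + bin_bp - 1)
            bins.append((lo, hi))
            lo = hi + 1
    return bins


def derive_gene_regions(
    gene: GeneModel,
    genome: GenomeSequence,
    flank_bp: int = 2000,
    bin_bp: int = 500,
) -> GeneRegions:
    """Derive body, promoter, downstream and their 500-bp bins for a gene.

    The promoter is the ``flank_bp`` window upstream of the strand-aware TSS
    and the downstream region the window past the TES, both clipped to the
    chromosome; bins tile each flank from the gene-proximal edge outward, so
    the first bin abuts the gene and a clipped flank shortens the outermost
    bin.
    """
    chrom_len = genome.length(gene.chrom)

    def clip(lo: int, hi: int) -> Interval | None:
        lo, hi = max(1, lo), min(chrom_len, hi)
        if lo > hi:
            return None
        return (lo, hi)

    if gene.strand == "+":
        promoter = clip(gene.start - flank_bp, gene.start - 1)
        downstream = clip(gene.end + 1, gene.end + flank_bp)
    else:
        promoter = clip(gene.end + 1, gene.end + flank_bp)
        downstream = clip(gene.start - flank_bp, gene.start - 1)

    def bins(region: Interval | None, proximal_right: bool) -> list[Interval]:
        if region is None:
            return []
        return _tile_bins(region[0], region[1], bin_bp, from_right=proximal_right)

    # gene-proximal edge: for + strand the promoter abuts the gene on its
    # right edge, the downstream region on its left edge; mirrored for -.
    if gene.strand == "+":
        pbins = bins(promoter, proximal_right=True)
        dbins = bins(downstream, proximal_right=False)
    else:
        pbins = bins(promoter, proximal_right=False)
        dbins = bins(downstream, proximal_right=True)

    if promoter is None or promoter[1] - promoter[0] + 1 < flank_bp:
        logger.debug("%s: promoter clipped at chromosome edge", gene.gene_id)
    return GeneRegions(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        body=gene.span,
        promoter=promoter,
        downstream=downstream,
        promoter_bins=pbins,
        downstream_bins=dbins,
    )


def find_n_runs(genome: GenomeSequence, min_len: int = 4) -> dict[str, list[Interval]]:
    """Maximal runs of >= min_len consecutive N per chromosome (1-based)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    pat = re.compile(f"N{{{min_len},}}")
    return {
        chrom: [(m.start() + 1, m.end()) for m in pat.finditer(genome.seq(chrom))]
        for chrom in genome.chrom_names
    }


def build_mask(
    genome: GenomeSequence,
    centromere_spans: dict[str, list[Interval]] | None = None,
    n_min_len: int = 4,
    chrom_end_margin: int = 3000,
) -> ChromosomeMask:
    return ChromosomeMask(
        centromere_spans=dict(centromere_spans or {}),
        n_run_spans=find_n_runs(genome, min_len=n_min_len),
        chrom_end_margin=chrom_end_margin,
    )


def write_mask_bed(mask: ChromosomeMask, path) -> None:
    """Mask spans as BED (0-based half-open at this boundary)."""
    with open(path, "w") as fh:
        for label, spans in (("centromere", mask.centromere_spans), ("n_run", mask.n_run_spans)):
            for chrom, ivs in sorted(spans.items()):
                for s, e in ivs:
                    fh.write(f"{chrom}\t{s - 1}\t{e}\t{label}\n")
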