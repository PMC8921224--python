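"""Split-read detection of non-reference TE insertions with TSD calling.

A transposition event leaves a new TE copy flanked by a short target-site
duplication (TSD). Reads spanning either junction of such an insertion
carry part TE sequence and part genomic flank; when aligned to the
reference they surface as unmapped or discordant mates. The caller:

1. selects read pairs with an unmapped or discordant member;
2. end-anchors one read end to a database of 5'/3' TE extremities
   (300 bp, strand-normalised; families lacking intact reference
   extremities excluded), requiring >= 20 matched nt;
3. recursively soft-clips the non-TE portion 1 nt at a time from the
   junction side until the remainder (>= 20 nt) maps uniquely to the
   reference, defining the genomic breakpoint;
4. validates the mate (properly mapped nearby on the opposite strand,
   mapped on the same TE, or reciprocally clip-mapped);
5. clusters breakpoints per (chromosome, TE, extremity) and calls an
   insertion where a 5'-side and a 3'-side cluster of >= 4 reads each have
   genomic footprints overlapping by 4-19 bp — that overlap is the TSD;
6. filters calls near centromeres, chromosome ends, N-runs, or spanning
   the donor TE copy itself.

The alignment backend is an exact-substring search with a uniqueness
check, sized for kilobase-scale genomes; on real data an external aligner
produces the SAM consumed here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pysam

from .genome import ChromosomeMask, GenomeSequence, Interval, TEAnnotation, revcomp

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_FAMILIES = ("ARNOLDY2", "ATCOPIA62", "ATCOPIA95", "TA12", "TAG1")


@dataclass
class TEExtremityDB:
    """5' and 3' extremity sequences per TE, in TE orientation."""

    extremities: dict[str, dict[str, str]]  # te_id -> {"5p": seq, "3p": seq}
    families: dict[str, str]
    donor_spans: dict[str, tuple[str, int, int]]
    excluded_families: tuple[str, ...] = ()


@dataclass
class AlignmentRecord:
    read_id: str
    is_read1: bool
    seq: str
    mapped: bool
    chrom: str | None = None
    pos: int | None = None  # 1-based leftmost
    strand: str | None = None
    proper_pair: bool = False
    insert_size: int = 0


@dataclass
class TEMatch:
    te_id: str
    te_end: str  # "5p" | "3p"
    matched_len: int
    genomic_seq: str  # non-TE remainder of the oriented read
    te_side: str  # side of the TE portion within the oriented read: "left" | "right"
    orientation: str  # "fwd" | "rev" (read used as given or reverse-complemented)
    ambiguous: bool = False


@dataclass
class ClippedCandidate:
    read_id: str
    te_id: str
    te_end: str
    te_matched_len: int
    chrom: str
    breakpoint: int
    genomic_interval: Interval
    genomic_strand: str
    clipped_len: int
    mate_support: str | None = None
    ambiguous: bool = False


@dataclass
class InsertionCall:
    chrom: str
    te_id: str
    family: str
    tsd: Interval
    n_reads_5prime: int
    n_reads_3prime: int
    filter_status: str = "PASS"

    @property
    def tsd_len(self) -> int:
        return self.tsd[1] - self.tsd[0] + 1


# ---------------------------------------------------------------------------


def build_extremity_db(
    tes: list[TEAnnotation],
    genome: GenomeSequence,
    ext_len: int = 300,
    excluded: tuple[str, ...] = DEFAULT_EXCLUDED_FAMILIES,
) -> TEExtremityDB:
    """Extract strand-normalised 5'/3' TE extremities.

    TEs shorter than twice ``ext_len`` contribute truncated,
    non-overlapping halves; TEs of excluded families are dropped.
    """
    extremities, families, spans = {}, {}, {}
    for te in tes:
        if te.family in excluded:
            continue
        seq = genome.fetch(te.chrom, te.start, te.end)
        if te.strand == "-":
            seq = revcomp(seq)
        if len(seq) >= 2 * ext_len:
            five, three = seq[:ext_len], seq[-ext_len:]
        else:
            half = len(seq) // 2
            five, three = seq[:half], seq[half:]
        extremities[te.te_id] = {"5p": five, "3p": three}
        families[te.te_id] = te.family
        spans[te.te_id] = (te.chrom, te.start, te.end)
    return TEExtremityDB(extremities, families, spans, excluded_families=tuple(excluded))


def read_sam(path) -> list[AlignmentRecord]:
    """Read alignment records from a (text) SAM file."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            seq = aln.query_sequence or ""
            if aln.is_reverse and not aln.is_unmapped:
                # store read bases in original orientation for exact matching
                seq = revcomp(seq)
            out.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    is_read1=not aln.is_read2,
                    seq=seq,
                    mapped=not aln.is_unmapped,
                    chrom=aln.reference_name if not aln.is_unmapped else None,
                    pos=aln.reference_start + 1 if not aln.is_unmapped else None,
                    strand=("-" if aln.is_reverse else "+") if not aln.is_unmapped else None,
                    proper_pair=aln.is_proper_pair,
                    insert_size=aln.template_length,
                )
            )
    return out


def select_candidate_reads(
    alignments: list[AlignmentRecord], max_insert: int = 3000
) -> list[tuple[AlignmentRecord, AlignmentRecord]]:
    """Read pairs with an unmapped member or a discordant configuration.

    Discordant: not flagged proper, insert size >= ``max_insert``, or both
    mates mapped on the same strand. Unpaired reads are skipped with a log
    message.
    """
    by_id: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        by_id.setdefault(rec.read_id, []).append(rec)
    pairs = []
    for read_id, recs in by_id.items():
        if len(recs) != 2:
            logger.info("skipping unpaired read %s", read_id)
            continue
        r1, r2 = recs
        unmapped = not (r1.mapped and r2.mapped)
        same_strand = r1.mapped and r2.mapped and r1.strand == r2.strand
        long_insert = max(abs(r1.insert_size), abs(r2.insert_size)) >= max_insert
        discordant = not (r1.proper_pair and r2.proper_pair) or long_insert or same_strand
        if unmapped or discordant:
            pairs.append((r1, r2))
    return pairs


def _longest_suffix_prefix(a: str, b: str, min_len: int) -> int:
    """Longest L >= min_len with a[-L:] == b[:L] (0 if none)."""
    for L in range(min(len(a) - 1, len(b)), min_len - 1, -1):
        if a[-L:] == b[:L]:
            return L
    return 0


def _longest_prefix_suffix(a: str, b: str, min_len: int) -> int:
    """Longest L >= min_len with a[:L] == b[-L:] (0 if none)."""
    for L in range(min(len(a) - 1, len(b)), min_len - 1, -1):
        if a[:L] == b[-L:]:
            return L
    return 0


def clip_map_te(read_seq: str, db: TEExtremityDB, min_match: int = 20) -> TEMatch | None:
    """End-anchor one read end to a TE extremity.

    A junction read carries the TE terminus at one of its ends: its suffix
    matches a 5' extremity's start, or its prefix matches a 3' extremity's
    end (both orientations of the read are tried). Returns the longest
    end-anchored exact match of >= ``min_match`` nt; an equally long match
    to a second TE is resolved to the lexicographically smaller te_id and
    flagged ambiguous.
    """
    if len(read_seq) < 2 * min_match:
        return None
    hits = []  # (L, te_id, te_end, orientation, te_side, genomic_seq)
    for orientation, r in (("fwd", read_seq), ("rev", revcomp(read_seq))):
        for te_id, ends in db.extremities.items():
            L = _longest_suffix_prefix(r, ends["5p"], min_match)
            if L:
                hits.append((L, te_id, "5p", orientation, "right", r[:-L]))
            L = _longest_prefix_suffix(r, ends["3p"], min_match)
            if L:
                hits.append((L, te_id, "3p", orientation, "left", r[L:]))
    if not hits:
        return None
    hits.sort(key=lambda h: (-h[0], h[1], h[2], h[3]))
    best = hits[0]
    ambiguous = any(h[0] == best[0] and h[1] != best[1] for h in hits[1:])
    return TEMatch(
        te_id=best[1],
        te_end=best[2],
        matched_len=best[0],
        genomic_seq=best[5],
        te_side=best[4],
        orientation=best[3],
        ambiguous=ambiguous,
    )


def recursive_genome_clip(
    te_match: TEMatch, genome: GenomeSequence, min_len: int = 20
) -> tuple[str, int, Interval, str, int] | None:
    """Locate the genomic portion of a junction read by recursive clipping.

    The non-TE remainder is trimmed 1 nt at a time from its junction
    (TE-side) end; the first trim length at which the remaining segment of
    >= ``min_len`` nt maps to exactly one genomic location defines the
    breakpoint — the mapped base adjacent to the clip. A segment with
    multiple exact hits is discarded as multi-mapping; shrinking below
    ``min_len`` without a hit discards the candidate.

    Returns (chrom, breakpoint, (start, end), strand, mapped_len) or None.
    """
    seg = te_match.genomic_seq
    junction_right = te_match.te_side == "right"
    for trim in range(0, len(seg) - min_len + 1):
        sub = seg[: len(seg) - trim] if junction_right else seg[trim:]
        hits = genome.find_all(sub)
        if len(hits) > 1:
            return None
        if len(hits) == 1:
            chrom, g1, g2, strand = hits[0]
            if junction_right:
                breakpoint = g2 if strand == "+" else g1
            else:
                breakpoint = g1 if strand == "+" else g2
            return chrom, breakpoint, (g1, g2), strand, len(sub)
    return None


def make_candidate(
    read: AlignmentRecord,
    db: TEExtremityDB,
    genome: GenomeSequence,
    min_match: int = 20,
) -> ClippedCandidate | None:
    """clip_map_te + recursive_genome_clip for one read."""
    m = clip_map_te(read.seq, db, min_match=min_match)
    if m is None:
        return None
    hit = recursive_genome_clip(m, genome, min_len=min_match)
    if hit is None:
        return None
    chrom, breakpoint, interval, strand, mapped_len = hit
    # the read's genomic orientation flips with the tried orientation
    if m.orientation == "rev":
        strand = "+" if strand == "-" else "-"
    return ClippedCandidate(
        read_id=read.read_id,
        te_id=m.te_id,
        te_end=m.te_end,
        te_matched_len=m.matched_len,
        chrom=chrom,
        breakpoint=breakpoint,
        genomic_interval=interval,
        genomic_strand=strand,
        clipped_len=mapped_len,
        ambiguous=m.ambiguous,
    )


def validate_mate(
    candidate: ClippedCandidate,
    mate: AlignmentRecord | None,
    db: TEExtremityDB,
    genome: GenomeSequence,
    max_insert: int = 3000,
    min_match: int = 20,
) -> str | None:
    """Mate-support criteria, tried in order.

    (a) ``proper_pair``: mate mapped on the reference, same chromosome,
        within ``max_insert`` bp of the breakpoint, opposite strand;
    (b) ``same_te``: mate sequence maps within an extremity of the same TE;
    (c) ``clip_opposite``: mate is itself clip-mapped to the same TE with a
        genomic portion on the opposite strand.
    """
    if mate is None:
        return None
    if (
        mate.mapped
        and mate.chrom == candidate.chrom
        and abs(mate.pos - candidate.breakpoint) < max_insert
        and mate.strand != candidate.genomic_strand
    ):
        return "proper_pair"
    ends = db.extremities.get(candidate.te_id, {})
    for ext in ends.values():
        if mate.seq and (mate.seq in ext or revcomp(mate.seq) in ext):
            return "same_te"
    mate_cand = make_candidate(mate, db, genome, min_match=min_match)
    if (
        mate_cand is not None
        and mate_cand.te_id == candidate.te_id
        and mate_cand.genomic_strand != candidate.genomic_strand
    ):
        return "clip_opposite"
    return None


# ---------------------------------------------------------------------------
# Clustering and calling


@dataclass
class _Cluster:
    te_end: str
    members: list[ClippedCandidate] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len({c.read_id for c in self.members})

    @property
    def footprint(self) -> Interval:
        return (
            min(c.genomic_interval[0] for c in self.members),
            max(c.genomic_interval[1] for c in self.members),
        )


def cluster_and_call(
    candidates: list[ClippedCandidate],
    db: TEExtremityDB,
    merge_window: int = 100,
    min_reads: int = 4,
    tsd_min: int = 4,
    tsd_max: int = 19,
) -> list[InsertionCall]:
    """Cluster validated candidates and call insertions with a TSD.

    Breakpoints of the same (chromosome, TE, extremity) within
    ``merge_window`` bp merge into one cluster; clusters of >= ``min_reads``
    distinct reads from opposite extremities whose genomic footprints
    overlap by ``tsd_min``..``tsd_max`` bp yield a call whose TSD is that
    overlap. Ambiguous-TE candidates are excluded. The result is invariant
    to input order (candidates are canonically sorted first).
    """
    usable = sorted(
        (c for c in candidates if not c.ambiguous),
        key=lambda c: (c.chrom, c.te_id, c.te_end, c.breakpoint, c.read_id),
    )
    clusters: dict[tuple[str, str], list[_Cluster]] = {}
    for cand in usable:
        key = (cand.chrom, cand.te_id)
        found = None
        for cl in clusters.get(key, []):
            if cl.te_end == cand.te_end and any(
                abs(cand.breakpoint - m.breakpoint) <= merge_window for m in cl.members
            ):
                found = cl
                break
        if found is None:
            found = _Cluster(te_end=cand.te_end)
            clusters.setdefault(key, []).append(found)
        found.members.append(cand)

    calls = []
    for (chrom, te_id), cls in sorted(clusters.items()):
        big = [c for c in cls if c.n_reads >= min_reads]
        for c5 in (c for c in big if c.te_end == "5p"):
            for c3 in (c for c in big if c.te_end == "3p"):
                f5, f3 = c5.footprint, c3.footprint
                lo, hi = max(f5[0], f3[0]), min(f5[1], f3[1])
                if lo > hi:
                    continue
                if tsd_min <= hi - lo + 1 <= tsd_max:
                    calls.append(
                        InsertionCall(
                            chrom=chrom,
                            te_id=te_id,
                            family=db.families.get(te_id, ""),
                            tsd=(lo, hi),
                            n_reads_5prime=c5.n_reads,
                            n_reads_3prime=c3.n_reads,
                        )
                    )
    calls.sort(key=lambda c: (c.chrom, c.tsd, c.te_id))
    return calls


def _near_span(pos_lo: int, pos_hi: int, span: Interval, margin: int) -> bool:
    return pos_lo <= span[1] + margin and pos_hi >= span[0] - margin


def filter_calls(
    calls: list[InsertionCall],
    mask: ChromosomeMask,
    donor_tes: list[TEAnnotation],
    genome: GenomeSequence,
    centromere_margin: int = 3000,
    n_run_margin: int = 500,
) -> list[InsertionCall]:
    """Apply the aberrant-region and donor-span filters.

    Removes calls within 3 kb of a centromere span or chromosome end,
    within 500 bp of an N-run, or whose TSD intersects the donor TE's own
    annotated span. Every call's ``filter_status`` is annotated in place;
    the returned list holds the PASS calls.
    """
    donor_span = {te.te_id: (te.chrom, te.start, te.end) for te in donor_tes}
    passed = []
    for call in calls:
        lo, hi = call.tsd
        status = "PASS"
        end_margin = mask.chrom_end_margin
        if lo <= end_margin or hi > genome.length(call.chrom) - end_margin:
            status = "chrom_end"
        elif any(
            _near_span(lo, hi, span, centromere_margin)
            for span in mask.centromere_spans.get(call.chrom, [])
        ):
            status = "centromere"
        elif any(
            _near_span(lo, hi, span, n_run_margin)
            for span in mask.n_run_spans.get(call.chrom, [])
        ):
            status = "n_run"
        else:
            donor = donor_span.get(call.te_id)
            if donor and donor[0] == call.chrom and lo <= donor[2] and hi >= donor[1]:
                status = "donor_span"
        call.filter_status = status
        if status == "PASS":
            passed.append(call)
    return passed


def call_insertions(
    alignments: list[AlignmentRecord],
    genome: GenomeSequence,
    tes: list[TEAnnotation],
    mask: ChromosomeMask,
    ext_len: int = 300,
    min_match: int = 20,
    min_reads: int = 4,
    tsd_min: int = 4,
    tsd_max: int = 19,
    merge_window: int = 100,
    excluded_families: tuple[str, ...] = DEFAULT_EXCLUDED_FAMILIES,
) -> tuple[list[InsertionCall], list[InsertionCall]]:
    """End-to-end caller: returns (passed_calls, all_calls)."""
    db = build_extremity_db(tes, genome, ext_len=ext_len, excluded=excluded_families)
    pairs = select_candidate_reads(alignments)
    validated = []
    for r1, r2 in pairs:
        for read, mate in ((r1, r2), (r2, r1)):
            cand = make_candidate(read, db, genome, min_match=min_match)
            if cand is None:
                continue
            support = validate_mate(cand, mate, db, genome, min_match=min_match)
            if support is None:
                continue
            cand.mate_support = support
            validated.append(cand)
    all_calls = cluster_and_call(
        validated,
        db,
        merge_window=merge_window,
        min_reads=min_reads,
        tsd_min=tsd_min,
        tsd_max=tsd_max,
    )
    passed = filter_calls(all_calls, mask, tes, genome)
    return passed, all_calls


def write_calls(calls: list[InsertionCall], bed_path=None, json_path=None) -> None:
    """Calls as BED (TSD interval, 0-based half-open) and/or JSON."""
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for c in calls:
                fh.write(f"{c.chrom}\t{c.tsd[0] - 1}\t{c.tsd[1]}\t{c.te_id}\t{c.tsd_len}\t.\n")
    if json_path is not None:
        payload = [
            {
                "chrom": c.chrom,
                "te_id": c.te_id,
                "family": c.family,
                "tsd_start": c.tsd[0],
                "tsd_end": c.tsd[1],
                "tsd_len": c.tsd_len,
                "n_reads_5prime": c.n_reads_5prime,
                "n_reads_3prime": c.n_reads_3prime,
                "filter_status": c.filter_status,
            }
            for c in calls
        ]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
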