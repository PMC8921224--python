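import numpy as np
import pytest

from methylfree import simulate
from methylfree.genome import ChromosomeMask, GenomeSequence, build_mask, revcomp
from methylfree.insertions import (
    AlignmentRecord,
    ClippedCandidate,
    InsertionCall,
    build_extremity_db,
    call_insertions,
    clip_map_te,
    cluster_and_call,
    filter_calls,
    make_candidate,
    read_sam,
    recursive_genome_clip,
    select_candidate_reads,
    validate_mate,
)

from conftest import make_te


@pytest.fixture(scope="module")
def ins_genome():
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, 20_000)].tobytes().decode()
    return GenomeSequence({"c1": seq})


@pytest.fixture(scope="module")
def ins_tes():
    return [
        make_te("teA", family="FAMA", start=1001, end=2000),
        make_te("teB", family="FAMB", start=3001, end=3400),
        make_te("teX", family="TAG1", start=5001, end=6000),  # excluded family
    ]


@pytest.fixture(scope="module")
def ins_db(ins_genome, ins_tes):
    return build_extremity_db(ins_tes, ins_genome)


class TestExtremityDB:
    def test_long_te_gets_300bp_ends(self, ins_genome, ins_db):
        ends = ins_db.extremities["teA"]
        assert ends["5p"] == ins_genome.fetch("c1", 1001, 1300)
        assert ends["3p"] == ins_genome.fetch("c1", 1701, 2000)

    def test_short_te_truncated_nonoverlapping_halves(self, ins_db):
        ends = ins_db.extremities["teB"]
        assert len(ends["5p"]) == 200 and len(ends["3p"]) == 200

    def test_excluded_family_absent(self, ins_db):
        assert "teX" not in ins_db.extremities

    def test_minus_strand_te_is_strand_normalised(self, ins_genome):
        te = make_te("teM", strand="-", start=1001, end=2000)
        db = build_extremity_db([te], ins_genome)
        assert db.extremities["teM"]["5p"] == revcomp(ins_genome.fetch("c1", 1701, 2000))


class TestCandidateSelection:
    def pair(self, **kw):
        defaults = dict(mapped=True, chrom="c1", pos=100, strand="+", proper_pair=True, insert_size=250)
        r1 = AlignmentRecord("r", True, "A" * 50, **{**defaults, **kw.get("r1", {})})
        r2 = AlignmentRecord("r", False, "A" * 50, **{**defaults, "strand": "-", **kw.get("r2", {})})
        return [r1, r2]

    def test_proper_pair_excluded(self):
        assert select_candidate_reads(self.pair()) == []

    def test_unmapped_mate_included(self):
        recs = self.pair(r1={"mapped": False, "proper_pair": False}, r2={"proper_pair": False})
        assert len(select_candidate_reads(recs)) == 1

    def test_same_strand_pair_is_discordant(self):
        recs = self.pair(r2={"strand": "+"})
        assert len(select_candidate_reads(recs)) == 1

    def test_long_insert_is_discordant(self):
        recs = self.pair(r1={"insert_size": 3500}, r2={"insert_size": -3500})
        assert len(select_candidate_reads(recs)) == 1

    def test_unpaired_read_skipped(self):
        lone = [AlignmentRecord("solo", True, "A" * 50, mapped=False)]
        assert select_candidate_reads(lone) == []


class TestClipMapTE:
    def test_junction_read_matches_extremity(self, ins_genome, ins_db):
        read = ins_genome.fetch("c1", 9001, 9070) + ins_db.extremities["teA"]["5p"][:30]
        m = clip_map_te(read, ins_db)
        assert m.te_id == "teA" and m.te_end == "5p" and m.matched_len == 30
        assert m.genomic_seq == ins_genome.fetch("c1", 9001, 9070)

    def test_below_20nt_match_rejected(self, ins_genome, ins_db):
        read = ins_genome.fetch("c1", 9001, 9081) + ins_db.extremities["teA"]["5p"][:19]
        assert clip_map_te(read, ins_db) is None

    def test_tie_between_tes_flagged_ambiguous(self, ins_genome, ins_tes):
        db = build_extremity_db(ins_tes, ins_genome)
        shared = db.extremities["teA"]["5p"][:30]
        db.extremities["teB"] = {"5p": shared, "3p": db.extremities["teB"]["3p"]}
        read = ins_genome.fetch("c1", 9001, 9070) + shared
        m = clip_map_te(read, db)
        assert m.te_id == "teA" and m.ambiguous

    def test_reverse_orientation_detected(self, ins_genome, ins_db):
        read = revcomp(ins_genome.fetch("c1", 9001, 9070) + ins_db.extremities["teA"]["5p"][:30])
        m = clip_map_te(read, ins_db)
        assert m.te_id == "teA" and m.orientation == "rev"


class TestRecursiveClip:
    def test_clean_tail_maps_at_trim_zero(self, ins_genome, ins_db):
        read = ins_genome.fetch("c1", 9001, 9070) + ins_db.extremities["teA"]["5p"][:30]
        m = clip_map_te(read, ins_db)
        hit = recursive_genome_clip(m, ins_genome)
        chrom, breakpoint, interval, strand, mapped_len = hit
        assert (chrom, breakpoint, strand) == ("c1", 9070, "+")
        assert interval == (9001, 9070) and mapped_len == 70

    def test_mutated_junction_bases_trimmed(self, ins_genome, ins_db):
        tail = ins_genome.fetch("c1", 9001, 9070)
        tail = tail[:-5] + revcomp(tail[-5:])[::-1].lower().upper()  # scramble last 5
        tail = tail[:-5] + "".join("A" if b != "A" else "C" for b in tail[-5:])
        m_read = tail + ins_db.extremities["teA"]["5p"][:30]
        m = clip_map_te(m_read, ins_db)
        hit = recursive_genome_clip(m, ins_genome)
        assert hit is not None
        chrom, breakpoint, interval, strand, mapped_len = hit
        assert breakpoint == 9065 and mapped_len == 65

    def test_unmappable_tail_discarded(self, ins_db, ins_genome):
        m = clip_map_te("GATTACA" * 10 + ins_db.extremities["teA"]["5p"][:30], ins_db)
        assert m is not None
        assert recursive_genome_clip(m, ins_genome) is None


class TestValidateMate:
    def candidate(self, ins_genome, ins_db):
        read = ins_genome.fetch("c1", 9001, 9070) + ins_db.extremities["teA"]["5p"][:30]
        return make_candidate(AlignmentRecord("r", True, read, mapped=False), ins_db, ins_genome)

    def test_proper_nearby_opposite_strand(self, ins_genome, ins_db):
        cand = self.candidate(ins_genome, ins_db)
        mate = AlignmentRecord("r", False, "A" * 50, mapped=True, chrom="c1", pos=8870, strand="-")
        assert validate_mate(cand, mate, ins_db, ins_genome) == "proper_pair"

    def test_mate_inside_same_te(self, ins_genome, ins_db):
        cand = self.candidate(ins_genome, ins_db)
        mate = AlignmentRecord(
            "r", False, ins_db.extremities["teA"]["5p"][100:180], mapped=False
        )
        assert validate_mate(cand, mate, ins_db, ins_genome) == "same_te"

    def test_distant_mate_rejected(self, ins_genome, ins_db):
        cand = self.candidate(ins_genome, ins_db)
        mate = AlignmentRecord("r", False, "A" * 50, mapped=True, chrom="c1", pos=12600, strand="-")
        assert validate_mate(cand, mate, ins_db, ins_genome) is None

    def test_missing_mate_rejected(self, ins_genome, ins_db):
        assert validate_mate(self.candidate(ins_genome, ins_db), None, ins_db, ins_genome) is None


def make_cluster_candidates(chrom, te_id, te_end, breakpoints, side):
    out = []
    for i, bp in enumerate(breakpoints):
        interval = (bp - 60, bp) if side == "left" else (bp, bp + 60)
        out.append(
            ClippedCandidate(
                read_id=f"{te_end}_{i}",
                te_id=te_id,
                te_end=te_end,
                te_matched_len=30,
                chrom=chrom,
                breakpoint=bp,
                genomic_interval=interval,
                genomic_strand="+",
                clipped_len=60,
            )
        )
    return out


class TestClusterAndCall:
    def db(self):
        from methylfree.insertions import TEExtremityDB

        return TEExtremityDB({}, {"teA": "FAMA"}, {})

    def test_overlap_gives_tsd(self):
        c5 = make_cluster_candidates("c1", "teA", "5p", [509] * 5, side="left")
        c3 = make_cluster_candidates("c1", "teA", "3p", [501] * 4, side="right")
        calls = cluster_and_call(c5 + c3, self.db())
        assert len(calls) == 1
        assert calls[0].tsd == (501, 509) and calls[0].tsd_len == 9
        assert calls[0].n_reads_5prime == 5 and calls[0].n_reads_3prime == 4

    def test_three_reads_insufficient(self):
        c5 = make_cluster_candidates("c1", "teA", "5p", [509] * 3, side="left")
        c3 = make_cluster_candidates("c1", "teA", "3p", [501] * 6, side="right")
        assert cluster_and_call(c5 + c3, self.db()) == []

    @pytest.mark.parametrize("tsd_len", [2, 3, 20, 25])
    def test_tsd_size_bounds(self, tsd_len):
        c5 = make_cluster_candidates("c1", "teA", "5p", [500 + tsd_len - 1] * 5, side="left")
        c3 = make_cluster_candidates("c1", "teA", "3p", [500] * 5, side="right")
        assert cluster_and_call(c5 + c3, self.db()) == []

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        c5 = make_cluster_candidates("c1", "teA", "5p", [509, 509, 508, 509, 509], side="left")
        c3 = make_cluster_candidates("c1", "teA", "3p", [501, 501, 501, 502], side="right")
        cands = c5 + c3
        base = cluster_and_call(list(cands), self.db())
        for _ in range(5):
            perm = [cands[i] for i in rng.permutation(len(cands))]
            assert cluster_and_call(perm, self.db()) == base

    def test_ambiguous_candidates_excluded(self):
        c5 = make_cluster_candidates("c1", "teA", "5p", [509] * 4, side="left")
        for c in c5:
            c.ambiguous = True
        c3 = make_cluster_candidates("c1", "teA", "3p", [501] * 4, side="right")
        assert cluster_and_call(c5 + c3, self.db()) == []


class TestFilterCalls:
    def call(self, lo, hi, te_id="teA"):
        return InsertionCall("c1", te_id, "FAMA", (lo, hi), 5, 5)

    def mask(self):
        return ChromosomeMask(
            centromere_spans={"c1": [(10_000, 10_500)]},
            n_run_spans={"c1": [(15_000, 15_050)]},
        )

    def test_near_chromosome_end_removed(self, ins_genome):
        calls = [self.call(17_495, 17_505)]  # 2.5 kb from the 20-kb end
        passed = filter_calls(calls, self.mask(), [], ins_genome)
        assert passed == [] and calls[0].filter_status == "chrom_end"

    def test_outside_n_run_margin_retained(self, ins_genome):
        calls = [self.call(15_651, 15_660)]  # 600 bp from the N-run
        passed = filter_calls(calls, self.mask(), [], ins_genome)
        assert len(passed) == 1

    def test_near_centromere_removed(self, ins_genome):
        calls = [self.call(12_600, 12_610)]
        passed = filter_calls(calls, self.mask(), [], ins_genome)
        assert passed == [] and calls[0].filter_status == "centromere"

    def test_inside_donor_span_removed(self, ins_genome, ins_tes):
        calls = [self.call(5_500, 5_510, te_id="teA")]
        donor = [make_te("teA", family="FAMA", start=5_400, end=6_400)]
        passed = filter_calls(calls, self.mask(), donor, ins_genome)
        assert passed == [] and calls[0].filter_status == "donor_span"


@pytest.fixture(scope="module")
def world():
    cfg = simulate.SimulationConfig(
        seed=23,
        n_genes_per_category={"UM": 4},
        insertion_zone_len=60_000,
        n_background_pairs=80,
    )
    genome, genes, tes, truth = simulate.simulate_genome(cfg)
    lines = simulate.simulate_insertion_readset(genome, tes, truth, cfg)
    return cfg, genome, tes, truth, lines


class TestEndToEnd:
    def test_all_planted_insertions_recovered_exactly(self, world, tmp_path):
        cfg, genome, tes, truth, lines = world
        sam = tmp_path / "r.sam"
        sam.write_text("\n".join(lines) + "\n")
        alignments = read_sam(sam)
        mask = build_mask(genome, centromere_spans=simulate.centromere_spans(truth))
        passed, all_calls = call_insertions(alignments, genome, tes, mask)
        expected = {
            (t["chrom"], t["tsd_start"], t["tsd_end"], t["te_id"]) for t in truth.insertions
        }
        got = {(c.chrom, c.tsd[0], c.tsd[1], c.te_id) for c in passed}
        assert got == expected
        assert len(all_calls) == len(passed)  # zero false or filtered calls

    def test_call_list_invariant_to_read_order(self, world, tmp_path):
        cfg, genome, tes, truth, lines = world
        sam = tmp_path / "r.sam"
        sam.write_text("\n".join(lines) + "\n")
        alignments = read_sam(sam)
        mask = build_mask(genome, centromere_spans=simulate.centromere_spans(truth))
        base, _ = call_insertions(alignments, genome, tes, mask)
        rng = np.random.default_rng(1)
        shuffled = [alignments[i] for i in rng.permutation(len(alignments))]
        again, _ = call_insertions(shuffled, genome, tes, mask)
        assert again == base
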