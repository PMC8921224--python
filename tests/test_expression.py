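import math

import numpy as np
import pandas as pd
import pytest

from methylfree.expression import (
    DesignError,
    IntronSplitCounts,
    call_de_features,
    classify_patterns,
    classify_regulation_pattern,
    compute_fpkm,
    de_sets,
    de_test,
    filter_expressed,
    intron_tem_3prime_test,
    intron_tem_screen,
    select_split_intron,
    size_factors,
)
from methylfree.simulate import _nb_draws

from conftest import make_gene
from test_methylome import table_from_rows


def nb_matrix(rng, mean, disp, n_features, samples):
    return pd.DataFrame(
        _nb_draws(rng, np.full((n_features, len(samples)), mean), disp, (n_features, len(samples))),
        index=[f"f{i}" for i in range(n_features)],
        columns=samples,
    )


class TestFpkm:
    def test_unit_case(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g"])
        fpkm = compute_fpkm(counts, pd.Series({"g": 1000}), pd.Series({"s1": 1e6}))
        assert fpkm.loc["g", "s1"] == pytest.approx(10.0)

    def test_zero_count(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g"])
        fpkm = compute_fpkm(counts, pd.Series({"g": 500}), pd.Series({"s1": 1e6}))
        assert fpkm.loc["g", "s1"] == 0.0

    def test_hand_arithmetic(self):
        counts = pd.DataFrame({"s1": [25]}, index=["g"])
        fpkm = compute_fpkm(counts, pd.Series({"g": 2500}), pd.Series({"s1": 5e6}))
        assert fpkm.loc["g", "s1"] == pytest.approx(2.0)

    def test_zero_length_errors(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g"])
        with pytest.raises(ValueError):
            compute_fpkm(counts, pd.Series({"g": 0}), pd.Series({"s1": 1e6}))


class TestFilterExpressed:
    def design(self):
        return pd.Series(
            {f"{g}_r{r}": g for g in ("WT", "ddcc", "met1", "mddcc") for r in (1, 2)}
        )

    def fpkm(self, per_genotype):
        design = self.design()
        row = {s: per_genotype[design[s]] for s in design.index}
        return pd.DataFrame([row], index=["g"])

    @pytest.mark.parametrize(
        "means,kept",
        [
            ({"WT": 0.1, "ddcc": 0.2, "met1": 0.3, "mddcc": 0.1}, False),
            ({"WT": 0.1, "ddcc": 0.9, "met1": 0.1, "mddcc": 0.1}, True),
            ({"WT": 0.5, "ddcc": 0.5, "met1": 0.5, "mddcc": 0.5}, True),  # boundary: >= keeps
        ],
    )
    def test_detectable_in_at_least_one_genotype(self, means, kept):
        out = filter_expressed(self.fpkm(means), self.design())
        assert (out == ["g"]) == kept


class TestDeTest:
    samples = [f"A_r{i}" for i in (1, 2, 3)] + [f"B_r{i}" for i in (1, 2, 3)]

    def design(self):
        return pd.Series([s.split("_")[0] for s in self.samples], index=self.samples)

    def test_size_factors_track_depth_ratio(self):
        rng = np.random.default_rng(0)
        counts = nb_matrix(rng, 200, 0.02, 500, self.samples)
        scaled = counts.copy()
        scaled["B_r1"] = (counts["B_r1"] * 2).astype(int)
        sf = size_factors(scaled)
        assert sf["B_r1"] / sf["A_r1"] == pytest.approx(2.0, rel=0.05)

    def test_identical_counts_give_null_result(self):
        counts = pd.DataFrame(
            {s: [100, 50] for s in self.samples}, index=["f0", "f1"]
        )
        res = de_test(counts, self.design(), ("B", "A"))
        assert res["log2fc"].abs().max() < 1e-9
        assert (res["p_value"] > 0.99).all()

    def test_planted_fourfold_recovered(self):
        rng = np.random.default_rng(5)
        counts = nb_matrix(rng, 200, 0.05, 400, self.samples)
        counts.iloc[0, 3:] = _nb_draws(rng, np.full(3, 800.0), 0.05, (3,))
        res = de_test(counts, self.design(), ("B", "A"))
        assert res.iloc[0]["log2fc"] == pytest.approx(2.0, abs=0.5)
        assert res.iloc[0]["padj"] < 0.01

    def test_all_zero_features_excluded_from_testing(self):
        counts = pd.DataFrame(
            {s: [100, 0] for s in self.samples}, index=["f0", "f1"]
        )
        res = de_test(counts, self.design(), ("B", "A"))
        assert np.isnan(res.loc["f1", "p_value"]) and np.isnan(res.loc["f1", "padj"])

    def test_fewer_than_two_replicates_errors(self):
        counts = pd.DataFrame({"A_r1": [1], "B_r1": [2], "B_r2": [3]})
        design = pd.Series({"A_r1": "A", "B_r1": "B", "B_r2": "B"})
        with pytest.raises(DesignError):
            de_test(counts, design, ("B", "A"))

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(17)
        counts = nb_matrix(rng, 200, 0.1, 2000, self.samples)
        res = de_test(counts, self.design(), ("B", "A"))
        frac = float((res["p_value"] < 0.05).mean())
        assert frac <= 0.07  # nominal 0.05 with conservative slack


class TestCallDeFeatures:
    def frame(self, log2fc, padj):
        return pd.DataFrame({"log2fc": [log2fc], "p_value": [padj], "padj": [padj]}, index=["f"])

    def test_gene_fold_change_boundary(self):
        assert call_de_features(self.frame(1.1, 0.005), "gene")["status"].iloc[0] == "up"
        assert call_de_features(self.frame(0.9, 1e-6), "gene")["status"].iloc[0] == "ns"

    def test_antisense_uses_fourfold(self):
        assert call_de_features(self.frame(1.5, 0.001), "antisense")["status"].iloc[0] == "ns"
        assert call_de_features(self.frame(2.5, 0.001), "antisense")["status"].iloc[0] == "up"

    def test_unknown_class_errors(self):
        with pytest.raises(ValueError):
            call_de_features(self.frame(1.0, 0.5), "plasmid")

    def test_up_down_disjoint(self):
        rng = np.random.default_rng(2)
        res = pd.DataFrame(
            {
                "log2fc": rng.normal(0, 2, 500),
                "p_value": rng.uniform(0, 1, 500),
                "padj": rng.uniform(0, 0.02, 500),
            }
        )
        out = call_de_features(res, "gene")
        up, down = de_sets(out)
        assert not (up & down)


def de_row(log2fc, p_value, padj, status):
    return pd.Series({"log2fc": log2fc, "p_value": p_value, "padj": padj, "status": status})


class TestRegulationPattern:
    def test_redundancy_only_mddcc(self):
        d, p = classify_regulation_pattern(
            de_row(0.1, 0.8, 0.9, "ns"), de_row(0.2, 0.7, 0.9, "ns"), de_row(3.0, 1e-9, 1e-8, "up")
        )
        assert (d, p) == ("up", "Redundancy")

    def test_dosage_one_mild_then_further(self):
        d, p = classify_regulation_pattern(
            de_row(0.2, 0.9, 0.95, "ns"),
            de_row(1.5, 1e-5, 1e-4, "up"),
            de_row(3.2, 1e-9, 1e-8, "up"),
        )
        assert (d, p) == ("up", "DosageI")

    def test_comparable_gap_is_mcg(self):
        d, p = classify_regulation_pattern(
            de_row(0.1, 0.9, 0.95, "ns"),
            de_row(2.9, 1e-7, 1e-6, "up"),
            de_row(3.0, 1e-9, 1e-8, "up"),
        )
        assert (d, p) == ("up", "mCG")

    def test_dosage_three_requires_both_mild(self):
        d, p = classify_regulation_pattern(
            de_row(1.2, 1e-4, 1e-3, "ns"),
            de_row(1.2, 1e-4, 1e-3, "ns"),
            de_row(3.0, 1e-9, 1e-8, "up"),
        )
        assert (d, p) == ("up", "DosageIII")

    def test_down_direction_mirrored(self):
        d, p = classify_regulation_pattern(
            de_row(-0.1, 0.9, 0.95, "ns"),
            de_row(-1.5, 1e-5, 1e-4, "down"),
            de_row(-3.2, 1e-9, 1e-8, "down"),
        )
        assert (d, p) == ("down", "DosageI")

    def test_not_de_in_mddcc_errors(self):
        with pytest.raises(ValueError):
            classify_regulation_pattern(
                de_row(0, 1, 1, "ns"), de_row(0, 1, 1, "ns"), de_row(0.5, 0.3, 0.6, "ns")
            )

    def test_bulk_table_skips_non_de(self):
        frames = {
            g: pd.DataFrame(
                {
                    "log2fc": [3.0, 0.1],
                    "p_value": [1e-9, 0.5],
                    "padj": [1e-8, 0.9],
                    "status": ["up" if g == "mddcc" else "ns", "ns"],
                },
                index=["f1", "f2"],
            )
            for g in ("ddcc", "met1", "mddcc")
        }
        frames["ddcc"].loc["f1", ["log2fc", "p_value", "padj", "status"]] = [0.1, 0.9, 0.95, "ns"]
        frames["met1"].loc["f1", ["log2fc", "p_value", "padj", "status"]] = [0.2, 0.8, 0.9, "ns"]
        out = classify_patterns(frames)
        assert list(out.index) == ["f1"]
        assert out.loc["f1", "pattern"] == "Redundancy"


class TestIntronTem:
    def split(self, wt5=100, wt3=100, m5=100, m3=20):
        return IntronSplitCounts(
            gene_id="g",
            split_intron=(100, 200),
            counts_5prime={"WT": wt5, "mddcc": m5},
            counts_3prime={"WT": wt3, "mddcc": m3},
        )

    def test_fivefold_depletion_flagged(self):
        stat, flagged, reason = intron_tem_3prime_test(self.split())
        assert stat == pytest.approx(math.log2(0.2))
        assert flagged and reason == "ok"

    def test_low_wt_5prime_excluded(self):
        stat, flagged, reason = intron_tem_3prime_test(self.split(wt5=9, wt3=500))
        assert stat is None and not flagged and reason == "excluded_wt_5prime_low"

    def test_identical_ratios_unflagged(self):
        stat, flagged, _ = intron_tem_3prime_test(self.split(m5=100, m3=100))
        assert stat == 0.0 and not flagged

    def test_mutant_5prime_zero_reported_with_reason(self):
        stat, flagged, reason = intron_tem_3prime_test(self.split(m5=0))
        assert stat is None and not flagged and reason == "mutant_5prime_zero"

    def test_scale_invariance_exact(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            wt5, wt3, m5, m3 = (int(x) for x in rng.integers(10, 5000, 4))
            c = int(rng.integers(2, 100))
            base, _, _ = intron_tem_3prime_test(self.split(wt5, wt3, m5, m3))
            scaled, _, _ = intron_tem_3prime_test(self.split(wt5, wt3, m5 * c, m3 * c))
            assert scaled == base  # exact, not approx

    def test_screen_emits_both_flag_tallies(self):
        splits = [
            self.split(),  # flagged in mddcc
            IntronSplitCounts(
                "g2",
                (1, 2),
                counts_5prime={"WT": 100, "met1": 100, "mddcc": 100},
                counts_3prime={"WT": 100, "met1": 10, "mddcc": 100},
            ),  # flagged in met1 only
        ]
        screen = intron_tem_screen(splits, mutants=("met1", "mddcc"))
        s = screen.attrs["summary"]
        assert s["n_flagged_mddcc"] == 1 and s["n_flagged_any_mutant"] == 2


def test_de_engine_agrees_with_pydeseq2_cross_check():
    """Independent cross-check: on a small panel with planted 4-fold shifts,
    the NB Wald stand-in and DESeq2 (via pydeseq2) give matching log2 fold
    changes and identical significance calls at padj < 0.01."""
    import warnings

    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    rng = np.random.default_rng(3)
    n = 120
    m = np.tile(np.full((n, 1), 300.0), (1, 6))
    m[:10, 3:] *= 4.0
    m[10:20, 3:] *= 0.25
    counts = pd.DataFrame(
        _nb_draws(rng, m, 0.05, (n, 6)).T,
        index=[f"s{j}" for j in range(6)],
        columns=[f"f{i}" for i in range(n)],
    )
    meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3}, index=counts.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(counts=counts, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        ds.summary()
    ref = ds.results_df
    mine = de_test(counts.T, pd.Series(meta["condition"]), ("B", "A"))
    assert (ref["log2FoldChange"] - mine["log2fc"]).abs().max() < 0.1
    assert ((ref["padj"] < 0.01) == (mine["padj"] < 0.01)).all()


def test_select_split_intron_maximises_noncg_level(toy_genome):
    gene = make_gene("g", start=1001, end=3000, exons=[(1001, 1400), (1801, 2200), (2601, 3000)])
    t = table_from_rows(
        [
            ("c1", 1500, "+", "CHH", 1, 10),  # first intron: 10%
            ("c1", 2300, "+", "CHG", 8, 10),  # second intron: 80%
        ]
    )
    assert select_split_intron(gene, t) == (2201, 2600)
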