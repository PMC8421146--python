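import pandas as pd
import pytest
from scipy import stats

from cutscan.editing_outcomes import (
    classify_junction,
    classify_table,
    fold_change,
    plasmid_profile,
    summarize,
)
from cutscan.synthetic_data import (
    JUNCTION_COLUMNS,
    SyntheticConfig,
    generate_reference,
    simulate_junctions,
)


def frame(rows):
    """rows: (prey_ref, prey_pos, present) triples."""
    return pd.DataFrame(
        [
            (f"r{i}", "chr1", 517, "+", ref, pos, "+", present)
            for i, (ref, pos, present) in enumerate(rows)
        ],
        columns=list(JUNCTION_COLUMNS),
    )


def classified_frame(outcomes, prey_pos=None):
    df = frame([("chr1", 0, 1)] * len(outcomes))
    df["outcome"] = outcomes
    if prey_pos is not None:
        df["prey_pos"] = prey_pos
    return df


class TestClassifyJunction:
    CUT = 517  # guide fixture cut position

    def test_no_junction_is_uncut(self, guide):
        assert classify_junction("chr1", self.CUT, 0, guide, []) == "uncut"

    def test_large_deletion_at_150(self, guide):
        got = classify_junction("chr1", self.CUT + 150, 1, guide, [])
        assert got == "large_deletion"

    def test_indel_at_30(self, guide):
        assert classify_junction("chr1", self.CUT + 30, 1, guide, []) == "indel"

    def test_boundary_100_is_indel(self, guide):
        assert classify_junction("chr1", self.CUT + 100, 1, guide, []) == "indel"

    def test_offtarget_translocation_near_call(self, guide):
        got = classify_junction("chr2", 5040, 1, guide, [("chr2", 5000)])
        assert got == "offtarget_translocation"

    def test_general_translocation_far_from_everything(self, guide):
        got = classify_junction("chr2", 900_000, 1, guide, [("chr2", 5000)])
        assert got == "general_translocation"

    def test_plasmid_insertion(self, guide):
        assert classify_junction("plasmid", 42, 1, guide, []) == "plasmid_insertion"

    def test_same_chrom_beyond_radius_is_general(self, guide):
        got = classify_junction("chr1", self.CUT + 30_000, 1, guide, [])
        assert got == "general_translocation"

    def test_empty_offtargets_never_offtarget_class(self, guide, rng):
        for _ in range(200):
            ref = "chr1" if rng.random() < 0.5 else "chr2"
            pos = int(rng.integers(0, 100_000))
            got = classify_junction(ref, pos, 1, guide, [])
            assert got != "offtarget_translocation"


class TestClassifyTable:
    def test_unknown_contig_error(self, guide):
        table = frame([("chrUn", 100, 1)])
        with pytest.raises(ValueError, match="chrUn"):
            classify_table(table, guide, known_refs={"chr1", "chr2"})

    def test_order_independence(self, guide, rng):
        rows = [
            ("chr1", int(rng.integers(0, 50_000)), int(rng.random() < 0.9))
            for _ in range(100)
        ]
        table = frame(rows)
        shuffled = table.sample(frac=1, random_state=7)
        a = classify_table(table, guide)
        b = classify_table(shuffled, guide).sort_index()
        assert (a["outcome"] == b["outcome"]).all()


class TestSummarize:
    def test_all_uncut_zero_efficiency(self):
        s = summarize(classified_frame(["uncut"] * 50))
        assert s.editing_efficiency == 0.0

    def test_printed_definition_arithmetic(self):
        outcomes = (
            ["indel"] * 10
            + ["large_deletion"] * 2
            + ["general_translocation"] * 3
            + ["uncut"] * 85
        )
        s = summarize(classified_frame(outcomes))
        assert s.editing_efficiency == pytest.approx(15.0)
        assert s.indel_rate == pytest.approx(10.0)

    def test_counts_conserved(self, rng):
        outcomes = rng.choice(
            ["uncut", "indel", "large_deletion", "general_translocation"], size=500
        ).tolist()
        s = summarize(classified_frame(outcomes))
        assert sum(s.counts.values()) == s.total_events == 500

    def test_empty_table_error(self):
        with pytest.raises(ValueError):
            summarize(classified_frame([]))

    def test_recovered_proportions_within_binomial_99(self):
        props = {
            "uncut": 0.45,
            "indel": 0.25,
            "large_deletion": 0.1,
            "offtarget_translocation": 0.1,
            "general_translocation": 0.05,
            "plasmid_insertion": 0.05,
        }
        cfg = SyntheticConfig(
            genome_length=120_000,
            chrom_count=2,
            planted_sites=[(3, "AGG", "chr2", 10_000)],
            outcome_proportions=props,
            n_events=10_000,
            seed=17,
        )
        genome, _, guide, truth = generate_reference(cfg)
        table = simulate_junctions(truth, cfg)
        classified = classify_table(
            table, guide, offtarget_cuts_from_truth(truth), known_refs=set(genome)
        )
        s = summarize(classified)
        for cls, p in props.items():
            lo = stats.binom.ppf(0.005, 10_000, p)
            hi = stats.binom.ppf(0.995, 10_000, p)
            assert lo <= s.counts[cls] <= hi, cls


def offtarget_cuts_from_truth(truth):
    """Adapter: truth sites -> the calls frame dialect used by classify_table."""
    return pd.DataFrame(
        {
            "chrom": [t.chrom for t in truth.off_targets],
            "start": [t.start for t in truth.off_targets],
            "end": [t.start + 23 for t in truth.off_targets],
            "strand": [t.strand for t in truth.off_targets],
        }
    )


class TestFoldChange:
    def test_identity(self):
        s = summarize(classified_frame(["indel"] * 10 + ["uncut"] * 10))
        assert fold_change(s, s, "indel_rate") == pytest.approx(1.0)

    def test_simple_ratio(self):
        a = summarize(classified_frame(["large_deletion"] * 4 + ["uncut"] * 96))
        b = summarize(classified_frame(["large_deletion"] * 2 + ["uncut"] * 98))
        assert fold_change(a, b, "large_deletion_rate") == pytest.approx(2.0)

    def test_zero_reference_error(self):
        a = summarize(classified_frame(["indel"] * 10))
        b = summarize(classified_frame(["uncut"] * 10))
        with pytest.raises(ZeroDivisionError):
            fold_change(a, b, "indel_rate")

    def test_planted_ratio_recovered(self):
        base_tl, ratio = 0.04, 1.5
        summaries = []
        for seed, tl in ((21, base_tl), (22, base_tl * ratio)):
            cfg = SyntheticConfig(
                genome_length=120_000,
                chrom_count=2,
                planted_sites=[],
                outcome_proportions={
                    "uncut": 1 - 0.3 - tl,
                    "indel": 0.3,
                    "general_translocation": tl,
                },
                n_events=10_000,
                seed=seed,
            )
            genome, _, guide, truth = generate_reference(cfg)
            table = simulate_junctions(truth, cfg)
            summaries.append(
                summarize(classify_table(table, guide, known_refs=set(genome)))
            )
        got = fold_change(summaries[1], summaries[0], "general_translocation_rate")
        # 99% interval on the ratio from the exact binomial bounds of each count
        lo1 = stats.binom.ppf(0.005, 10_000, base_tl * ratio)
        hi1 = stats.binom.ppf(0.995, 10_000, base_tl * ratio)
        lo0 = stats.binom.ppf(0.005, 10_000, base_tl)
        hi0 = stats.binom.ppf(0.995, 10_000, base_tl)
        assert lo1 / hi0 <= got <= hi1 / lo0


class TestPlasmidProfile:
    def test_rate_arithmetic(self):
        outcomes = ["plasmid_insertion"] * 5 + ["indel"] * 9995
        df = classified_frame(outcomes, prey_pos=[50] * 5 + [0] * 9995)
        rate, _ = plasmid_profile(df, plasmid_length=3000)
        assert rate == pytest.approx(50.0)

    def test_zero_plasmid_junctions(self):
        df = classified_frame(["indel"] * 100)
        rate, profile = plasmid_profile(df, plasmid_length=1000)
        assert rate == 0.0
        assert (profile == 0).all()

    def test_planted_window_maximal_bin(self, rng):
        pos = rng.integers(700, 800, size=40).tolist() + [50, 1500]
        outcomes = ["plasmid_insertion"] * len(pos) + ["indel"] * 100
        df = classified_frame(outcomes, prey_pos=pos + [0] * 100)
        _, profile = plasmid_profile(df, plasmid_length=3000, binsize=100)
        assert profile.argmax() == 7
        assert profile[7] == 40

    def test_linearity(self):
        df1 = classified_frame(
            ["plasmid_insertion"] * 5 + ["indel"] * 95, prey_pos=[10] * 5 + [0] * 95
        )
        df2 = classified_frame(
            ["plasmid_insertion"] * 10 + ["indel"] * 95, prey_pos=[10] * 10 + [0] * 95
        )
        r1, _ = plasmid_profile(df1, 1000, denominator="on_target_indels")
        r2, _ = plasmid_profile(df2, 1000, denominator="on_target_indels")
        assert r2 == pytest.approx(2 * r1)

    def test_both_denominators(self):
        outcomes = ["plasmid_insertion"] * 2 + ["indel"] * 4 + ["large_deletion"] * 4
        df = classified_frame(outcomes, prey_pos=[10, 20] + [0] * 8)
        r_edit, _ = plasmid_profile(df, 1000, denominator="editing_events")
        r_indel, _ = plasmid_profile(df, 1000, denominator="on_target_indels")
        assert r_edit == pytest.approx(2 / 10 * 100_000)
        assert r_indel == pytest.approx(2 / 4 * 100_000)

    def test_zero_denominator_error(self):
        df = classified_frame(["uncut"] * 10)
        with pytest.raises(ZeroDivisionError):
            plasmid_profile(df, 1000)
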