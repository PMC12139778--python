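"""Five-step filtering, replicate summaries, nested genotype comparison."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import simpull_stoich as ss


class FixedLabels:
    """Stub classifier returning predetermined labels (pipeline plumbing)."""

    def __init__(self, labels):
        self.labels = np.asarray(labels)

    def classify_traces(self, raw_traces):
        return self.labels[: len(raw_traces)].copy()


def trace_tables(n, n_frames=20, seed=0):
    rng = np.random.default_rng(seed)
    g = pd.DataFrame(rng.normal(200, 5, (n_frames, n)),
                     columns=range(n))
    f = pd.DataFrame(rng.normal(200, 5, (n_frames, n)),
                     columns=range(n))
    pairs = pd.DataFrame({"pair_id": np.arange(n),
                          "green_spot_id": np.arange(n),
                          "farred_spot_id": np.arange(n),
                          "field_id": "f0"})
    return pairs, g, f


class TestRunPipeline:
    def test_filter_matches_exhaustive_predicate_enumeration(self):
        combos = list(itertools.product(ss.GREEN_CLASSES, ss.FARRED_CLASSES))
        pairs, g, f = trace_tables(len(combos))
        green = FixedLabels([c[0] for c in combos])
        farred = FixedLabels([c[1] for c in combos])
        classified, counts = ss.run_pipeline(pairs, g, f, green, farred)

        expected = {(gc, fc): (gc == "1-step" and fc != "rejected")
                    for gc, fc in combos}  # brute-force predicate
        for row in classified.itertuples():
            assert row.retained == expected[(row.green_class,
                                             row.farred_class)]
        assert counts["retained"] == sum(expected.values())
        assert counts["retained"] + counts["rejected_by_filter"] \
            == counts["classified"]
        assert counts["classified"] + counts["orphaned"] == counts["pairs_in"]

    def test_retained_examples(self):
        pairs, g, f = trace_tables(2)
        classified, _ = ss.run_pipeline(
            pairs, g, f, FixedLabels(["1-step", "1-step"]),
            FixedLabels(["rejected", "2-step"]))
        assert list(classified["retained"]) == [False, True]

    def test_orphan_pairs_are_excluded_and_counted(self):
        pairs, g, f = trace_tables(4)
        pairs.loc[2, "farred_spot_id"] = 99  # no such trace
        classified, counts = ss.run_pipeline(
            pairs, g, f, FixedLabels(["1-step"] * 4),
            FixedLabels(["2-step"] * 4))
        assert counts["orphaned"] == 1
        assert counts["classified"] == 3
        assert 2 not in classified["pair_id"].values

    def test_flagged_nan_traces_are_orphaned(self):
        pairs, g, f = trace_tables(3)
        f[1] = np.nan  # border-flagged trace
        _, counts = ss.run_pipeline(pairs, g, f,
                                    FixedLabels(["1-step"] * 3),
                                    FixedLabels(["1-step"] * 3))
        assert counts["orphaned"] == 1


def classified_frame(labels, field_id="f0"):
    return pd.DataFrame({
        "field_id": field_id,
        "green_class": "1-step",
        "farred_class": labels,
        "retained": True,
    })


def design_frame(fields):
    return ss.ReplicateDesign(pd.DataFrame(fields))


class TestSummarize:
    DESIGN = [{"field_id": "f0", "genotype": "wt", "bio_rep": 1,
               "tech_rep": 1}]

    def test_single_replicate_percentages(self):
        labels = ["1-step"] * 6 + ["2-step"] * 3 + ["3-and-higher"]
        summary = ss.summarize(classified_frame(labels),
                               design_frame(self.DESIGN))
        row = summary.technical.iloc[0]
        assert row["pct_1-step"] == 60.0
        assert row["pct_2-step"] == 30.0
        assert row["pct_3-and-higher"] == 10.0
        assert row["oligomeric_pct"] == 40.0

    def test_all_monomeric_gives_zero_oligomeric(self):
        summary = ss.summarize(classified_frame(["1-step"] * 8),
                               design_frame(self.DESIGN))
        assert summary.technical.iloc[0]["oligomeric_pct"] == 0.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(1)
        labels = rng.choice(["1-step", "2-step", "3-and-higher"], 157)
        summary = ss.summarize(classified_frame(list(labels)),
                               design_frame(self.DESIGN))
        row = summary.technical.iloc[0]
        total = sum(row[f"pct_{c}"] for c in
                    ("1-step", "2-step", "3-and-higher"))
        assert abs(total - 100.0) < 1e-9

    def test_invariant_to_pair_ordering_and_file_splitting(self):
        rng = np.random.default_rng(2)
        labels = list(rng.choice(["1-step", "2-step"], 60))
        base = classified_frame(labels)
        shuffled = base.sample(frac=1.0, random_state=3).reset_index(drop=True)
        split = pd.concat([base.iloc[:17], base.iloc[17:]],
                          ignore_index=True)
        design = design_frame(self.DESIGN)
        ref = ss.summarize(base, design).technical
        for variant in (shuffled, split):
            got = ss.summarize(variant, design).technical
            pd.testing.assert_frame_equal(ref, got)

    def test_biological_level_pools_technical_counts(self):
        design = design_frame([
            {"field_id": "a", "genotype": "wt", "bio_rep": 1, "tech_rep": 1},
            {"field_id": "b", "genotype": "wt", "bio_rep": 1, "tech_rep": 2},
        ])
        classified = pd.concat([
            classified_frame(["1-step"] * 9 + ["2-step"], field_id="a"),
            classified_frame(["2-step"] * 9 + ["1-step"], field_id="b"),
        ], ignore_index=True)
        summary = ss.summarize(classified, design)
        bio = summary.biological.iloc[0]
        assert bio["oligomeric_pct"] == 50.0          # pooled counts
        assert bio["oligomeric_pct_mean_of_tech"] == 50.0
        gen = summary.genotype.iloc[0]
        assert gen["oligomeric_pct_mean"] == 50.0

    def test_empty_replicates_are_flagged(self):
        design = design_frame(self.DESIGN + [
            {"field_id": "f1", "genotype": "wt", "bio_rep": 1,
             "tech_rep": 2}])
        summary = ss.summarize(classified_frame(["1-step"] * 4),
                               design)
        assert summary.excluded_replicates == [("wt", 1, 2)]


class TestCompareGroups:
    @staticmethod
    def technical(values_by_genotype, n_tech=1, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for gen, values in values_by_genotype.items():
            for bio, v in enumerate(values):
                for tech in range(n_tech):
                    rows.append({"genotype": gen, "bio_rep": bio,
                                 "tech_rep": tech,
                                 "oligomeric_pct": v + rng.normal(0, noise)
                                 if noise else v})
        return pd.DataFrame(rows)

    def test_identical_groups_give_f_zero_p_one(self):
        tech = self.technical({"a": [40.0, 42.0, 38.0],
                               "b": [40.0, 42.0, 38.0]})
        res = ss.compare_groups(tech)
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_balanced_nested_anova_equals_one_way_on_bio_means(self):
        tech = self.technical({"wt": [40.0, 45.0, 38.0, 41.0],
                               "mut": [28.0, 25.0, 30.0, 27.0]},
                              n_tech=5, noise=2.0, seed=4)
        res = ss.compare_groups(tech)
        means = tech.groupby(["genotype", "bio_rep"])["oligomeric_pct"].mean()
        f, p = stats.f_oneway(means["wt"].to_numpy(), means["mut"].to_numpy())
        assert abs(res.p_value - p) < 1e-9
        assert np.isclose(res.f_statistic, f)

    def test_power_to_detect_a_fifteen_point_shift(self):
        # bio-replicate SD 5, n = 9 vs 10: >90% rejections at alpha 0.05
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(200):
            tech = self.technical({
                "wt": list(rng.normal(40, 5, 10)),
                "mut": list(rng.normal(25, 5, 9))})
            if ss.compare_groups(tech).p_value < 0.05:
                rejections += 1
        assert rejections / 200 > 0.90

    def test_tukey_table_covers_all_genotype_pairs(self):
        tech = self.technical({"a": [40.0, 41.0, 39.0],
                               "b": [30.0, 31.0, 29.0],
                               "c": [40.5, 40.0, 39.5]})
        res = ss.compare_groups(tech)
        assert len(res.tukey) == 3
        ab = res.tukey[(res.tukey["group_a"] == "a")
                       & (res.tukey["group_b"] == "b")]
        assert ab["p_adj"].iloc[0] < 0.05

    def test_single_biological_replicate_is_an_error(self):
        tech = self.technical({"a": [40.0], "b": [30.0, 31.0]})
        with pytest.raises(ValueError, match="biological"):
            ss.compare_groups(tech)

    def test_single_genotype_is_an_error(self):
        tech = self.technical({"a": [40.0, 41.0]})
        with pytest.raises(ValueError, match="genotypes"):
            ss.compare_groups(tech)


def test_oracle_classified_pipeline_recovers_oligomeric_fraction():
    """Trace-level pipeline with rule-based classification is close to
    the simulated 40% oligomeric fraction (no blinking, full labeling)."""
    acq = ss.AcquisitionParams(blink_rate=0.0)
    n = 800
    truth = ss.simulate_complexes(
        ss.StoichModel(p_farred={1: 0.6, 2: 0.3, 3: 0.1}), n,
        image_shape=(4000, 4000), min_separation=0.0, seed=42)
    g, f, _ = ss.simulate_traces(truth, acq, seed=43)
    pairs = pd.DataFrame({"pair_id": np.arange(n),
                          "green_spot_id": np.arange(n),
                          "farred_spot_id": np.arange(n),
                          "field_id": "f0"})
    classified, _ = ss.run_pipeline(
        pairs, pd.DataFrame(g.T), pd.DataFrame(f.T),
        ss.RuleBasedClassifier(ss.GREEN), ss.RuleBasedClassifier(ss.FARRED))
    kept = classified[classified["retained"]]
    olig = kept["farred_class"].isin(["2-step", "3-and-higher"]).mean() * 100
    assert abs(olig - 40.0) <= 5.0
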