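"""Mann-Whitney, Bonferroni, sex-difference classification, contribution."""

import numpy as np
import pandas as pd
import pytest

from msy_seg.phenotypes import (
    bonferroni,
    classify_sex_difference,
    compare_consomic,
    contribution_fold,
    load_table3,
    mann_whitney,
    table3_class_counts,
)
from msy_seg.simulate import PhenotypeEffect, simulate_phenotypes

from _oracles import oracle_mann_whitney, oracle_mw_exact_p


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        """Complete separation at n=3 vs 3 gives the exact two-sided
        p = 2/20 over all C(6,3) relabelings."""
        u, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)
        _, p_oracle = oracle_mann_whitney([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(p_oracle)

    def test_identical_multisets_give_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("seed", range(100))
    def test_exact_branch_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        pooled = rng.permutation(np.arange(n_a + n_b, dtype=float) * 1.7 + 0.3)
        a, b = pooled[:n_a], pooled[n_a:]
        u, p = mann_whitney(a, b)
        u_o, p_o = oracle_mann_whitney(a, b)
        assert u == pytest.approx(u_o)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_approximation_close_to_exact_distribution_at_n10(self):
        """For n=10 vs 10 the tie-free normal-approximation p used above
        the exact-enumeration size limit stays within 0.01 of the exact
        null distribution (counting-recurrence oracle)."""
        rng = np.random.default_rng(42)
        a = rng.normal(0.0, 1.0, size=10)
        b = rng.normal(1.0, 1.0, size=10)
        u, p_asym = mann_whitney(a, b)
        p_exact = oracle_mw_exact_p(u, 10, 10)
        assert abs(p_asym - p_exact) < 0.01

    @pytest.mark.parametrize("seed", range(20))
    def test_symmetry_under_group_swap(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=5), rng.normal(size=7)
        u_ab, p_ab = mann_whitney(a, b)
        u_ba, p_ba = mann_whitney(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert p_ab == pytest.approx(p_ba)


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01], m=10) == [pytest.approx(0.1)]
        assert bonferroni([0.5], m=4) == [1.0]

    def test_never_decreases_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(3)
        ps = rng.random(20)
        adj = bonferroni(ps, m=25)
        assert all(a >= p for a, p in zip(adj, ps))
        assert all(0 <= a <= 1 for a in adj)
        # ordering is preserved weakly (capping at 1 may introduce ties)
        adj_by_p = np.asarray(adj)[np.argsort(ps)]
        assert (np.diff(adj_by_p) >= 0).all()

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])


class TestSexDifferenceClassification:
    def test_published_table_counts(self):
        """The packaged consomic table reproduces the published class
        counts: 15/2/10 for the FHH cross and 22/1/3 for the SS cross."""
        counts = table3_class_counts()
        assert counts["FHH-YBN/Mcwi"] == {
            "both": 15,
            "A_only": 2,
            "B_only": 10,
            "neither": 0,
        }
        assert counts["SS-YBN/Mcwi"] == {
            "both": 22,
            "A_only": 1,
            "B_only": 3,
            "neither": 0,
        }

    def test_counts_sum_to_rows(self):
        table = load_table3()
        counts = table3_class_counts(table)
        assert sum(counts["FHH-YBN/Mcwi"].values()) == 27
        assert sum(counts["SS-YBN/Mcwi"].values()) == 26
        assert len(table) == 53

    def test_all_false_flags_are_neither(self):
        df = pd.DataFrame({"a": [False] * 4, "b": [False] * 4})
        counts, labels = classify_sex_difference(df, "a", "b")
        assert counts == {"both": 0, "A_only": 0, "B_only": 0, "neither": 4}
        assert (labels == "neither").all()

    def test_missing_flag_is_an_error(self):
        df = pd.DataFrame({"a": [True, None], "b": [True, False]})
        with pytest.raises(ValueError, match="missing"):
            classify_sex_difference(df, "a", "b")


class TestContributionFold:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["chromosome", "n_significant", "n_measured", "size_mb", "n_genes"]
        )

    def test_uniform_table_gives_fold_one(self):
        table = self._table(
            [("chr1", 5, 100, 50, 500), ("chr2", 5, 100, 50, 500), ("chrY", 5, 100, 50, 500)]
        )
        rec = contribution_fold(table, "chrY")
        assert rec.fold_vs_mean_per_mb == pytest.approx(1.0)
        assert rec.fold_vs_max_per_10_genes == pytest.approx(1.0)

    def test_tenfold_fraction_at_equal_size(self):
        table = self._table(
            [("chr1", 2, 100, 50, 500), ("chr2", 2, 100, 50, 500), ("chrY", 20, 100, 50, 500)]
        )
        rec = contribution_fold(table, "chrY")
        assert rec.fold_vs_mean_per_mb == pytest.approx(10.0)
        assert rec.fold_vs_max_per_mb == pytest.approx(10.0)

    def test_hand_computed_two_panel_style_table(self):
        # chrY: (20/100)/2 = 0.1 per Mb; chr1: (4/100)/50 = 8e-4; chr2: (6/120)/40 = 1.25e-3
        table = self._table(
            [("chr1", 4, 100, 50, 600), ("chr2", 6, 120, 40, 400), ("chrY", 20, 100, 2, 20)]
        )
        rec = contribution_fold(table, "chrY")
        per_mb = {"chr1": 8e-4, "chr2": 1.25e-3, "chrY": 0.1}
        assert rec.fold_vs_mean_per_mb == pytest.approx(
            per_mb["chrY"] / np.mean([per_mb["chr1"], per_mb["chr2"]])
        )
        assert rec.fold_vs_max_per_mb == pytest.approx(per_mb["chrY"] / per_mb["chr2"])
        per_10 = {"chr1": (4 / 100) / 60, "chr2": (6 / 120) / 40, "chrY": (20 / 100) / 2}
        assert rec.fold_vs_max_per_10_genes == pytest.approx(per_10["chrY"] / per_10["chr2"])

    def test_unmeasured_chromosome_skipped_with_warning(self):
        table = self._table(
            [("chr1", 5, 100, 50, 500), ("chr3", 0, 0, 30, 300), ("chrY", 5, 100, 50, 500)]
        )
        with pytest.warns(UserWarning, match="chr3"):
            rec = contribution_fold(table, "chrY")
        assert rec.skipped == ["chr3"]


class TestSimulatedPhenotypePipeline:
    def test_null_sex_effect_rejects_at_nominal_rate(self):
        """With zero sex effect the male-female Mann-Whitney rejects in
        roughly alpha of replicates (type-I control)."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a, b = rng.normal(size=(2, 10))
            _, p = mann_whitney(a, b)
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.01 <= rate <= 0.09

    def test_large_sex_effect_always_detected(self):
        """A 5-SD sex effect at n=10 is classified significant in >=99 %
        of replicates."""
        effects = [
            PhenotypeEffect(
                "bp", "control", baseline=100.0,
                strain_effects={"S": 0.0}, sex_effects=5.0, noise_sd=1.0, n_per_group=10,
            )
        ]
        detected = 0
        n_rep = 200
        for seed in range(n_rep):
            df = simulate_phenotypes(effects, seed=seed)
            males = df.loc[df["sex"] == "male", "value"]
            females = df.loc[df["sex"] == "female", "value"]
            _, p = mann_whitney(males, females)
            detected += p < 0.05
        assert detected / n_rep >= 0.99

    def test_consomic_comparison_report(self):
        effects = [
            PhenotypeEffect(
                "bp", "control", baseline=100.0,
                strain_effects={"P": 0.0, "C": 8.0}, noise_sd=1.0,
            ),
            PhenotypeEffect(
                "hr", "control", baseline=300.0,
                strain_effects={"P": 0.0, "C": 0.0}, noise_sd=5.0,
            ),
        ]
        df = simulate_phenotypes(effects, seed=5)
        report = compare_consomic(df, "C", "P", family_size=131)
        by_phen = report.set_index("phenotype")
        assert bool(by_phen.loc["bp", "significant"])
        assert not bool(by_phen.loc["hr", "significant"])
        # Bonferroni against the full 131-phenotype family
        assert by_phen.loc["bp", "p_adj"] == pytest.approx(
            min(1.0, by_phen.loc["bp", "p_raw"] * 131)
        )
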