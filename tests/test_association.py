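import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from pyroppi.association import (
    association_scan,
    checkpoint_correlation,
    compute_tmb,
    correlate,
    diff_expression_log2ratio,
    mutation_frequency,
    subtype_compare,
)
from pyroppi.cohort import StratumSkipped


class TestCorrelate:
    def test_monotone_spearman_is_one(self):
        res = correlate([1, 2, 3], [2, 4, 6], method="spearman")
        assert res.coefficient == pytest.approx(1.0)

    def test_antitone_spearman_is_minus_one(self):
        res = correlate([1, 2, 3], [3, 2, 1], method="spearman")
        assert res.coefficient == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        res = correlate([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.flag == "constant_input"
        assert np.isnan(res.coefficient)

    def test_missing_values_pairwise_dropped(self):
        res = correlate([1, 2, np.nan, 4, 5], [2, 4, 6, 8, np.nan])
        assert res.n == 3

    def test_exact_permutation_p_matches_enumeration(self):
        # 8 distinct pairs: compare against a literal loop over all 8!
        # pairings of the y-ranks
        from itertools import permutations

        rng = np.random.default_rng(41)
        x = rng.normal(size=8)
        y = 0.6 * x + rng.normal(0, 1, size=8)
        res = correlate(x, y, method="spearman")
        rx, ry = rankdata(x), rankdata(y)
        rx_c = (rx - rx.mean()) / rx.std()
        ry_c = (ry - ry.mean()) / ry.std()
        obs = float(rx_c @ ry_c) / 8
        count = total = 0
        for perm in permutations(range(8)):
            rho = float(rx_c[list(perm)] @ ry_c) / 8
            total += 1
            if abs(rho) >= abs(obs) - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(43)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = correlate(x, y, method="spearman")
        warped = correlate(np.exp(x), y ** 3 + 5 * y, method="spearman")
        assert warped.coefficient == pytest.approx(base.coefficient, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            correlate([1, 2], [2, 1])


class TestAssociationScan:
    @staticmethod
    def planted(n=200, coupling=0.5, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, size=n)
        samples = [f"s{i}" for i in range(n)]
        ppi = pd.DataFrame({"ppi": a + rng.normal(0, 0.05, n)},
                           index=pd.Index(samples, name="sample"))
        scores = pd.DataFrame({
            "immune_score": coupling * a + rng.normal(0, 0.1, n),
            "tumor_purity": np.clip(1 - coupling * a + rng.normal(0, 0.1, n), 0, 1),
        }, index=ppi.index)
        return ppi, scores

    def test_recovers_planted_signs(self):
        ppi, scores = self.planted()
        res, _ = association_scan(ppi, scores)
        res = res.set_index("variable")
        assert res.loc["immune_score", "coefficient"] > 0
        assert res.loc["immune_score", "p"] < 0.05
        assert res.loc["tumor_purity", "coefficient"] < 0
        assert res.loc["tumor_purity", "p"] < 0.05

    def test_absent_variable_logged(self):
        ppi, scores = self.planted(n=20)
        res, skips = association_scan(ppi, scores, variables=["immune_score", "ghost"])
        assert "pan/ghost" in skips
        assert set(res["variable"]) == {"immune_score"}


class TestCheckpointCorrelation:
    def test_planted_gene_positive_and_invariance(self):
        rng = np.random.default_rng(47)
        n = 100
        a = rng.uniform(0, 1, n)
        samples = [f"s{i}" for i in range(n)]
        ppi = pd.DataFrame({"ppi": a}, index=pd.Index(samples, name="sample"))
        expr = pd.DataFrame({
            s: [2 * ai + rng.normal(0, 0.2), rng.normal(), 1.0]
            for s, ai in zip(samples, a)
        }, index=["PDCD1", "OTHER", "FLAT"])
        res = checkpoint_correlation(ppi, expr, ["PDCD1", "FLAT", "GHOST"])
        res = res.set_index("gene")
        assert res.loc["PDCD1", "coefficient"] > 0.8
        assert res.loc["FLAT", "flag"] == "constant_input"
        assert res.loc["GHOST", "flag"] == "missing"
        # identically permuting sample order leaves r unchanged
        perm = rng.permutation(samples)
        res2 = checkpoint_correlation(ppi.loc[perm], expr[perm], ["PDCD1"])
        assert res2.loc[0, "coefficient"] == pytest.approx(
            res.loc["PDCD1", "coefficient"], abs=1e-12)


class TestSubtypes:
    @staticmethod
    def cohort(ppis_by_subtype, seed=0):
        rng = np.random.default_rng(seed)
        rows_p, rows_a, samples = [], [], []
        i = 0
        for subtype, values in ppis_by_subtype.items():
            for v in values:
                samples.append(f"s{i}")
                rows_p.append(v)
                rows_a.append(subtype)
                i += 1
        ppi = pd.DataFrame({"ppi": rows_p}, index=pd.Index(samples, name="sample"))
        ann = pd.DataFrame({"cancer_type": "X", "tissue": "tumor",
                            "patient_id": samples, "immune_subtype": rows_a},
                           index=ppi.index)
        return ppi, ann

    def test_identical_distributions_null(self):
        vals = list(np.arange(10.0))
        ppi, ann = self.cohort({"C1": vals, "C2": vals, "C3": vals})
        res = subtype_compare(ppi, ann)
        assert res["kruskal_p"] > 0.9

    def test_planted_ordering_recovered(self):
        rng = np.random.default_rng(53)
        ppi, ann = self.cohort({
            "C2": list(3 + rng.normal(0, 0.2, 15)),
            "C3": list(2 + rng.normal(0, 0.2, 15)),
            "C4": list(1 + rng.normal(0, 0.2, 15)),
        })
        res = subtype_compare(ppi, ann)
        med = res["medians"]
        assert med["C2"] > med["C3"] > med["C4"]
        assert res["kruskal_p"] < 0.01

    def test_singleton_subtype_excluded(self):
        ppi, ann = self.cohort({"C1": [1, 2, 3], "C2": [4, 5, 6], "C5": [9]})
        res = subtype_compare(ppi, ann)
        assert res["excluded_subtypes"] == ["C5"]

    def test_single_subtype_skipped(self):
        ppi, ann = self.cohort({"C1": [1, 2, 3, 4]})
        with pytest.raises(StratumSkipped):
            subtype_compare(ppi, ann)


class TestTmb:
    def test_worked_example_76_rows_over_38_mb(self):
        mut = pd.DataFrame({
            "sample": ["s1"] * 76,
            "gene": [f"g{i}" for i in range(76)],
            "variant_classification": ["Missense_Mutation"] * 76,
        })
        tmb, _ = compute_tmb(mut, ["s1"], exome_mb=38.0)
        assert tmb["s1"] == pytest.approx(2.0)

    def test_absent_sample_zero(self):
        mut = pd.DataFrame(columns=["sample", "gene", "variant_classification"])
        tmb, _ = compute_tmb(mut, ["s1", "s2"])
        assert (tmb == 0).all()

    def test_silent_rows_excluded_from_numerator(self):
        mut = pd.DataFrame({
            "sample": ["s1"] * 10,
            "gene": [f"g{i}" for i in range(10)],
            "variant_classification": ["Silent"] * 4 + ["Missense_Mutation"] * 6,
        })
        tmb, _ = compute_tmb(mut, ["s1"], exome_mb=1.0)
        assert tmb["s1"] == pytest.approx(6.0)

    def test_unknown_class_counted_in_qc(self):
        mut = pd.DataFrame({
            "sample": ["s1", "s1"],
            "gene": ["a", "b"],
            "variant_classification": ["Missense_Mutation", "Weird_Class"],
        })
        tmb, qc = compute_tmb(mut, ["s1"], exome_mb=1.0)
        assert tmb["s1"] == 1.0
        assert qc["rows_unknown_class"] == 1
        assert qc["unknown_classes"] == ["Weird_Class"]

    def test_additive_over_disjoint_splits(self):
        rng = np.random.default_rng(59)
        mut = pd.DataFrame({
            "sample": rng.choice(["s1", "s2", "s3"], 50),
            "gene": rng.choice([f"g{i}" for i in range(20)], 50),
            "variant_classification": rng.choice(
                ["Missense_Mutation", "Silent", "Nonsense_Mutation"], 50),
        })
        samples = ["s1", "s2", "s3"]
        whole, _ = compute_tmb(mut, samples)
        first, _ = compute_tmb(mut.iloc[:25], samples)
        second, _ = compute_tmb(mut.iloc[25:], samples)
        pd.testing.assert_series_equal(whole, first + second)

    def test_fixture_six_nonsynonymous_rows(self, fixture_cohort):
        ann = fixture_cohort.clinical
        tmb, _ = compute_tmb(fixture_cohort.mutations,
                             ann.index[ann["tissue"] == "tumor"], exome_mb=38.0)
        assert tmb["P1T"] == pytest.approx(2 / 38)
        assert tmb["P4T"] == pytest.approx(0.0)  # only a Silent row
        assert tmb.sum() == pytest.approx(6 / 38)


class TestMutationFrequency:
    def test_fraction_and_dedup(self):
        ann = pd.DataFrame({"cancer_type": "X", "tissue": "tumor",
                            "patient_id": list("abcd")},
                           index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"))
        mut = pd.DataFrame({
            "sample": ["s1", "s1", "s1", "s2"],
            "gene": ["TP53", "TP53", "TP53", "TP53"],
            "variant_classification": ["Missense_Mutation"] * 4,
        })
        freq = mutation_frequency(mut, ann, ["TP53", "GHOST"]).set_index("gene")
        assert freq.loc["TP53", "frequency"] == pytest.approx(0.5)
        assert freq.loc["GHOST", "frequency"] == 0.0


class TestLog2Ratio:
    def test_back_transform_matches_hand_oracle(self):
        # tumor linear means 8, normal 2 -> log2 ratio 2.0
        samples = ["t1", "t2", "n1", "n2"]
        expr = pd.DataFrame(
            {s: [np.log2(v + 1)] for s, v in zip(samples, [8.0, 8.0, 2.0, 2.0])},
            index=["G"])
        expr.loc["PAD"] = 1.0
        ann = pd.DataFrame({"cancer_type": "X",
                            "tissue": ["tumor", "tumor", "normal", "normal"],
                            "patient_id": list("abcd")},
                           index=pd.Index(samples, name="sample"))
        res = diff_expression_log2ratio(expr, ann, ["G"]).set_index("gene")
        assert res.loc["G", "log2_ratio"] == pytest.approx(2.0)

    def test_equal_means_zero_and_zero_normal_flagged(self):
        samples = ["t1", "t2", "n1", "n2"]
        ann = pd.DataFrame({"cancer_type": "X",
                            "tissue": ["tumor", "tumor", "normal", "normal"],
                            "patient_id": list("abcd")},
                           index=pd.Index(samples, name="sample"))
        expr = pd.DataFrame({s: [np.log2(4 + 1)] for s in samples}, index=["EQ"])
        expr.loc["ZN"] = [np.log2(3 + 1), np.log2(5 + 1), 0.0, 0.0]
        res = diff_expression_log2ratio(expr, ann, ["EQ", "ZN"]).set_index("gene")
        assert res.loc["EQ", "log2_ratio"] == pytest.approx(0.0)
        assert res.loc["ZN", "flag"] == "zero_normal_mean"
        assert res.loc["ZN", "log2_ratio"] > 20  # pseudocount denominator
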