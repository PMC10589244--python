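import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from pyroppi.cohort import (
    StratumSkipped,
    clinical_association,
    cox_partial_loglik,
    cox_univariate,
    diff_ppi_paired,
    diff_ppi_unpaired,
    logrank_test,
    split_groups,
    survival_scan,
    validate_annotations,
)
from pyroppi.simulate import SimulationConfig, simulate_survival
from tests.conftest import (
    enumerate_ranksum_p,
    enumerate_signed_rank_p,
    logrank_chi2_oracle,
)


def make_tables(tumor_ppi, normal_ppi, stratum="X"):
    samples = [f"t{i}" for i in range(len(tumor_ppi))] + \
              [f"n{i}" for i in range(len(normal_ppi))]
    ppi = pd.DataFrame({"ppi": list(tumor_ppi) + list(normal_ppi)},
                       index=pd.Index(samples, name="sample"))
    ann = pd.DataFrame({
        "cancer_type": stratum,
        "tissue": ["tumor"] * len(tumor_ppi) + ["normal"] * len(normal_ppi),
        "patient_id": [f"p{i}" for i in range(len(tumor_ppi))] +
                      [f"p{i}" for i in range(len(normal_ppi))],
    }, index=ppi.index)
    return ppi, ann


class TestUnpairedDiff:
    def test_separated_groups_exact_p(self):
        ppi, ann = make_tables([4, 5, 6], [1, 2, 3])
        res = diff_ppi_unpaired(ppi, ann, "X")
        assert res.p == pytest.approx(0.1)  # 2 / C(6,3) = 2/20

    def test_identical_multisets_p_one(self):
        ppi, ann = make_tables([1, 2, 3], [1, 2, 3])
        # combined ties force the asymptotic branch; p must be ~1
        res = diff_ppi_unpaired(ppi, ann, "X")
        assert res.p == pytest.approx(1.0, abs=0.05)

    def test_single_vs_single_no_resolution(self):
        ppi, ann = make_tables([2.0], [1.0])
        assert diff_ppi_unpaired(ppi, ann, "X").p == pytest.approx(1.0)

    def test_empty_group_skipped(self):
        ppi, ann = make_tables([1, 2, 3], [])
        with pytest.raises(StratumSkipped):
            diff_ppi_unpaired(ppi, ann, "X")

    def test_exact_p_matches_enumeration_small_n(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 6))
            x = rng.permutation(np.arange(1.0, nx + ny + 1))[:nx]
            y = np.setdiff1d(np.arange(1.0, nx + ny + 1), x)[:ny]
            ppi, ann = make_tables(x, y)
            res = diff_ppi_unpaired(ppi, ann, "X")
            assert res.p == pytest.approx(enumerate_ranksum_p(x, y), abs=1e-10)


class TestPairedDiff:
    @staticmethod
    def paired_tables(diffs):
        n = len(diffs)
        samples = [f"p{i}{s}" for i in range(n) for s in ("t", "n")]
        base = np.arange(1.0, n + 1) * 10
        values = []
        for i, d in enumerate(diffs):
            values += [base[i] + d, base[i]]
        ppi = pd.DataFrame({"ppi": values}, index=pd.Index(samples, name="sample"))
        ann = pd.DataFrame({
            "cancer_type": "X",
            "tissue": ["tumor", "normal"] * n,
            "patient_id": [f"p{i}" for i in range(n) for _ in range(2)],
        }, index=ppi.index)
        return ppi, ann

    def test_all_positive_differences_exact(self):
        ppi, ann = self.paired_tables([1, 2, 3])
        res = diff_ppi_paired(ppi, ann, "X")
        assert res.p == pytest.approx(0.25)  # 2/8 sign assignments

    def test_symmetric_differences_p_one(self):
        ppi, ann = self.paired_tables([1, -1])
        assert diff_ppi_paired(ppi, ann, "X").p == pytest.approx(1.0)

    def test_all_zero_differences_skipped(self):
        ppi, ann = self.paired_tables([0, 0, 0])
        with pytest.raises(StratumSkipped, match="zero"):
            diff_ppi_paired(ppi, ann, "X")

    def test_exact_p_matches_sign_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            diffs = rng.permutation(np.arange(1, 8, dtype=float))[
                : int(rng.integers(3, 8))]
            diffs *= rng.choice([-1, 1], size=len(diffs))
            ppi, ann = self.paired_tables(list(diffs))
            res = diff_ppi_paired(ppi, ann, "X")
            assert res.p == pytest.approx(enumerate_signed_rank_p(diffs), abs=1e-10)

    def test_fixture_pairs_match_enumeration(self, fixture_cohort):
        from pyroppi.scoring import compute_ppi

        ppi = compute_ppi(fixture_cohort.expression, fixture_cohort.catalog)
        res = diff_ppi_paired(ppi, fixture_cohort.clinical, "FIXT")
        diffs = [
            ppi.loc[f"P{i}T", "ppi"] - ppi.loc[f"P{i}N", "ppi"] for i in range(1, 5)
        ]
        assert res.p == pytest.approx(enumerate_signed_rank_p(diffs), abs=1e-10)


class TestSplitGroups:
    @staticmethod
    def tumor_ppi(values, stratum="X"):
        samples = [f"s{i}" for i in range(len(values))]
        ppi = pd.DataFrame({"ppi": values}, index=pd.Index(samples, name="sample"))
        ann = pd.DataFrame({"cancer_type": stratum, "tissue": "tumor",
                            "patient_id": samples}, index=ppi.index)
        return ppi, ann

    def test_median_split_above_threshold_high(self):
        ppi, ann = self.tumor_ppi([1.0, 2.0, 3.0, 4.0])
        groups = split_groups(ppi, ann, rule="median")
        assert set(groups.index[groups["group"] == "low"]) == {"s0", "s1"}
        assert set(groups.index[groups["group"] == "high"]) == {"s2", "s3"}

    def test_ties_at_median_go_low_then_skip(self):
        ppi, ann = self.tumor_ppi([1.0, 1.0, 1.0, 5.0])
        with pytest.raises(StratumSkipped):
            split_groups(ppi, ann, rule="median")

    def test_top_bottom_30_ceiling(self):
        ppi, ann = self.tumor_ppi(list(np.arange(10.0)))
        groups = split_groups(ppi, ann, rule="top_bottom_30")
        counts = groups["group"].value_counts()
        assert counts["high"] == 3 and counts["low"] == 3
        assert len(groups) == 6  # 4 discarded

    def test_mean_rule_recorded(self):
        ppi, ann = self.tumor_ppi([0.0, 1.0, 9.0, 10.0])
        groups = split_groups(ppi, ann, rule="mean")
        assert (groups["rule"] == "mean").all()
        assert set(groups.index[groups["group"] == "high"]) == {"s2", "s3"}


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = ["a", "a", "a", "b", "b", "b"]
        res = logrank_test(t, e, g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle(self):
        t = [1, 2, 3, 3]
        e = [1, 1, 0, 0]
        g = ["a", "a", "b", "b"]
        res = logrank_test(t, e, g)
        assert res.chi2 == pytest.approx(logrank_chi2_oracle(t, e, g), rel=1e-9)

    def test_oracle_on_random_data_with_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(8, 30))
            t = rng.integers(1, 8, size=n).astype(float)
            e = rng.integers(0, 2, size=n)
            g = rng.choice(["a", "b"], size=n)
            if e.sum() == 0 or len(np.unique(g)) < 2:
                continue
            res = logrank_test(t, e, g)
            assert res.chi2 == pytest.approx(logrank_chi2_oracle(t, e, g), rel=1e-8)

    def test_all_censored_sentinel(self):
        res = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert np.isnan(res.chi2) and res.n_events == 0

    def test_relabeling_invariance_and_late_censor(self):
        t = [1.0, 2, 4, 5, 6, 7, 8]
        e = [1, 1, 0, 1, 0, 1, 0]
        g = ["a", "b", "a", "b", "a", "b", "a"]
        base = logrank_test(t, e, g)
        flipped = logrank_test(t, e, ["b" if x == "a" else "a" for x in g])
        assert base.chi2 == pytest.approx(flipped.chi2, rel=1e-12)
        # pushing an already-censored subject's time further past the last
        # event leaves every risk set at the event times unchanged
        extended = logrank_test(t[:-1] + [999.0], e, g)
        assert extended.chi2 == pytest.approx(base.chi2, rel=1e-12)


class TestCox:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate([1, 2, 3, 4], [1, 1, 1, 0], [2, 2, 2, 2])

    def test_binary_covariate_matches_grid_search(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        e = [1, 1, 1, 1, 1, 0]
        x = [1.0, 0.0, 1.0, 0.0, 1.0, 0.0]
        res = cox_univariate(t, e, x)
        grid = np.linspace(-5, 5, 100001)
        ll = np.array([cox_partial_loglik(b, t, e, x) for b in grid])
        assert res.coef == pytest.approx(grid[ll.argmax()], abs=1e-4)

    def test_negating_covariate_inverts_hr(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=40)
        cfg = SimulationConfig(seed=0)
        t, e = simulate_survival(x, 0.7, cfg, rng)
        res = cox_univariate(t, e, x)
        neg = cox_univariate(t, e, -x)
        assert neg.hr == pytest.approx(1.0 / res.hr, rel=1e-6)

    def test_score_zero_at_estimate(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=60)
        cfg = SimulationConfig(seed=0)
        t, e = simulate_survival(x, 0.5, cfg, rng)
        res = cox_univariate(t, e, x)
        eps = 1e-6
        ll_plus = cox_partial_loglik(res.coef + eps, t, e, x)
        ll_minus = cox_partial_loglik(res.coef - eps, t, e, x)
        assert (ll_plus - ll_minus) / (2 * eps) == pytest.approx(0.0, abs=1e-6)

    def test_agrees_with_lifelines_without_ties(self):
        rng = np.random.default_rng(29)
        x = rng.normal(size=80)
        cfg = SimulationConfig(seed=0)
        t, e = simulate_survival(x, 0.6, cfg, rng)
        res = cox_univariate(t, e, x)
        cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert res.coef == pytest.approx(float(cph.params_["x"]), abs=1e-6)
        assert res.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-6)


class TestSurvivalScan:
    @staticmethod
    def hazard_cohort(beta, n=300, seed=0):
        rng = np.random.default_rng(seed)
        cfg = SimulationConfig(seed=0, censor_rate=0.2)
        score = rng.uniform(0, 1, size=n)
        t, e = simulate_survival(score, beta, cfg, rng)
        samples = [f"s{i}" for i in range(n)]
        ppi = pd.DataFrame({"ppi": score}, index=pd.Index(samples, name="sample"))
        ann = pd.DataFrame({
            "cancer_type": "SIM", "tissue": "tumor", "patient_id": samples,
            "os_time": t, "os_event": e,
        }, index=ppi.index)
        return ppi, ann

    def test_recovers_adverse_hazard(self):
        ppi, ann = self.hazard_cohort(beta=1.5)
        scan, _ = survival_scan(ppi, ann, endpoints=("os",))
        row = scan.iloc[0]
        assert row["hr"] > 1
        assert row["direction"] == "adverse"
        assert row["logrank_p_bh"] < 0.05

    def test_zero_event_endpoint_logged_not_reported(self):
        ppi, ann = self.hazard_cohort(beta=0.5, n=50)
        ann["dss_time"] = ann["os_time"]
        ann["dss_event"] = 0
        scan, skips = survival_scan(ppi, ann, endpoints=("os", "dss"))
        assert set(scan["endpoint"]) == {"OS"}
        assert "SIM/dss" in skips


class TestClinicalAssociation:
    def test_identical_distribution_across_sexes(self):
        samples = [f"s{i}" for i in range(8)]
        ppi = pd.DataFrame({"ppi": [1, 2, 3, 4, 1, 2, 3, 4]},
                           index=pd.Index(samples, name="sample"))
        ann = pd.DataFrame({
            "cancer_type": "X", "tissue": "tumor", "patient_id": samples,
            "sex": ["male"] * 4 + ["female"] * 4,
        }, index=ppi.index)
        res = clinical_association(ppi, ann, "sex")
        assert res["p"] == pytest.approx(1.0, abs=0.05)

    def test_chi_square_diagonal_contingency(self):
        samples = [f"s{i}" for i in range(20)]
        ppi = pd.DataFrame({"ppi": np.arange(20.0)},
                           index=pd.Index(samples, name="sample"))
        ann = pd.DataFrame({
            "cancer_type": "X", "tissue": "tumor", "patient_id": samples,
            "sex": ["male"] * 10 + ["female"] * 10,
        }, index=ppi.index)
        groups = pd.DataFrame({
            "group": ["low"] * 10 + ["high"] * 10,
            "cancer_type": "X",
        }, index=ppi.index)
        res = clinical_association(ppi, ann, "sex", groups=groups)
        # [[10, 0], [0, 10]] -> n(ad-bc)^2 / row/col products = 20
        assert res["chi2"] == pytest.approx(20.0)

    def test_three_level_variable_uses_kruskal(self):
        rng = np.random.default_rng(31)
        samples = [f"s{i}" for i in range(30)]
        ppi = pd.DataFrame({"ppi": rng.normal(size=30)},
                           index=pd.Index(samples, name="sample"))
        ann = pd.DataFrame({
            "cancer_type": "X", "tissue": "tumor", "patient_id": samples,
            "grade": rng.choice(["G1", "G2", "G3"], size=30),
        }, index=ppi.index)
        res = clinical_association(ppi, ann, "grade")
        assert res["test"] == "kruskal_wallis"


class TestValidation:
    def test_zero_times_shifted_negative_rejected(self):
        ann = pd.DataFrame({
            "cancer_type": ["X", "X"], "tissue": ["tumor", "tumor"],
            "os_time": [0.0, 10.0], "os_event": [1, 0],
        }, index=pd.Index(["a", "b"], name="sample"))
        out = validate_annotations(ann)
        assert out.loc["a", "os_time"] == 0.5
        ann.loc["a", "os_time"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            validate_annotations(ann)
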