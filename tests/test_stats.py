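import numpy as np
import pytest
from scipy import stats as sps

from myoinvade import stats as st


class TestDiagnosticSummary:
    def test_published_t1w_counts(self):
        pred = ["IA"] * 33 + ["IB"] * 15
        true = ["IA"] * 30 + ["IB"] * 3 + ["IA"] * 7 + ["IB"] * 8
        s = st.diagnostic_summary(pred, true)
        assert s.accuracy == pytest.approx(38 / 48)
        assert (s.n_over, s.n_under) == (7, 3)
        assert s.over_diagnosis_rate == pytest.approx(0.700)

    def test_published_radiologist_counts(self):
        pred = ["IA"] * 41 + ["IB"] * 31
        true = ["IA"] * 39 + ["IB"] * 2 + ["IA"] * 14 + ["IB"] * 17
        s = st.diagnostic_summary(pred, true)
        assert s.accuracy == pytest.approx(56 / 72)
        assert s.over_diagnosis_rate == pytest.approx(14 / 16)

    def test_all_correct_flags_undefined_rates(self):
        s = st.diagnostic_summary(["IA", "IB"], ["IA", "IB"])
        assert s.accuracy == 1.0
        assert s.over_diagnosis_rate == 0.0
        assert "no_incompatible_cases" in s.flags

    def test_counts_conserved_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 60))
            pred = rng.choice(["IA", "IB"], size=n).tolist()
            true = rng.choice(["IA", "IB"], size=n).tolist()
            s = st.diagnostic_summary(pred, true)
            assert s.n_compatible + s.n_over + s.n_under == s.n == n

    def test_bad_labels_and_lengths(self):
        with pytest.raises(ValueError):
            st.diagnostic_summary(["IA"], ["IA", "IB"])
        with pytest.raises(ValueError):
            st.diagnostic_summary(["II"], ["IA"])


class TestPearsonChi2:
    def test_reader_comparison_reproduces_published_values(self):
        res = st.pearson_chi2(st.ContingencyTable2x2(38, 10, 56, 16))
        assert round(res.chi2, 3) == 0.033
        assert round(res.p, 3) == 0.856

    def test_leiomyoma_effect_p_value(self):
        res = st.pearson_chi2(st.ContingencyTable2x2(9, 6, 29, 4))
        assert round(res.p, 3) == 0.027

    def test_perfect_independence(self):
        res = st.pearson_chi2(st.ContingencyTable2x2(10, 10, 10, 10))
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_matches_uncorrected_reference_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a, b, c, d = (int(v) for v in rng.integers(1, 40, size=4))
            ours = st.pearson_chi2(st.ContingencyTable2x2(a, b, c, d))
            ref_chi2, ref_p, ref_df, _ = sps.chi2_contingency(
                [[a, b], [c, d]], correction=False)
            assert ours.chi2 == pytest.approx(ref_chi2)
            assert ours.p == pytest.approx(ref_p)
            assert ours.df == ref_df

    def test_zero_margin_rejected_and_low_expected_flagged(self):
        with pytest.raises(ValueError, match="margin"):
            st.pearson_chi2(st.ContingencyTable2x2(0, 0, 5, 5))
        assert st.pearson_chi2(st.ContingencyTable2x2(2, 3, 3, 2)).low_expected


class TestCorrelation:
    def test_exact_linear_relationships(self):
        x = np.arange(10.0)
        assert st.pearson_correlation(x, 2 * x + 1).r == pytest.approx(1.0)
        assert st.pearson_correlation([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        res = st.pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            st.pearson_correlation([1, 2], [1, 2])
        with pytest.raises(ValueError):
            st.pearson_correlation([1, 1, 1], [1, 2, 3])


class TestAnova:
    def test_hand_decomposed_example(self):
        res = st.oneway_anova([[1, 2, 3], [2, 3, 4]])
        assert res.F == pytest.approx(1.5)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p == pytest.approx(sps.f.sf(1.5, 1, 4))
        assert round(res.p, 3) == 0.288

    def test_identical_groups_give_f_zero(self):
        assert st.oneway_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]]).F == 0.0
        res = st.oneway_anova([[5.0, 5.0], [5.0, 5.0]])
        assert res.F == 0.0 and res.p == 1.0

    def test_zero_within_variance_flagged(self):
        res = st.oneway_anova([[1, 1], [2, 2]])
        assert res.p == 0.0
        assert "zero_within_group_variance" in res.flags

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            a = rng.normal(size=int(rng.integers(3, 12)))
            b = rng.normal(loc=0.5, size=int(rng.integers(3, 12)))
            res = st.oneway_anova([a, b])
            t = sps.ttest_ind(a, b, equal_var=True)
            assert res.F == pytest.approx(t.statistic**2)
            assert res.p == pytest.approx(t.pvalue)

    def test_matches_reference_on_many_groups(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc=m, size=8) for m in (0.0, 0.3, 1.0)]
        res = st.oneway_anova(groups)
        ref = sps.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestFiveNumber:
    def test_examples(self):
        fn = st.five_number_summary([1, 2, 3, 4, 5])
        assert (fn.min, fn.q1, fn.median, fn.q3, fn.max) == (1, 2, 3, 4, 5)
        fn = st.five_number_summary([0, 0.5, 1])
        assert (fn.q1, fn.q3) == (0.25, 0.75)
        fn = st.five_number_summary([7.0])
        assert fn.min == fn.q1 == fn.median == fn.q3 == fn.max == 7.0

    def test_ordering_invariant_on_random_data(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            fn = st.five_number_summary(rng.normal(size=int(rng.integers(1, 50))))
            assert fn.min <= fn.q1 <= fn.median <= fn.q3 <= fn.max

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.five_number_summary([])


class TestPrintedTables:
    def test_all_asserted_statistics_reproduce(self):
        report = st.reproduce_printed_tables()
        asserted = report[report["asserted"]]
        assert asserted["match"].all()
        # the three known in-source inconsistencies are reported, unasserted
        known = report[~report["asserted"]]
        assert len(known["name"].unique()) == 3

    def test_headline_accuracies(self):
        report = st.reproduce_printed_tables().set_index(["name", "quantity"])
        acc = report["computed"]
        assert round(acc[("ai_t1w", "accuracy_pct")], 1) == 79.2
        assert round(acc[("ai_t2w", "accuracy_pct")], 1) == 70.8
        assert round(acc[("radiologists", "accuracy_pct")], 1) == 77.8


def test_cohort_report_structure_and_conservation():
    rng = np.random.default_rng(5)
    true_f = rng.uniform(0, 1, size=40)
    pred_f = np.clip(true_f + rng.normal(0, 0.05, size=40), 0, 1)
    true_s = ["IB" if f >= 0.5 else "IA" for f in true_f]
    pred_s = ["IB" if f >= 0.5 else "IA" for f in pred_f]
    lm = rng.uniform(size=40) < 0.4
    rep = st.cohort_report(pred_s, true_s, pred_fractions=pred_f,
                           true_fractions=true_f, leiomyoma_flags=lm)
    assert rep.conservation_ok()
    assert rep.correlation is not None and rep.correlation.r > 0.8
    assert set(rep.by_leiomyoma) == {"present", "absent"}
    assert "compatible" in rep.fraction_summaries
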