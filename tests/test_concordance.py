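"""Confusion-table construction, Wilson CIs, kappa, technique agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctfusion.concordance import (
    ConfusionTable,
    build_confusion,
    cohen_kappa,
    compare_techniques,
    concordance_fraction,
    mann_whitney_counts,
    pool_tables,
    proportion_ci,
    reconcile_marginals,
    sensitivity_specificity,
)


def make_cohort_calls():
    """The clinical detection pattern: 56 samples with tissue truth
    14 ALK / 9 ROS1 / 12 RET / 5 MET + 16 controls, of which 10/6/7/5 are
    detected in the liquid biopsy and no sample is called falsely positive."""
    truth, calls = {}, {}
    i = 0
    for gene, n_true, n_det in [("ALK", 14, 10), ("ROS1", 9, 6), ("RET", 12, 7), ("MET", 5, 5)]:
        for j in range(n_true):
            sid = f"s{i}"; i += 1
            truth[sid] = gene
            calls[sid] = gene if j < n_det else "none"
    for _ in range(16):
        sid = f"s{i}"; i += 1
        truth[sid] = "none"
        calls[sid] = "none"
    return calls, truth


class TestBuildConfusion:
    def test_per_gene_cells(self):
        calls, truth = make_cohort_calls()
        t = build_confusion(calls, truth, "ALK")
        assert (t.tp, t.fn, t.fp, t.tn) == (10, 4, 0, 42)
        assert t.concordant == 52 and t.discordant == 4

    def test_overall_pools_per_gene_tables(self):
        calls, truth = make_cohort_calls()
        overall = build_confusion(calls, truth, "overall")
        assert overall.n == 224
        assert overall.concordant == 212 and overall.discordant == 12
        per_gene = [build_confusion(calls, truth, g) for g in ("ALK", "MET", "RET", "ROS1")]
        assert pool_tables(per_gene) == ConfusionTable(
            overall.tp, overall.fn, overall.fp, overall.tn, "overall"
        )

    def test_perfect_calls(self):
        calls, truth = make_cohort_calls()
        t = build_confusion(truth, truth, "overall")
        assert t.fn == 0 and t.fp == 0

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sample sets differ"):
            build_confusion({"a": "ALK"}, {"b": "ALK"}, "ALK")


class TestSensitivitySpecificity:
    @pytest.mark.parametrize(
        "table, sens, lo, hi",
        [
            (ConfusionTable(10, 4, 0, 42), 71.43, 45.35, 88.33),
            (ConfusionTable(28, 12, 0, 184), 70.0, 54.6, 81.9),
            (ConfusionTable(5, 0, 0, 51), 100.0, 56.6, 100.0),
        ],
    )
    def test_wilson_sensitivity(self, table, sens, lo, hi):
        s, _ = sensitivity_specificity(table)
        assert s.estimate * 100 == pytest.approx(sens, abs=0.01)
        assert s.ci_low * 100 == pytest.approx(lo, abs=0.06)
        assert s.ci_high * 100 == pytest.approx(hi, abs=0.06)

    def test_perfect_specificity_with_ci(self):
        from scipy.stats import norm

        _, spec = sensitivity_specificity(ConfusionTable(10, 4, 0, 42))
        assert spec.estimate == 1.0
        assert spec.ci_low == pytest.approx(1 / (1 + norm.ppf(0.975) ** 2 / 42), abs=1e-9)

    def test_empty_margin_undefined(self):
        sens, spec = sensitivity_specificity(ConfusionTable(0, 0, 2, 8))
        assert sens is None and spec is not None

    def test_wilson_at_phat_one_closed_form(self):
        """Wilson lower bound at p=1 equals 1/(1+z^2/n)."""
        from scipy.stats import norm

        z2 = norm.ppf(0.975) ** 2
        for n in (5, 16, 42, 184):
            ci = proportion_ci(n, n)
            assert ci.ci_low == pytest.approx(1 / (1 + z2 / n), abs=1e-9)
            assert ci.ci_high == 1.0

    @given(k=st.integers(0, 50), n=st.integers(1, 50))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_wilson_bounds_contain_estimate(self, k, n):
        if k > n:
            k = n
        ci = proportion_ci(k, n)
        assert 0.0 <= ci.ci_low <= ci.estimate <= ci.ci_high <= 1.0


class TestKappa:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (ConfusionTable(10, 4, 0, 42), 0.79),
            (ConfusionTable(6, 3, 0, 47), 0.77),
            (ConfusionTable(7, 5, 0, 44), 0.69),
            (ConfusionTable(5, 0, 0, 51), 1.00),
            (ConfusionTable(28, 12, 0, 184), 0.79),
        ],
    )
    def test_reference_values(self, table, expected):
        assert round(cohen_kappa(table).kappa, 2) == pytest.approx(expected)

    def test_exact_alk_value(self):
        """(10,4,0,42): p_o = 52/56, p_e = 0.6607, kappa = 0.7895."""
        res = cohen_kappa(ConfusionTable(10, 4, 0, 42))
        assert res.kappa == pytest.approx(0.7895, abs=5e-4)

    def test_perfect_agreement(self):
        assert cohen_kappa(ConfusionTable(7, 0, 0, 13)).kappa == 1.0

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cohen_kappa(ConfusionTable(0, 0, 0, 10))

    @given(
        tp=st.integers(0, 30), fn=st.integers(0, 30),
        fp=st.integers(0, 30), tn=st.integers(0, 30),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_kappa_bounded_by_observed_agreement(self, tp, fn, fp, tn):
        """kappa <= p_o always; kappa = 1 iff FP = FN = 0 (non-degenerate)."""
        n = tp + fn + fp + tn
        if n < 2:
            return
        t = ConfusionTable(tp, fn, fp, tn)
        p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / t.n**2
        if p_e == 1.0:
            return
        res = cohen_kappa(t)
        p_o = concordance_fraction(t)
        assert res.kappa <= p_o + 1e-12
        if fp == 0 and fn == 0:
            assert res.kappa == pytest.approx(1.0)
        else:
            assert res.kappa < 1.0
        assert res.ci_low <= res.kappa <= res.ci_high


class TestConcordanceFraction:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (ConfusionTable(10, 4, 0, 42), 52 / 56),   # 92.86%
            (ConfusionTable(7, 5, 0, 44), 51 / 56),    # 91.07%
            (ConfusionTable(6, 3, 0, 47), 53 / 56),    # 94.64%
            (ConfusionTable(5, 0, 0, 51), 1.0),
        ],
    )
    def test_values(self, table, expected):
        assert concordance_fraction(table) == pytest.approx(expected)


class TestTechniqueComparison:
    def test_printed_marginals_reconstruct_joint(self):
        """n=40, A detects 28, B detects 25, 23 agree -> (18,10,7,5), union 87.5%."""
        cells = reconcile_marginals(40, 28, 25, 23)
        assert cells == (18, 10, 7, 5)

    def test_all_positive_degenerate(self):
        assert reconcile_marginals(7, 7, 7, 7) == (7, 0, 0, 0)

    def test_parity_violation_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            reconcile_marginals(40, 28, 25, 24)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            reconcile_marginals(10, 9, 9, 0)

    def test_compare_techniques_union_and_agreement(self):
        a = {f"s{i}": i < 28 for i in range(40)}
        b = {f"s{i}": (i < 18) or (28 <= i < 35) for i in range(40)}
        comp = compare_techniques(a, b)
        assert comp.joint == (18, 10, 7, 5)
        assert comp.agreement == pytest.approx(23 / 40)
        assert comp.union_detection == pytest.approx(0.875)

    def test_identical_callsets(self):
        a = {f"s{i}": i < 10 for i in range(20)}
        comp = compare_techniques(a, dict(a))
        assert comp.agreement == 1.0
        assert comp.union_detection == pytest.approx(0.5)

    def test_disjoint_positives_covering_cohort(self):
        a = {f"s{i}": i < 10 for i in range(20)}
        b = {f"s{i}": i >= 10 for i in range(20)}
        comp = compare_techniques(a, b)
        assert comp.agreement == 0.0 and comp.union_detection == 1.0

    @given(
        n=st.integers(2, 60),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_reconcile_is_left_inverse_of_compare(self, n, data):
        """reconcile_marginals recovers the joint table compare_techniques built."""
        flags_a = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        flags_b = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        a = {f"s{i}": fa for i, fa in enumerate(flags_a)}
        b = {f"s{i}": fb for i, fb in enumerate(flags_b)}
        comp = compare_techniques(a, b)
        n_agree = comp.both_pos + comp.both_neg
        assert reconcile_marginals(
            n, comp.both_pos + comp.a_only, comp.both_pos + comp.b_only, n_agree
        ) == comp.joint


class TestMannWhitney:
    def test_tied_identical_groups(self):
        _, p = mann_whitney_counts([5, 6], [5, 6])
        assert p == pytest.approx(1.0)

    def test_complete_separation_exact(self):
        """(1,2,3) vs (10,11,12): U=0, exact two-tailed p = 2/20 = 0.1."""
        u, p = mann_whitney_counts([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_clinical_scale_separation_significant(self):
        """Counts like the positive-vs-negative clinical groups (medians
        ~6756 vs ~8, n = 7 vs 49) are overwhelmingly significant."""
        rng = np.random.default_rng(3)
        pos = rng.lognormal(np.log(6756), 0.55, size=7)
        neg = rng.poisson(8, size=49)
        _, p = mann_whitney_counts(pos, neg)
        assert p < 1e-4

    @pytest.mark.parametrize("m, n", [(6, 6), (8, 5), (10, 10)])
    def test_enumeration_matches_scipy_exact_on_tie_free_data(self, m, n):
        """On tie-free data the enumeration reproduces the exact
        distribution scipy computes by recursion."""
        import scipy.stats as sps

        rng = np.random.default_rng(8)
        x = rng.normal(0.0, 1.0, size=m)
        y = rng.normal(0.8, 1.0, size=n)
        _, p_exact = mann_whitney_counts(x, y)
        p_scipy = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p_exact == pytest.approx(p_scipy, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_counts([], [1.0])
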