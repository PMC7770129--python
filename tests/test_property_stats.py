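"""Classification rules and group statistics vs. independent oracles."""

import numpy as np
import pandas as pd
import pytest

from nbescore import (
    ArgumentError,
    DegenerateDataError,
    HIAClass,
    InsufficientDataError,
    NBEResult,
    SolubilityClass,
    anova_oneway,
    classify_hia,
    classify_solubility,
    correlate_nbe_with_property,
    spearman,
    two_group_test,
)
from nbescore.property_stats import INSOLUBLE_TERMS, SOLUBLE_TERMS
from oracles import (
    anova_oracle,
    mwu_asymptotic_oracle,
    mwu_exact_oracle,
    spearman_oracle,
    student_t_oracle,
    welch_oracle,
)


class TestClassifySolubility:
    @pytest.mark.parametrize("term", INSOLUBLE_TERMS)
    def test_insoluble_terms(self, term):
        assert classify_solubility(term) is SolubilityClass.INSOLUBLE

    @pytest.mark.parametrize("term", SOLUBLE_TERMS)
    def test_soluble_terms(self, term):
        assert classify_solubility(term) is SolubilityClass.SOLUBLE

    @pytest.mark.parametrize(
        "term", ["slightly soluble", "sparingly soluble", "", "unknown", "soluble in ethanol"]
    )
    def test_unlisted_terms_unclassified(self, term):
        assert classify_solubility(term) is SolubilityClass.UNCLASSIFIED

    def test_case_and_whitespace_insensitive(self):
        assert classify_solubility("  Freely   SOLUBLE ") is SolubilityClass.SOLUBLE
        assert classify_solubility("Poorly Soluble") is SolubilityClass.INSOLUBLE

    def test_totality(self):
        """Every string lands in exactly one of the three classes."""
        for term in [*INSOLUBLE_TERMS, *SOLUBLE_TERMS, "xyzzy", "soluble-ish"]:
            assert classify_solubility(term) in SolubilityClass


class TestClassifyHIA:
    @pytest.mark.parametrize("fa,expected", [
        (85, HIAClass.HIA_PLUS),
        (10, HIAClass.HIA_MINUS),
        (30, HIAClass.HIA_PLUS),   # boundary belongs to HIA+ (>= convention)
        (29.999, HIAClass.HIA_MINUS),
        (0, HIAClass.HIA_MINUS),
        (100, HIAClass.HIA_PLUS),
    ])
    def test_threshold_rule(self, fa, expected):
        assert classify_hia(fa) is expected

    @pytest.mark.parametrize("bad", [-1, 101, float("nan"), float("inf")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ArgumentError):
            classify_hia(bad)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [1, 4, 9]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert spearman(x, y).rho == pytest.approx(spearman(y, x).rho, rel=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=30), rng.normal(size=30)
        base = spearman(x, y)
        transformed = spearman(np.exp(x), y**3)
        assert transformed.rho == pytest.approx(base.rho, rel=1e-12)

    def test_tied_data_matches_hand_midrank_oracle(self):
        x = [1, 2, 2, 3, 4, 4, 4, 5, 6, 7]
        y = [2, 1, 3, 3, 5, 4, 6, 6, 7, 9]
        rho_oracle, p_oracle = spearman_oracle(x, y)
        res = spearman(x, y)
        assert res.rho == pytest.approx(rho_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_constant_vector_is_error_not_zero(self):
        with pytest.raises(DegenerateDataError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            spearman([1, 2], [2, 1])

    def test_nan_pairs_dropped(self):
        res = spearman([1, 2, 3, np.nan, 5], [1, 2, 3, 4, np.nan])
        assert res.n == 3 and res.n_dropped == 2


class TestTwoGroupTest:
    def test_identical_samples_show_no_difference(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        for kind in ("t_test", "wilcoxon"):
            res = two_group_test(a, a, kind=kind)
            assert res.p_value > 0.9

    def test_welch_hand_example(self):
        a = [27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1]
        b = [27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0]
        t_oracle, _df, p_oracle = welch_oracle(a, b)
        res = two_group_test(a, b, kind="t_test")
        assert res.statistic == pytest.approx(t_oracle, abs=1e-10)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_student_t_option(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 15)
        t_oracle, p_oracle = student_t_oracle(a, b)
        res = two_group_test(a, b, kind="t_test", equal_var=True)
        assert res.statistic == pytest.approx(t_oracle, abs=1e-10)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_wilcoxon_small_matches_exhaustive_enumeration(self):
        a, b = [1, 2, 3, 4], [11, 12, 13, 14]
        u_oracle, p_oracle = mwu_exact_oracle(a, b)
        res = two_group_test(a, b, kind="wilcoxon")
        assert res.statistic == u_oracle == 0.0
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert p_oracle == pytest.approx(2 / 70)  # 2 x 1/C(8,4)

    def test_label_symmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 9)
        for kind in ("t_test", "wilcoxon"):
            fwd = two_group_test(a, b, kind=kind)
            rev = two_group_test(b, a, kind=kind)
            assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-12)

    def test_degenerate_both_constant(self):
        with pytest.raises(DegenerateDataError):
            two_group_test([2.0, 2.0, 2.0], [2.0, 2.0], kind="t_test")

    def test_group_summaries_reported(self):
        res = two_group_test([1, 2, 3], [4, 5, 6, 7], labels=("lo", "hi"))
        assert res.group_labels == ("lo", "hi")
        assert res.group_ns == (3, 4)
        assert res.group_means == pytest.approx((2.0, 5.5))


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        g = [1.0, 2.0, 3.0]
        res = anova_oneway([g, g, g])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_sums_of_squares(self):
        groups = [[3, 2, 1, 4], [5, 6, 7], [9, 8, 7, 10, 11]]
        f_oracle, p_oracle = anova_oracle(groups)
        res = anova_oneway(groups)
        assert res.statistic == pytest.approx(f_oracle, abs=1e-10)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ArgumentError):
            anova_oneway([[1, 2], [3, 4]])


class TestAgreementWithOracles:
    """Implementation vs. independent formula oracles on random data,
    including ties, across a spread of sample sizes."""

    def test_hundred_random_datasets(self):
        rng = np.random.default_rng(20260919)
        for trial in range(100):
            n1, n2 = rng.integers(5, 200, size=2)
            # integer-valued draws guarantee heavy ties
            a = rng.integers(0, 30, n1).astype(float)
            b = rng.integers(0, 30, n2).astype(float) + rng.choice([0.0, 0.5])
            a[1] = a[0]  # guarantee at least one tie -> asymptotic rank path
            n = int(min(n1, n2))

            rho_o, p_o = spearman_oracle(a[:n], b[:n])
            res = spearman(a[:n], b[:n])
            assert res.rho == pytest.approx(rho_o, abs=1e-8)
            assert res.p_value == pytest.approx(p_o, abs=1e-8)

            t_o, _df, tp_o = welch_oracle(a, b)
            rt = two_group_test(a, b, kind="t_test")
            assert rt.statistic == pytest.approx(t_o, abs=1e-8)
            assert rt.p_value == pytest.approx(tp_o, abs=1e-8)

            u_o, up_o = mwu_asymptotic_oracle(a, b)
            rw = two_group_test(a, b, kind="wilcoxon")
            assert rw.statistic == pytest.approx(u_o, abs=1e-8)
            assert rw.p_value == pytest.approx(up_o, abs=1e-8)

            c = rng.integers(0, 30, rng.integers(5, 200)).astype(float)
            f_o, fp_o = anova_oracle([a, b, c])
            ra = anova_oneway([a, b, c])
            assert ra.statistic == pytest.approx(f_o, abs=1e-8)
            assert ra.p_value == pytest.approx(fp_o, abs=1e-8)


def _results_from(ids, nbes):
    return [
        NBEResult(id=i, nbe=v, total_bond_energy=v * 100, mw=100.0,
                  n_bonds=10, n_unmatched=0, table_source="test")
        for i, v in zip(ids, nbes)
    ]


class TestCorrelateWithProperty:
    def test_antitone_property_gives_minus_one(self):
        ids = [f"m{i}" for i in range(10)]
        nbes = list(range(10))
        table = pd.DataFrame({"id": ids, "prop": [-v for v in nbes]})
        res = correlate_nbe_with_property(_results_from(ids, nbes), table, "prop")
        assert res.rho == pytest.approx(-1.0)
        assert res.n == 10

    def test_join_uses_id_intersection(self):
        ids = [f"m{i}" for i in range(10)]
        table = pd.DataFrame({"id": ids[:5], "prop": [1.0, 2, 3, 4, 5]})
        res = correlate_nbe_with_property(_results_from(ids, range(10)), table, "prop")
        assert res.n == 5
        assert res.n_dropped == 5

    def test_too_few_joined_pairs(self):
        ids = ["a", "b", "c"]
        table = pd.DataFrame({"id": ["a", "b"], "prop": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            correlate_nbe_with_property(_results_from(ids, [1, 2, 3]), table, "prop")

    def test_unknown_property_rejected(self):
        table = pd.DataFrame({"id": ["a"], "prop": [1.0]})
        with pytest.raises(ArgumentError):
            correlate_nbe_with_property(_results_from(["a"], [1.0]), table, "other")
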