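import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_sign_permutation, oracle_wilcoxon_exact
from sisterdiv.contrasts import (
    binomial_sign_test,
    contrast,
    diversity_contrast_analysis,
    host_specificity_test,
    sign_permutation_test,
    wilcoxon_normal_approx,
    wilcoxon_signed_rank_exact,
)
from sisterdiv.synthetic import generate_sister_table

nonzero_ints = st.integers(-50, 50).filter(lambda x: x != 0)


class TestContrastMetrics:
    def test_logratio_closed_form(self):
        assert contrast("logratio", 150, 3) == pytest.approx(math.log(50))

    def test_raw_identity(self):
        assert contrast("raw", 7.3, 7.3) == 0.0

    def test_proportional_closed_form(self):
        assert contrast("proportional", 41, 46) == pytest.approx(-5 / 87)

    @pytest.mark.parametrize("a,b", [(0, 3), (-1, 2), (3, 0)])
    def test_logratio_domain_error(self, a, b):
        with pytest.raises(ValueError):
            contrast("logratio", a, b)


class TestSignPermutation:
    @pytest.mark.parametrize("contrasts,expected", [
        ([1, 2, 3], 0.25),        # only +/-(+,+,+) reach |6| among 8 patterns
        ([5], 1.0),               # both signs tie on |sum|
        ([5, 5], 0.5),            # sums {10, 0, 0, -10}
    ])
    def test_small_cases_enumerated_by_hand(self, contrasts, expected):
        assert sign_permutation_test(contrasts) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sign_permutation_test([0.0, 0.0])

    @given(st.lists(nonzero_ints, min_size=1, max_size=10))
    @settings(deadline=None, derandomize=True, max_examples=150)
    def test_equals_brute_force_oracle(self, contrasts):
        assert sign_permutation_test(contrasts) == pytest.approx(
            oracle_sign_permutation(contrasts))

    @given(st.lists(nonzero_ints, min_size=1, max_size=10))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_sign_flip_and_order_invariance(self, contrasts):
        p = sign_permutation_test(contrasts)
        assert sign_permutation_test([-c for c in contrasts]) == p
        assert sign_permutation_test(sorted(contrasts)) == p


class TestWilcoxonExact:
    def test_all_positive_no_ties(self):
        w, p = wilcoxon_signed_rank_exact([1, 2, 3, 4, 5])
        assert w == 15.0
        assert p == pytest.approx(2 / 32)  # both extremes of 2^5 patterns

    def test_symmetric_input_maximal_p(self):
        w, p = wilcoxon_signed_rank_exact([3.0, -3.0, 1.0, -1.0])
        assert p == 1.0

    def test_zero_only_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank_exact([0.0])

    @given(st.lists(nonzero_ints, min_size=2, max_size=11))
    @settings(deadline=None, derandomize=True, max_examples=150)
    def test_equals_enumeration_oracle_with_ties(self, contrasts):
        w, p = wilcoxon_signed_rank_exact(contrasts)
        w_ref, p_ref = oracle_wilcoxon_exact(contrasts)
        assert w == w_ref
        assert p == pytest.approx(p_ref)

    @given(st.lists(nonzero_ints, min_size=2, max_size=11, unique_by=abs))
    @settings(deadline=None, derandomize=True, max_examples=75)
    def test_one_sided_equals_oracle(self, contrasts):
        w, p = wilcoxon_signed_rank_exact(contrasts, alternative="greater")
        w_ref, p_ref = oracle_wilcoxon_exact(contrasts, alternative="greater")
        assert (w, p) == (w_ref, pytest.approx(p_ref))


class TestWilcoxonNormalApprox:
    def test_centered_statistic_gives_p_one(self):
        # 25 contrasts arranged so W+ equals its null mean m(m+1)/4
        m = 25
        vals = list(range(1, m + 1))
        target = m * (m + 1) // 4
        chosen, acc = [], 0
        for v in reversed(vals):
            if acc + v <= target:
                chosen.append(v)
                acc += v
        signed = [v if v in chosen else -v for v in vals]
        w, p = wilcoxon_normal_approx(signed)
        assert w == target
        assert p == 1.0

    def test_all_positive_m20_strongly_significant(self):
        w, p = wilcoxon_normal_approx(list(range(1, 21)))
        assert p < 0.001

    def test_converges_to_exact_at_m20(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            vals = rng.normal(size=20)
            vals = vals[vals != 0]
            _, p_norm = wilcoxon_normal_approx(vals)
            _, p_exact = wilcoxon_signed_rank_exact(vals)
            worst = max(worst, abs(p_norm - p_exact))
        assert worst <= 0.02


class TestBinomialSignTest:
    @pytest.mark.parametrize("k,n,expected", [
        (7, 13, 1.0),
        (0, 4, 0.125),
        (1, 1, 1.0),
    ])
    def test_tail_doubling(self, k, n, expected):
        assert binomial_sign_test(k, n) == pytest.approx(expected)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            binomial_sign_test(5, 4)


class TestDiversityContrastAnalysis:
    def test_table1_logratio_dispatches_exact_wilcoxon(self, table1):
        res = diversity_contrast_analysis(table1, "logratio")
        assert res.n_used == 13
        assert res.test_used == "wilcoxon_exact"
        assert res.statistic == 50.0
        assert res.tails == "two"

    def test_small_table_dispatches_sign_permutation(self):
        table = generate_sister_table(8, seed=3)
        res = diversity_contrast_analysis(table, "logratio")
        assert res.test_used == "sign_permutation"
        assert res.n_used <= 8

    def test_large_table_dispatches_normal_approx(self):
        table = generate_sister_table(25, seed=4)
        res = diversity_contrast_analysis(table, "logratio")
        if res.n_used >= 20:
            assert res.test_used == "wilcoxon_normal"

    def test_all_tied_table_errors(self):
        from sisterdiv.core_io import SisterPair, SisterPairTable
        pairs = tuple(
            SisterPair(f"p{i}", "G", 5, 0.0, "N", 5, 0.0) for i in range(13))
        with pytest.raises(ValueError, match="nonzero"):
            diversity_contrast_analysis(SisterPairTable(pairs), "logratio")

    def test_pair_order_invariance(self, table1):
        from sisterdiv.core_io import SisterPairTable
        shuffled = SisterPairTable(tuple(reversed(table1.pairs)))
        a = diversity_contrast_analysis(table1, "logratio")
        b = diversity_contrast_analysis(shuffled, "logratio")
        assert a.p_value == b.p_value
        assert a.statistic == b.statistic


class TestHostSpecificity:
    def test_table1_six_positive_differences(self, table1):
        res = host_specificity_test(table1)
        assert res.n_used == 6
        assert res.n_positive == 6
        assert res.tails == "one"

    def test_table1_exact_one_tailed_p(self, table1):
        res = host_specificity_test(table1)
        assert res.p_value == pytest.approx(0.5 ** 6)

    def test_single_positive_difference(self):
        from sisterdiv.core_io import SisterPair, SisterPairTable
        table = SisterPairTable((
            SisterPair("a", "G", 5, 10.0, "N", 5, 40.0),))
        res = host_specificity_test(table)
        assert res.p_value == 0.5


class TestTypeICalibration:
    def test_null_sister_tables_do_not_over_reject(self):
        """Under equal rates the logratio and sign tests hold their level.

        10^3 ERM-null tables of 13 pairs; two-tailed rejection at nominal 5%
        must stay at or below 6%.
        """
        n_tables = 1000
        rej_lr = rej_binom = 0
        for i in range(n_tables):
            table = generate_sister_table(13, rate_ratio=1.0, seed=50_000 + i)
            res = diversity_contrast_analysis(table, "logratio")
            rej_lr += res.p_value < 0.05
            n_more = sum(1 for p in table if p.n_galler > p.n_nongaller)
            n_less = sum(1 for p in table if p.n_galler < p.n_nongaller)
            if n_more + n_less:
                rej_binom += binomial_sign_test(n_more, n_more + n_less) < 0.05
        assert rej_lr / n_tables <= 0.06
        assert rej_binom / n_tables <= 0.06
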