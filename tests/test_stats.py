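"""Prevalence CIs, regularity index, kappa, Spearman and burden."""

from __future__ import annotations

import datetime as dt
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from litcomorbid.errors import UndefinedStatisticError
from litcomorbid.phenotype import PhenotypeCall
from litcomorbid.stats import (
    AgreementTable,
    burden_summary,
    cohens_kappa,
    prevalence_ci,
    round_half_up,
    sperrin_I,
    spearman_rho,
)


def kappa_oracle(a: int, d: int, b: int, c: int) -> float:
    """Direct po/pe computation for a 2x2 two-rater table."""
    n = a + b + c + d
    po = (a + d) / n
    pa, pb = (a + b) / n, (a + c) / n
    pe = pa * pb + (1 - pa) * (1 - pb)
    return (po - pe) / (1 - pe)


def spearman_oracle(x, y) -> float:
    """Average ranks then Pearson correlation, from first principles."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestPrevalenceCI:
    def test_large_count_uses_wald(self):
        est = prevalence_ci(93, 741)
        assert est.method == "normal"
        assert round_half_up(est.p_per_1000) == 125.5

    def test_zero_successes_wilson_lower_exactly_zero(self):
        est = prevalence_ci(0, 741)
        assert est.method == "wilson"
        assert est.p_per_1000 == 0.0
        assert est.ci_low_per_1000 == 0.0
        assert round_half_up(est.ci_high_per_1000) == 5.2

    def test_small_count_switches_to_wilson(self):
        est = prevalence_ci(3, 741)
        assert est.method == "wilson"
        assert est.rounded() == (4.0, 1.4, 11.8)

    def test_full_count_is_exactly_1000(self):
        est = prevalence_ci(741, 741)
        assert est.p_per_1000 == 1000.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            prevalence_ci(0, 0)

    @given(st.integers(0, 300), st.integers(1, 300))
    def test_reported_bounds_stay_in_range(self, k, n):
        k = min(k, n)
        est = prevalence_ci(k, n)
        assert 0.0 <= est.ci_low_per_1000 <= est.p_per_1000 <= est.ci_high_per_1000
        if est.method == "wilson":
            assert est.ci_high_per_1000 <= 1000.0


class TestSperrinI:
    def test_equal_spacing_gives_one(self):
        dates = [dt.date(2005, 1, 1) + dt.timedelta(days=30 * i) for i in range(8)]
        assert sperrin_I(dates).I == pytest.approx(1.0)

    def test_two_encounters_give_one(self):
        assert sperrin_I([dt.date(2005, 1, 1), dt.date(2009, 1, 1)]).I == pytest.approx(1.0)

    def test_hand_computed_three_point_case(self):
        # gaps 1/10 and 9/10: Var = 0.16, I = 2/3 + (1/3)(1 - sqrt(0.32))
        expected = 2 / 3 + (1 / 3) * (1 - math.sqrt(2 * 0.16))
        assert sperrin_I([0.0, 1.0, 10.0]).I == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.8114, abs=5e-5)

    def test_undefined_cases_signal(self):
        with pytest.raises(UndefinedStatisticError):
            sperrin_I([dt.date(2005, 1, 1)])
        with pytest.raises(UndefinedStatisticError):
            sperrin_I([5.0, 5.0, 5.0])

    @given(
        st.lists(st.integers(0, 3650), min_size=2, max_size=15, unique=True),
        st.integers(1, 4),
        st.integers(-1000, 1000),
    )
    def test_affine_invariance_of_date_axis(self, days, scale, shift):
        base = sperrin_I(sorted(float(d) for d in days)).I
        moved = sperrin_I(sorted(float(d) * scale + shift for d in days)).I
        assert moved == pytest.approx(base, abs=1e-9)


class TestCohensKappa:
    def test_published_vote_partition(self):
        assert round(cohens_kappa(AgreementTable(140, 304, 11, 11)), 2) == 0.89

    def test_perfect_agreement_with_both_categories(self):
        assert cohens_kappa(AgreementTable(10, 5, 0, 0)) == pytest.approx(1.0)

    def test_chance_level_agreement_is_zero(self):
        # po = pe = 0.5 for the uniform 2x2 table
        assert cohens_kappa(AgreementTable(1, 1, 1, 1)) == pytest.approx(0.0)

    def test_degenerate_marginals_signal(self):
        with pytest.raises(UndefinedStatisticError):
            cohens_kappa(AgreementTable(10, 0, 0, 0))

    def test_symmetric_under_rater_swap(self):
        t = AgreementTable(30, 50, 7, 2)
        assert cohens_kappa(t) == pytest.approx(cohens_kappa(t.transposed()))

    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 6), st.integers(0, 6))
    def test_matches_direct_po_pe_oracle(self, a, d, b, c):
        assert cohens_kappa(AgreementTable(a, d, b, c)) == pytest.approx(
            kappa_oracle(a, d, b, c), abs=1e-12
        )

    def test_matches_sklearn_on_label_vectors(self):
        from sklearn.metrics import cohen_kappa_score

        a, d, b, c = 140, 304, 11, 11
        r1 = [1] * (a + b) + [0] * (c + d)
        r2 = [1] * a + [0] * b + [1] * c + [0] * d
        assert cohens_kappa(AgreementTable(a, d, b, c)) == pytest.approx(
            cohen_kappa_score(r1, r2)
        )


class TestSpearman:
    def test_identity_is_one(self):
        assert spearman_rho([1, 2, 3, 4], [1, 2, 3, 4]).rho == pytest.approx(1.0)

    def test_constant_vector_signals(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_exhaustive_small_inputs_match_rank_then_pearson_oracle(self):
        values = [0, 0, 1, 2, 2]  # heavy ties
        x = [3, 1, 4, 1, 5]
        for perm in itertools.permutations(values):
            assert spearman_rho(x, list(perm)).rho == pytest.approx(
                spearman_oracle(x, perm), abs=1e-12
            )

    @given(st.lists(st.integers(0, 50), min_size=3, max_size=12))
    def test_invariant_under_strictly_monotone_transform(self, y):
        x = list(range(len(y)))
        if len(set(y)) < 2:
            return
        base = spearman_rho(x, y).rho
        transformed = spearman_rho(x, [v**3 + 2 * v for v in y]).rho
        assert transformed == pytest.approx(base, abs=1e-12)


class TestBurden:
    @staticmethod
    def calls_for(flags):
        return [
            PhenotypeCall(f"P{i}", "D1", bool(f), frozenset({"text"}) if f else frozenset())
            for i, f in enumerate(flags)
        ]

    def test_disease_free_cohort(self):
        est = burden_summary(self.calls_for([0] * 20))
        assert est.p_per_1000 == 0.0 and est.method == "wilson"

    def test_saturated_cohort_normal_method(self):
        est = burden_summary(self.calls_for([1] * 20))
        assert est.p_per_1000 == 1000.0 and est.method == "normal"

    def test_planted_burden_covered_by_ci(self):
        """With a planted 18% burden at n=741, the estimate's 95% CI should
        contain the truth in about 95% of replicates."""
        rng_seeds = range(200)
        n, p_true = 741, 0.18
        hits = 0
        for seed in rng_seeds:
            rng = np.random.default_rng(10_000 + seed)
            flags = rng.random(n) < p_true
            est = burden_summary(self.calls_for(flags))
            if est.ci_low_per_1000 <= 1000 * p_true <= est.ci_high_per_1000:
                hits += 1
        assert hits >= 186  # >= 93% of 200
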