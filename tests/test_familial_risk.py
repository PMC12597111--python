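"""Cohort rates, relative enumeration, observed/expected, RR and Poisson inference."""

import math

import numpy as np
import pytest
from scipy.stats import poisson

from famclust import (
    agresti_min_ci,
    build_rate_table,
    enumerate_relatives,
    familial_rr_report,
    garwood_ci,
    observed_expected,
    poisson_upper_p,
    relative_risk,
    simulate_genealogy,
)
from famclust.simulate import SimParams, high_risk_example

from conftest import build_genealogy


class TestRateTable:
    def _uniform_cohort(self, n, n_cases):
        rows = [(f"i{k:03d}", None, None, "M", 1930 + (k % 5), k < n_cases) for k in range(n)]
        return build_genealogy(rows)

    def test_single_cohort_rate(self):
        g = self._uniform_cohort(100, 1)
        rates = build_rate_table(g, g.affected_ids())
        assert len(rates.rates) == 1
        (key, (n, c, rate)), = rates.rates.items()
        assert (n, c, rate) == (100, 1, 0.01)
        assert key.bin_start == 1930 and key.sex == "M" and not key.in_state

    def test_no_cases_gives_zero_rates(self):
        g = self._uniform_cohort(50, 0)
        rates = build_rate_table(g, set())
        assert all(r == 0 for _, _, r in rates.rates.values())

    def test_totals_conserved_across_cohorts(self):
        g = simulate_genealogy(SimParams(seed=4))
        cases = {i.id for k, i in enumerate(g) if k % 37 == 0}
        g.set_affected(cases)
        rates = build_rate_table(g, cases)
        assert rates.n_individuals == len(g)
        assert rates.n_cases == len(cases)

    def test_five_year_bins_anchored_at_multiples_of_five(self):
        g = self._uniform_cohort(10, 0)
        rates = build_rate_table(g, set())
        assert rates.key_for("F", 1934, "in_state").bin_start == 1930
        assert rates.key_for("F", 1935, "in_state").bin_start == 1935
        shifted = build_rate_table(g, set(), anchor=3)
        assert shifted.key_for("F", 1934, "in_state").bin_start == 1933

    def test_cases_only_in_one_cohort(self):
        rows = [(f"m{k}", None, None, "M", 1930, k == 0) for k in range(10)]
        rows += [(f"f{k}", None, None, "F", 1930, False) for k in range(10)]
        g = build_genealogy(rows)
        rates = build_rate_table(g, g.affected_ids())
        by_sex = {k.sex: r for k, (_, _, r) in rates.rates.items()}
        assert by_sex == {"M": 0.1, "F": 0.0}


class TestEnumerateRelatives:
    def test_first_degree_nuclear_family(self, extended_family):
        assert enumerate_relatives(extended_family, "kid1", 1) == {
            "dad", "mom", "kid2", "halfsib", "gkid1",
        } - {"halfsib"}  # half-sib is degree 2

    def test_second_degree_includes_grandparents_uncle_halfsib(self, extended_family):
        got = enumerate_relatives(extended_family, "kid1", 2)
        assert {"gpa", "gma", "uncle", "halfsib"} <= got
        assert "cousin1" not in got

    def test_third_degree_includes_first_cousins(self, extended_family):
        got = enumerate_relatives(extended_family, "kid1", 3)
        assert "cousin1" in got
        # grand-niece/nephew of the uncle: gkid1 is uncle's grand-nephew
        assert "gkid1" in enumerate_relatives(extended_family, "uncle", 3)

    def test_isolated_founder_has_no_kin(self):
        g = build_genealogy([("solo", None, None, "M", 1900)])
        for degree in (1, 2, 3):
            assert enumerate_relatives(g, "solo", degree) == set()

    def test_degrees_disjoint_and_never_self(self):
        g = simulate_genealogy(SimParams(n_founders=12, n_generations=4, seed=9))
        ids = sorted(g.ids)
        rng = np.random.default_rng(1)
        for i in rng.choice(ids, size=30, replace=False):
            sets = {d: enumerate_relatives(g, i, d) for d in (1, 2, 3)}
            assert i not in sets[1] | sets[2] | sets[3]
            assert not sets[1] & sets[2]
            assert not sets[1] & sets[3]
            assert not sets[2] & sets[3]


class TestObservedExpected:
    def test_affected_siblings_counted_once_each(self, extended_family):
        extended_family.set_affected({"kid1", "kid2"})
        rates = build_rate_table(extended_family, {"kid1", "kid2"})
        n_rel, obs, exp = observed_expected(extended_family, {"kid1", "kid2"}, 1, rates)
        # union: dad, mom, kid1, kid2, gkid1 -> each person once
        assert n_rel == 5
        assert obs == 2
        assert exp == pytest.approx(sum(
            rates.rate_for(extended_family[r]) for r in ("dad", "mom", "kid1", "kid2", "gkid1")
        ))

    def test_no_cases(self, extended_family):
        rates = build_rate_table(extended_family, set())
        assert observed_expected(extended_family, set(), 1, rates) == (0, 0, 0)

    def test_union_never_exceeds_per_case_sum(self):
        g, cases = high_risk_example()
        rates = build_rate_table(g, cases)
        for degree in (1, 2, 3):
            n_rel, obs, _ = observed_expected(g, cases, degree, rates)
            per_case = sum(len(enumerate_relatives(g, c, degree)) for c in cases)
            assert n_rel <= per_case
            assert obs <= len(cases)


class TestRelativeRisk:
    def test_observed_one_expected_sixteen_tenths(self):
        assert relative_risk(1, 1.6) == pytest.approx(0.625)

    def test_zero_observed(self):
        assert relative_risk(0, 2.3) == 0.0

    def test_division_example(self):
        assert relative_risk(8, 0.6) == pytest.approx(13.3333, abs=1e-4)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(3, 0.0)


class TestPoissonUpperP:
    def test_closed_form_two_observed(self):
        # P(X >= 2) = 1 - e^-0.4 (1 + 0.4)
        assert poisson_upper_p(2, 0.4) == pytest.approx(1 - math.exp(-0.4) * 1.4, rel=1e-12)

    def test_zero_observed_is_one(self):
        assert poisson_upper_p(0, 5.0) == 1.0

    def test_decreasing_in_expected(self):
        grid = [0.2, 0.5, 1.0, 2.0, 5.0, 10.0]
        for obs in (1, 3, 8):
            ps = [poisson_upper_p(obs, e) for e in grid]
            assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_nonincreasing_in_observed(self):
        for exp in (0.3, 1.0, 4.0):
            ps = [poisson_upper_p(o, exp) for o in range(8)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestAgrestiMinCI:
    def test_zero_observed_boundary(self):
        lo, hi = agresti_min_ci(0, 1.0)
        assert lo == 0.0 and hi > 0.0

    def test_contains_point_estimate_and_no_wider_than_exact(self):
        lo, hi = agresti_min_ci(1, 1.6)
        glo, ghi = garwood_ci(1, 1.6)
        assert lo <= 0.625 <= hi
        assert glo == pytest.approx(0.0158, abs=2e-4)
        assert ghi == pytest.approx(3.49, abs=0.01)
        assert glo <= lo and hi <= ghi

    def test_central_method_equals_garwood(self):
        for obs, exp in [(0, 0.7), (1, 1.6), (5, 2.0)]:
            assert agresti_min_ci(obs, exp, method="central") == pytest.approx(
                garwood_ci(obs, exp)
            )

    def test_width_decreases_with_expected_at_fixed_ratio(self):
        widths = []
        for exp in (0.5, 1.0, 2.0, 4.0, 8.0):
            obs = int(round(2 * exp))  # RR fixed at ~2
            lo, hi = agresti_min_ci(obs, exp)
            widths.append(hi - lo)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_inverts_the_midp_test(self):
        # at the bounds, the mid-P tail probability equals alpha/2
        obs, exp = 4, 1.3
        lo, hi = agresti_min_ci(obs, exp, level=0.95)
        mu_lo, mu_hi = lo * exp, hi * exp
        tail_lo = poisson.sf(obs - 1, mu_lo) - 0.5 * poisson.pmf(obs, mu_lo)
        tail_hi = poisson.cdf(obs, mu_hi) - 0.5 * poisson.pmf(obs, mu_hi)
        assert tail_lo == pytest.approx(0.025, abs=1e-4)
        assert tail_hi == pytest.approx(0.025, abs=1e-4)


class TestFamilialRRReport:
    def test_rows_combine_components(self):
        g, cases = high_risk_example()
        rates = build_rate_table(g, cases)
        rows = familial_rr_report(g, cases, rates)
        assert [r.relationship_degree for r in rows] == [1, 2, 3]
        for row in rows:
            n_rel, obs, exp = observed_expected(g, cases, row.relationship_degree, rates)
            assert (row.n_relatives, row.observed) == (n_rel, obs)
            if exp > 0:
                assert row.rr == pytest.approx(obs / exp)
                assert row.ci_low <= row.rr <= row.ci_high or obs == 0
                assert row.p_one_tailed == pytest.approx(poisson_upper_p(obs, exp))

    def test_empty_case_set_rejected(self, trio):
        with pytest.raises(ValueError):
            familial_rr_report(trio, set())

    def test_zero_expected_flagged_not_dropped(self, extended_family):
        # rates built with no cases: every cohort rate is 0, RR undefined
        zero_rates = build_rate_table(extended_family, set())
        rows = familial_rr_report(extended_family, {"kid1", "kid2"}, zero_rates)
        for row in rows:
            assert row.expected == 0
            assert math.isnan(row.rr) and math.isnan(row.ci_low)
            assert row.p_one_tailed == 1.0
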