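"""Disproportionality metrics (PRR, ROR, IC) and the composite SDR rule."""

import math

import numpy as np
import pytest

from oralpv.signals import (
    ContingencyTable2x2,
    MetricCI,
    build_2x2,
    classify_sdr,
    evaluate_term,
    information_component,
    prr,
    qualify,
    ror,
)

from conftest import multi_collection, record


class TestBuild2x2:
    def test_toy_counts(self):
        c = multi_collection(
            [
                record("r1", ("x",), vclass="covid19"),
                record("r2", ("y",), vclass="covid19"),
                record("r3", ("x",), vclass="comparator"),
                record("r4", ("y",), vclass="comparator"),
            ]
        )
        t = build_2x2(c, "x")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_no_comparator_arm(self):
        c = multi_collection([record("r1", ("x",)), record("r2", ("y",))])
        t = build_2x2(c, "x")
        assert (t.c, t.d) == (0, 0)
        assert not qualify(t)

    def test_scope_counts_any_position(self):
        c = multi_collection([record("r1", ("filler", "x"), vclass="covid19"),
                              record("r2", ("y",), vclass="comparator")])
        assert build_2x2(c, "x", "any_position").a == 1
        assert build_2x2(c, "x", "primary_only").a == 0

    def test_single_term_dialect_rejected(self):
        from conftest import single_collection

        c = single_collection([record("r1", "x")])
        with pytest.raises(ValueError, match="multi-term"):
            build_2x2(c, "x")


class TestPRR:
    def test_hand_computed_ratio(self):
        m = prr(ContingencyTable2x2(10, 990, 5, 1995))
        # (10/1000) / (5/2000) = 4 exactly
        assert m.point == pytest.approx(4.0)
        se = math.sqrt(1 / 10 - 1 / 1000 + 1 / 5 - 1 / 2000)
        assert m.ci_low == pytest.approx(4.0 * math.exp(-1.96 * se))
        assert m.ci_high == pytest.approx(4.0 * math.exp(1.96 * se))

    def test_equal_proportions_give_unity(self):
        assert prr(ContingencyTable2x2(10, 90, 20, 180)).point == pytest.approx(1.0)

    @pytest.mark.parametrize("t", [ContingencyTable2x2(0, 10, 5, 5), ContingencyTable2x2(5, 5, 0, 10)])
    def test_undefined_when_an_arm_has_no_cases(self, t):
        assert prr(t) is None


class TestROR:
    def test_hand_computed_odds_ratio(self):
        m = ror(ContingencyTable2x2(10, 990, 5, 1995))
        assert m.point == pytest.approx((10 * 1995) / (990 * 5))

    def test_unit_table(self):
        assert ror(ContingencyTable2x2(1, 1, 1, 1)).point == pytest.approx(1.0)

    def test_zero_cell_undefined(self):
        assert ror(ContingencyTable2x2(5, 0, 3, 10)) is None


class TestInformationComponent:
    def test_zero_when_observed_equals_expected(self):
        # margins give E = (20)(100)/200 = 10 = a
        ic, _ = information_component(ContingencyTable2x2(10, 90, 10, 90))
        assert ic == pytest.approx(0.0)

    def test_hand_computed_shrinkage_value(self):
        # margins: E = (100+0)(100+300)/1600 = 25
        t = ContingencyTable2x2(100, 300, 0, 1200)
        ic, ic025 = information_component(t)
        assert ic == pytest.approx(math.log2(100.5 / 25.5))
        assert ic025 == pytest.approx(ic - 3.3 / math.sqrt(100.5) - 2 / 100.5 ** 1.5)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            information_component(ContingencyTable2x2(0, 0, 0, 0))

    def test_monotone_in_observed_count_with_margins_fixed(self):
        # vary a while row1 = a+b and col1 = a+c and N stay fixed
        row1, col1, n = 200, 50, 2000
        values = []
        for a in range(5, 46, 5):
            t = ContingencyTable2x2(a, row1 - a, col1 - a, n - row1 - col1 + a)
            values.append(information_component(t)[0])
        assert all(x < y for x, y in zip(values, values[1:]))

    @pytest.mark.parametrize("a,e_ratio", [(3, 0.5), (3, 2.0), (10, 1.0), (100, 0.25)])
    def test_ic025_close_to_gamma_posterior_quantile(self, a, e_ratio):
        """The closed-form IC025 approximates the 2.5th posterior percentile."""
        e = a * e_ratio
        # construct margins achieving this expectation: col1 = a + c
        # choose b so E=(a+c)(a+b)/N == e with c, d free
        rng = np.random.default_rng(1234)
        draws = rng.gamma(shape=a + 0.5, scale=1.0 / (e + 0.5), size=200_000)
        mc_q = np.log2(np.quantile(draws, 0.025))
        ic = math.log2((a + 0.5) / (e + 0.5))
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2 * (a + 0.5) ** -1.5
        assert ic025 == pytest.approx(mc_q, abs=0.15)


class TestQualification:
    def test_no_exposed_cases_disqualifies(self):
        assert not qualify(ContingencyTable2x2(0, 100, 5, 95))

    def test_no_comparator_cases_disqualifies(self):
        assert not qualify(ContingencyTable2x2(35, 65, 0, 100))

    def test_sufficient_counts_qualify(self):
        assert qualify(ContingencyTable2x2(10, 90, 5, 95))

    def test_thresholds_configurable(self):
        t = ContingencyTable2x2(2, 98, 1, 99)
        assert not qualify(t, min_covid=3)
        assert qualify(t, min_covid=2)


class TestClassifySDR:
    def test_all_three_criteria_met(self):
        # strongest published signal row
        sdr = classify_sdr(
            MetricCI(17.57, 10.28, 30.03), MetricCI(17.57, 10.28, 30.04), 4.14, 3.60
        )
        assert sdr == "yes"

    def test_weak_point_estimates_fail(self):
        sdr = classify_sdr(MetricCI(1.36, 1.17, 1.59), MetricCI(1.36, 1.17, 1.59), 0.45, 0.29)
        assert sdr == "no"

    def test_frequentist_lower_bound_below_one_fails(self):
        sdr = classify_sdr(MetricCI(4.99, 0.60, 41.41), MetricCI(4.99, 0.60, 41.41), 2.32, 0.20)
        assert sdr == "no"

    def test_negative_ic025_fails_even_with_strong_frequentist(self):
        sdr = classify_sdr(MetricCI(3.0, 1.5, 6.0), MetricCI(3.0, 1.5, 6.0), 1.0, -0.1)
        assert sdr == "no"

    def test_unqualified_is_disqualified(self):
        assert classify_sdr(None, None, None, None, qualified=False) == "disqualified"


def test_ror_at_least_prr_for_elevated_signals():
    """ROR >= PRR whenever PRR >= 1 (algebraic consequence of the 2x2 form)."""
    rng = np.random.default_rng(42)
    checked = 0
    while checked < 50:
        a, b, c, d = (int(x) for x in rng.integers(1, 500, size=4))
        t = ContingencyTable2x2(a, b, c, d)
        p, r = prr(t), ror(t)
        if p.point >= 1.0:
            assert r.point >= p.point - 1e-12
            checked += 1


def test_evaluate_term_matches_brute_force_recount():
    rng = np.random.default_rng(3)
    recs = []
    for i in range(400):
        vclass = "comparator" if rng.random() < 0.4 else "covid19"
        terms = ["filler"]
        if rng.random() < 0.1:
            terms.append("x")
        recs.append(record(f"r{i}", tuple(terms), vclass=vclass))
    c = multi_collection(recs)
    m = evaluate_term(c, "x")
    a = sum("x" in r.terms and r.vaccine_class == "covid19" for r in c.records)
    cc = sum("x" in r.terms and r.vaccine_class == "comparator" for r in c.records)
    assert (m.table.a, m.table.c) == (a, cc)
    assert m.table.n == c.n_total
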