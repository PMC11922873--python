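import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import integrate
from scipy import stats as st

from pvfaers.disproportionality import (ContingencyTable, MgpsPrior, bcpnn_ic, build_table,
                                        ebgm, evaluate_signal, fit_mgps_prior,
                                        posterior_cdf, posterior_mixture_weight, ror)
from pvfaers.term_mapping import load_endpoints
from tests.conftest import make_case

tables_strategy = st_.tuples(
    st_.integers(1, 300), st_.integers(1, 300), st_.integers(1, 300), st_.integers(1, 2000)
).map(lambda t: ContingencyTable(*t))


class TestContingencyTable:
    def test_counts_from_cohorts(self, endpoints):
        ep = next(e for e in endpoints if e.name == "dyskinesia")
        cohort = [make_case(case_id=f"A{i}", reactions=["Dystonia"]) for i in range(3)]
        cohort += [make_case(case_id=f"B{i}", reactions=["Tremor"]) for i in range(7)]
        background = [make_case(case_id=f"C{i}", reactions=["Dyskinesia"]) for i in range(9)]
        background += [make_case(case_id=f"D{i}", reactions=["Fall"]) for i in range(81)]
        t = build_table(cohort, background, ep)
        assert (t.a, t.b, t.c, t.d) == (3, 7, 9, 81)

    def test_endpoint_absent_everywhere(self, endpoints):
        ep = next(e for e in endpoints if e.name == "wearing_off")
        t = build_table([make_case(reactions=["Tremor"])],
                        [make_case(reactions=["Fall"])], ep)
        assert t.a == 0 and t.c == 0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


class TestRor:
    def test_point_estimate_hand_value(self):
        r = ror(ContingencyTable(25, 75, 100, 9800))
        assert r.ror == pytest.approx(25 * 9800 / (75 * 100))

    def test_independence_gives_unity(self):
        assert ror(ContingencyTable(10, 90, 100, 900)).ror == pytest.approx(1.0)

    def test_zero_cell_correction(self):
        r = ror(ContingencyTable(0, 10, 5, 100))
        assert r.corrected
        expected = (0.5 * 100.5) / (10.5 * 5.5)
        assert r.ror == pytest.approx(expected)
        assert math.isfinite(r.ci_low) and math.isfinite(r.ci_high)

    def test_interval_matches_independent_implementation(self):
        """Cross-check point estimate and Wald CI against statsmodels."""
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for cells in [(25, 75, 100, 9800), (342, 3392, 1556, 17926), (7, 13, 29, 151)]:
            a, b, c, d = cells
            t2 = sm.Table2x2(np.array([[a, b], [c, d]]))
            r = ror(ContingencyTable(a, b, c, d))
            assert r.ror == pytest.approx(t2.oddsratio)
            low, high = t2.oddsratio_confint(0.05)
            assert r.ci_low == pytest.approx(low, rel=1e-6)
            assert r.ci_high == pytest.approx(high, rel=1e-6)

    @settings(max_examples=50, derandomize=True)
    @given(t=tables_strategy)
    def test_swap_inverts_and_scaling_preserves_point(self, t):
        r = ror(t)
        swapped = ror(ContingencyTable(t.c, t.d, t.a, t.b))
        assert swapped.ror == pytest.approx(1 / r.ror)
        scaled = ror(ContingencyTable(3 * t.a, 3 * t.b, 3 * t.c, 3 * t.d))
        assert scaled.ror == pytest.approx(r.ror)
        assert (scaled.ci_high / scaled.ci_low) < (r.ci_high / r.ci_low)


class TestBcpnnIc:
    def test_zero_when_observed_equals_expected(self):
        t = ContingencyTable(10, 90, 90, 810)  # E = 100*100/1000 = 10
        assert t.expected == pytest.approx(10.0)
        assert bcpnn_ic(t).ic == pytest.approx(0.0)

    def test_hand_value(self):
        ic = bcpnn_ic(ContingencyTable(25, 75, 100, 9800))
        assert ic.expected == pytest.approx(1.25)
        assert ic.ic == pytest.approx(math.log2(25.5 / 1.75))
        assert ic.ic025 == pytest.approx(ic.ic - 3.3 / math.sqrt(25.5) - 2.0 * 25.5 ** -1.5)

    def test_strictly_increasing_in_observed_count_at_fixed_expected(self):
        # margins (100, 100) and N=10000+a keep E = 1 for every a
        values = []
        for a in range(0, 100, 7):
            t = ContingencyTable(a, 100 - a, 100 - a, 9800 + a)
            assert t.expected == pytest.approx(1.0)
            values.append(bcpnn_ic(t).ic)
        assert all(x < y for x, y in zip(values, values[1:]))

    @settings(max_examples=50, derandomize=True)
    @given(t=tables_strategy)
    def test_sign_matches_observed_minus_expected(self, t):
        ic = bcpnn_ic(t)
        if abs(t.a - ic.expected) > 1e-9:
            assert (ic.ic > 0) == (t.a > ic.expected)


class TestMgps:
    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(0)
        pairs = list(zip(rng.poisson(2.0, 50), rng.uniform(0.5, 5.0, 50)))
        p1 = fit_mgps_prior(pairs)
        p2 = fit_mgps_prior(pairs)
        assert (p1.alpha1, p1.beta1, p1.alpha2, p1.beta2, p1.p_mix) == \
               (p2.alpha1, p2.beta1, p2.alpha2, p2.beta2, p2.p_mix)

    def test_all_zero_counts_flagged_nonconverged(self):
        with pytest.warns(UserWarning, match="not identifiable"):
            prior = fit_mgps_prior([(0, 1.0)] * 10)
        assert not prior.converged

    def test_too_few_tables_rejected(self):
        with pytest.raises(ValueError):
            fit_mgps_prior([(3, 1.0)])

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            MgpsPrior(-1.0, 1.0, 1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            MgpsPrior(1.0, 1.0, 1.0, 1.0, 1.5)


DIFFUSE = MgpsPrior(0.1, 0.1, 0.2, 0.1, 0.5)
INFORMATIVE = MgpsPrior(2.0, 2.0, 1.0, 1.0, 0.7)


class TestEbgm:
    def test_dominating_unit_prior_forces_unity(self):
        prior = MgpsPrior(10000.0, 10000.0, 10000.0, 10000.0, 0.5)
        for a in (0, 3, 40):
            t = ContingencyTable(a, 100, 50, 5000)
            assert ebgm(t, prior).ebgm == pytest.approx(1.0, rel=0.02)

    def test_likelihood_dominates_diffuse_prior(self):
        t = ContingencyTable(500, 500, 10, 99000)  # a/E ~ 98
        r = ebgm(t, DIFFUSE)
        assert r.ebgm == pytest.approx(t.a / t.expected, rel=0.05)

    def test_quantiles_bracket_point_and_match_cdf(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            t = ContingencyTable(int(rng.integers(0, 60)), int(rng.integers(5, 400)),
                                 int(rng.integers(1, 400)), int(rng.integers(100, 20000)))
            prior = INFORMATIVE if rng.random() < 0.5 else DIFFUSE
            r = ebgm(t, prior)
            assert r.eb05 < r.ebgm < r.eb95
            assert posterior_cdf(r.eb05, t.a, t.expected, prior) == pytest.approx(0.05, abs=1e-6)
            assert posterior_cdf(r.eb95, t.a, t.expected, prior) == pytest.approx(0.95, abs=1e-6)

    def test_quantile_against_numerical_integration_oracle(self):
        """Independent oracle: integrate the posterior mixture density."""
        rng = np.random.default_rng(11)
        for _ in range(6):
            t = ContingencyTable(int(rng.integers(1, 50)), int(rng.integers(5, 300)),
                                 int(rng.integers(1, 300)), int(rng.integers(100, 10000)))
            prior = INFORMATIVE
            e = t.expected
            q = posterior_mixture_weight(t.a, e, prior)

            def pdf(lam):
                return (q * st.gamma.pdf(lam, prior.alpha1 + t.a, scale=1 / (prior.beta1 + e))
                        + (1 - q) * st.gamma.pdf(lam, prior.alpha2 + t.a,
                                                 scale=1 / (prior.beta2 + e)))

            r = ebgm(t, prior)
            mass, _ = integrate.quad(pdf, 0, r.eb05, limit=200)
            assert mass == pytest.approx(0.05, abs=1e-6)

    def test_nondecreasing_in_observed_count(self):
        values = [ebgm(ContingencyTable(a, 100 - a, 100 - a, 9800 + a), INFORMATIVE).ebgm
                  for a in range(0, 100, 9)]  # E fixed at 1
        assert all(x <= y + 1e-12 for x, y in zip(values, values[1:]))

    def test_shrinkage_stays_between_unity_and_observed_ratio(self):
        for a in (30, 80, 200):
            t = ContingencyTable(a, 300, 50, 30000)
            r = ebgm(t, DIFFUSE)
            assert 1.0 <= r.ebgm <= t.a / t.expected * 1.01

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            ebgm(ContingencyTable(0, 0, 0, 5), INFORMATIVE)


class TestSignalCriterion:
    def test_all_rules_required(self):
        from pvfaers.disproportionality import EbgmResult, IcResult, RorResult
        passing = (RorResult(3.03, 2.37, 3.88, False), IcResult(1.58, 1.23, 20.0),
                   EbgmResult(3.0, 2.44, 3.7, 0.5))
        assert evaluate_signal(*passing).is_signal

        low_ror = (RorResult(2.99, 1.5, 5.9, False), IcResult(1.58, 1.23, 20.0),
                   EbgmResult(3.0, 2.44, 3.7, 0.5))
        decision = evaluate_signal(*low_ror)
        assert not decision.is_signal
        assert not decision.criteria_met["ror_rule"]
        assert decision.criteria_met["ic_rule"] and decision.criteria_met["ebgm_rule"]

    @pytest.mark.parametrize("ror_v,low,ic025,eb05,expected", [
        (3.0, 1.01, 0.01, 2.01, True),    # all rules exactly cleared
        (3.0, 1.0, 0.5, 3.0, False),      # CI lower bound not > 1
        (5.0, 2.0, 0.0, 3.0, False),      # IC025 not > 0
        (5.0, 2.0, 1.0, 2.0, False),      # EB05 not > 2
    ])
    def test_rule_boundaries(self, ror_v, low, ic025, eb05, expected):
        from pvfaers.disproportionality import EbgmResult, IcResult, RorResult
        decision = evaluate_signal(RorResult(ror_v, low, ror_v * 2, False),
                                   IcResult(ic025 + 1, ic025, 10.0),
                                   EbgmResult(eb05 + 1, eb05, eb05 + 2, 0.5))
        assert decision.is_signal is expected
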