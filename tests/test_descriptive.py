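import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from pvfaers.descriptive import (FreqRow, ae_total, concomitant_ranking, demographics_table,
                                 endpoint_frequency_table, percent, sex_contrast,
                                 significance_stars, subgroup_compare)
from pvfaers.io_faers import DrugEntry
from pvfaers.screening import ConfigurationError
from pvfaers.synthetic import Association, DrugSpec, SyntheticConfig, generate
from tests.conftest import make_case


class TestPercentConvention:
    @pytest.mark.parametrize("count,denom,expected", [
        (26, 1455, 1.79), (930, 1455, 63.92), (906, 1959, 46.25),
        (1556, 19482, 7.99), (0, 100, 0.0), (1, 3, 33.33), (5, 0, 0.0),
    ])
    def test_half_up_two_decimals(self, count, denom, expected):
        assert percent(count, denom) == expected

    def test_freq_row_revalidates_percent(self):
        FreqRow("v", "l", 26, 1.79, 1455)
        with pytest.raises(ValueError):
            FreqRow("v", "l", 26, 1.80, 1455)


class TestDemographics:
    def test_empty_cohort(self):
        table = demographics_table([])
        assert table.rows == [] and table.weight_median is None

    def test_outcome_denominator_is_sum_of_category_counts(self):
        """A report may carry several outcome codes; each is counted and the
        block's denominator is the code total, not the cohort size."""
        cohort = [
            make_case(case_id="1", outcomes=("hospitalization", "death")),
            make_case(case_id="2", outcomes=("hospitalization",)),
            make_case(case_id="3", outcomes=("other_serious",)),
            make_case(case_id="4"),
        ]
        rows = {(r.variable, r.level): r for r in demographics_table(cohort).rows}
        hosp = rows[("serious_outcome", "hospitalization")]
        assert hosp.count == 2 and hosp.denominator == 4  # 2+1+1 outcome codes
        assert hosp.percent == 50.0
        # while the categorical blocks use the cohort size
        assert rows[("sex", "female")].denominator == 4

    def test_weight_median_iqr(self):
        cohort = [make_case(case_id=str(i), weight_kg=w)
                  for i, w in enumerate([60.0, 70.0, 80.0, None])]
        table = demographics_table(cohort)
        assert table.weight_median == 70.0
        assert table.weight_q1 == 65.0 and table.weight_q3 == 75.0


class TestEndpointFrequencies:
    def _cohorts(self):
        bsz = [
            make_case(case_id="b1", sex="female", reactions=["Dyskinesia", "Tremor"]),
            make_case(case_id="b2", sex="male", reactions=["Dystonia"]),
            make_case(case_id="b3", sex="male", reactions=["Fatigue"]),
        ]
        cd = [
            make_case(case_id="c1", sex="female", reactions=["On and off phenomenon"]),
            make_case(case_id="c2", sex="female", reactions=["Tremor", "Fatigue"]),
        ]
        return {"BSZ": bsz, "CD": cd}

    def test_denominators_are_ae_totals(self, endpoints):
        cohorts = self._cohorts()
        assert ae_total(cohorts["BSZ"]) == 4 and ae_total(cohorts["CD"]) == 3
        rows = {(r.variable, r.level): r for r in endpoint_frequency_table(cohorts, endpoints)}

        total = rows[("dyskinesia", "total")]
        assert (total.count, total.denominator) == (2, 7)
        sub = rows[("dyskinesia", "BSZ")]
        assert (sub.count, sub.denominator) == (2, 4)
        female = rows[("dyskinesia", "BSZ/female")]
        assert (female.count, female.denominator) == (1, 2)
        onoff = rows[("on_off_phenomenon", "CD")]
        assert (onoff.count, onoff.denominator) == (1, 3)

    def test_case_counts_once_per_endpoint(self, endpoints):
        cohorts = {"X": [make_case(reactions=["Dyskinesia", "Dystonia", "Ballismus"])]}
        rows = {(r.variable, r.level): r for r in endpoint_frequency_table(cohorts, endpoints)}
        assert rows[("dyskinesia", "X")].count == 1


class TestConcomitantRanking:
    def test_planted_frequencies_recovered(self, tmp_path, queries):
        """Co-medication marginals planted in the generator come back in
        order (pramipexole > amantadine > rasagiline)."""
        cfg = SyntheticConfig(
            n_cases=2500, seed=21,
            drugs=(
                DrugSpec("MADOPAR", "LEVODOPA\\BENSERAZIDE", 1.0, (("ORAL", 1.0),),
                         (("PS", 1.0),), pd_indication_p=1.0, target_label="BSZ"),
                DrugSpec("MIRAPEX", "PRAMIPEXOLE", 0.30, (("ORAL", 1.0),), (("C", 1.0),)),
                DrugSpec("AMANTADINE", "AMANTADINE", 0.15, (("ORAL", 1.0),), (("C", 1.0),)),
                DrugSpec("AZILECT", "RASAGILINE", 0.05, (("ORAL", 1.0),), (("C", 1.0),)),
            ),
            pt_probs=(("Dizziness", 0.6), ("Nausea", 0.1)),
            duplicate_fraction=0.0,
        )
        result = generate(cfg)
        from pvfaers.io_faers import deduplicate
        cases = deduplicate(result.as_raw_tables())
        ranking = concomitant_ranking(cases, queries[0], k=5)
        assert [name for name, _, _ in ranking] == ["pramipexole", "amantadine", "rasagiline"]
        counts = {name: cnt for name, cnt, _ in ranking}
        assert counts["pramipexole"] > counts["amantadine"] > counts["rasagiline"]

    def test_target_and_partner_entries_excluded(self, queries):
        case = make_case(drugs=[
            DrugEntry("MADOPAR", "LEVODOPA\\BENSERAZIDE", "suspect_primary", "oral",
                      ("Parkinson's disease",)),
            DrugEntry("MIRAPEX", "PRAMIPEXOLE DIHYDROCHLORIDE", "concomitant", "oral", ()),
        ])
        ranking = concomitant_ranking([case], queries[0])
        assert ranking == [("pramipexole", 1, 100.0)]

    def test_no_comedication_gives_empty_ranking(self, queries):
        assert concomitant_ranking([make_case()], queries[0]) == []

    def test_k_larger_than_dictionary(self, queries):
        case = make_case(drugs=[
            make_case().drugs[0],
            DrugEntry("COMTAN", "ENTACAPONE", "concomitant", "oral", ()),
        ])
        ranking = concomitant_ranking([case], queries[0], k=500)
        assert ranking == [("entacapone", 1, 100.0)]

    def test_empty_dictionary_is_configuration_error(self, queries):
        with pytest.raises(ConfigurationError):
            concomitant_ranking([make_case()], queries[0], anti_pd_drugs=[])


class TestSubgroupCompare:
    def test_identical_proportions(self):
        t = subgroup_compare([[10, 90], [10, 90]])
        assert t.method == "chi_square"
        assert t.statistic == pytest.approx(0.0)
        assert t.p_value == pytest.approx(1.0)

    def test_pearson_statistic_matches_closed_form(self):
        """Oracle: chi2 = N(ad-bc)^2 / (row and column margin product)."""
        a, b, c, d = 20, 80, 5, 95
        n = a + b + c + d
        oracle = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        t = subgroup_compare([[a, b], [c, d]])
        assert t.method == "chi_square"
        assert t.statistic == pytest.approx(oracle)

    def test_small_expected_cells_use_exact_test(self):
        t = subgroup_compare([[1, 9], [9, 21]])  # smallest expected cell 2.5
        assert t.method == "fisher"
        assert 0 <= t.p_value <= 1

    def test_expected_cell_of_exactly_five_stays_chi_square(self):
        assert subgroup_compare([[1, 9], [9, 1]]).method == "chi_square"

    def test_zero_margin_degenerate(self):
        t = subgroup_compare([[0, 10], [0, 20]])
        assert t.degenerate and t.p_value == 1.0

    @settings(max_examples=40, derandomize=True)
    @given(a=st_.integers(0, 60), b=st_.integers(0, 60),
           c=st_.integers(0, 60), d=st_.integers(0, 60))
    def test_two_sided_p_symmetric_under_row_and_column_swaps(self, a, b, c, d):
        p0 = subgroup_compare([[a, b], [c, d]]).p_value
        assert subgroup_compare([[c, d], [a, b]]).p_value == pytest.approx(p0)
        assert subgroup_compare([[b, a], [d, c]]).p_value == pytest.approx(p0)

    def test_sex_contrast_branch(self, endpoints):
        ep = next(e for e in endpoints if e.name == "dyskinesia")
        cohort = [make_case(case_id=f"f{i}", sex="female",
                            reactions=["Dyskinesia", "Tremor"]) for i in range(30)]
        cohort += [make_case(case_id=f"m{i}", sex="male",
                             reactions=["Tremor", "Fall"]) for i in range(30)]
        t = sex_contrast(cohort, ep)
        assert t.p_value < 0.001

    def test_stars(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.01) == "*"
        assert significance_stars(0.2) == ""
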