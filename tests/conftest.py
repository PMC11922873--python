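from __future__ import annotations

import warnings

import pytest

from pvfaers.io_faers import CaseReport, DrugEntry, deduplicate, load_pt_soc, read_quarter
from pvfaers.screening import default_queries
from pvfaers.synthetic import default_config, generate
from pvfaers.term_mapping import load_endpoints

warnings.filterwarnings("ignore", message="PT probabilities capped")


@pytest.fixture(scope="session")
def endpoints():
    return load_endpoints()


@pytest.fixture(scope="session")
def pt_soc():
    return load_pt_soc()


@pytest.fixture(scope="session")
def queries():
    return default_queries()


@pytest.fixture(scope="session")
def bsz_query(queries):
    return queries[0]


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One modest synthetic quarter shared across tests: the generation
    result (with ground truth), the output directory and the deduplicated
    case list."""
    outdir = tmp_path_factory.mktemp("faers_small")
    result = generate(default_config(n_cases=1500, seed=5), outdir)
    cases = deduplicate(read_quarter(outdir))
    return result, outdir, cases


def make_case(case_id="C1", drugs=None, reactions=None, indications=None,
              sex="female", age_years=70.0, outcomes=(), reporter="physician",
              country_group="Europe", weight_kg=70.0, received_date="20240115"):
    """Minimal CaseReport factory for predicate-level tests."""
    from pvfaers.io_faers import age_band
    drugs = drugs if drugs is not None else [
        DrugEntry("MADOPAR (levodopa/benserazide)", "LEVODOPA\\BENSERAZIDE",
                  "suspect_primary", "oral", ("Parkinson's disease",))]
    reactions = list(reactions) if reactions is not None else ["Dyskinesia"]
    return CaseReport(
        case_id=case_id, primary_id=case_id + "1", received_date=received_date,
        age_years=age_years, age_band=age_band(age_years), sex=sex,
        weight_kg=weight_kg, reporter=reporter, country_group=country_group,
        outcomes=tuple(outcomes), drugs=drugs, reactions=reactions,
        indications=list(indications) if indications is not None else [],
    )


@pytest.fixture
def case_factory():
    return make_case
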