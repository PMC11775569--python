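import logging

import numpy as np
import pytest

from preciseadr.cohort import AdverseEventReport, build_vocabulary
from preciseadr.graph import FeatureConfig, build_graph
from preciseadr.simulate import CohortSpec, generate_cohort

logging.getLogger("preciseadr").setLevel(logging.ERROR)


def make_report(rid="r1", diseases=("D1",), drugs=("M1",), age=50, sex=1,
                weight=70.0, qualification=1, date="2020-01-01",
                adrs=("S1",)):
    return AdverseEventReport(report_id=rid, diseases=frozenset(diseases),
                              drugs=frozenset(drugs), age=age, sex=sex,
                              weight=weight, qualification=qualification,
                              date=date, adrs=frozenset(adrs))


@pytest.fixture
def tiny_reports():
    """Six hand-built reports over 3 diseases, 3 drugs, 3 ADRs."""
    return [
        make_report("r1", ("D1", "D2"), ("M1",), 63, 2, 70.5, 1, adrs=("S1", "S3")),
        make_report("r2", ("D2",), ("M2",), 40, 1, None, 2, adrs=("S2",)),
        make_report("r3", ("D3",), ("M1", "M3"), 8, 2, 25.0, 3, adrs=("S1",)),
        make_report("r4", ("D1",), ("M2",), 75, 1, 80.0, 1, adrs=("S2", "S3")),
        make_report("r5", ("D2", "D3"), ("M3",), 30, 2, 60.0, 2, adrs=("S3",)),
        make_report("r6", ("D1",), ("M1",), 55, 1, 90.0, 1, adrs=("S1",)),
    ]


@pytest.fixture
def tiny_vocab(tiny_reports):
    return build_vocabulary(tiny_reports)


@pytest.fixture
def tiny_graph(tiny_reports, tiny_vocab):
    return build_graph(tiny_reports, tiny_vocab, FeatureConfig())


def null_spec(n_patients=200, n_adrs=8, base_logit=-2.5, noise_rate=0.0,
              seed=0, **kwargs):
    """A cohort spec with no planted effects."""
    n_dis, n_drug = kwargs.pop("n_diseases", 12), kwargs.pop("n_drugs", 12)
    return CohortSpec(
        n_patients=n_patients, n_diseases=n_dis, n_drugs=n_drug,
        n_adrs=n_adrs,
        base_adr_logit=np.full(n_adrs, float(base_logit)),
        drug_effect=np.zeros((n_drug, n_adrs)),
        gender_effect=np.zeros(n_adrs),
        age_effect=np.zeros((n_adrs, 3)),
        noise_rate=noise_rate, seed=seed, **kwargs)


@pytest.fixture
def small_cohort():
    reports, truth = generate_cohort(null_spec(n_patients=120, seed=7))
    return reports
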