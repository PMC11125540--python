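import numpy as np
import pytest

from colosim import make_default_params, presimulate, replay_cohort
from colosim.outcomes import CohortOutcomes
from colosim.params import ColonoscopyParams


@pytest.fixture(scope="session")
def default_bundle():
    return make_default_params("default_us")


@pytest.fixture(scope="session")
def null_bundle():
    return make_default_params("null_disease")


@pytest.fixture(scope="session")
def cohort_50k(default_bundle):
    """Shared medium cohort with its no-screening arm (CRN baseline)."""
    cohort = presimulate(50_000, default_bundle, seed=101)
    baseline = replay_cohort(cohort, default_bundle, ())
    outcomes = CohortOutcomes.from_record(baseline, cohort, default_bundle.costs)
    return cohort, baseline, outcomes


def perfect_colonoscopy(bundle) -> ColonoscopyParams:
    d = bundle.colonoscopy.to_dict()
    d.update(
        reach_prob_splenic=1.0, reach_prob_hepatic=1.0, reach_prob_cecum=1.0,
        detection_sensitivity=[1.0] * 6, cancer_detection_sensitivity=1.0,
        complication_prob={"perforation": 0.0, "bleeding": 0.0, "serosa_burn": 0.0},
        adherence=1.0,
    )
    return ColonoscopyParams.from_dict(d)


def null_colonoscopy(bundle) -> ColonoscopyParams:
    d = bundle.colonoscopy.to_dict()
    d.update(
        detection_sensitivity=[0.0] * 6, cancer_detection_sensitivity=0.0,
        complication_prob={"perforation": 0.0, "bleeding": 0.0, "serosa_burn": 0.0},
    )
    return ColonoscopyParams.from_dict(d)
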