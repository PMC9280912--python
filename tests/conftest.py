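import numpy as np
import pytest

from ceus_tirads.cohort_model import (
    Arrival,
    Category,
    CEUSFeatureSet,
    Cohort,
    EnhancementDegree,
    Homogeneity,
    NoduleRecord,
    Pathology,
    Pattern,
    USFeatureSet,
    Washout,
)
from ceus_tirads.regrading import apply_model
from ceus_tirads.synthetic_cohort import build_fixture


def enhancing_panel(
    degree=EnhancementDegree.ISO,
    arrival=Arrival.EQUAL_OR_EARLIER,
    homogeneity=Homogeneity.HOMOGENEOUS,
    pattern=Pattern.DIFFUSE,
    washout=Washout.LATER_OR_EQUAL,
    ring=False,
) -> CEUSFeatureSet:
    return CEUSFeatureSet(
        enhancement_degree=degree,
        arrival=arrival,
        homogeneity=homogeneity,
        pattern=pattern,
        washout=washout,
        peripheral_ring=ring,
    )


@pytest.fixture
def fig2_record() -> NoduleRecord:
    """Solid nodule with an irregular margin (two suspicious signs → 4b)
    showing a completely bland CEUS panel (score 0); Hashimoto's thyroiditis."""
    return NoduleRecord(
        id="fig2",
        us=USFeatureSet(solid=True, irregular_or_illdefined_margin=True),
        ceus=enhancing_panel(),
        pathology=Pathology.BENIGN,
        age=38,
        sex=None,
    )


@pytest.fixture
def fig3_record() -> NoduleRecord:
    """Same US presentation (4b) but a fully malignant-pattern CEUS panel;
    papillary thyroid carcinoma."""
    return NoduleRecord(
        id="fig3",
        us=USFeatureSet(solid=True, irregular_or_illdefined_margin=True),
        ceus=enhancing_panel(
            degree=EnhancementDegree.HYPO,
            arrival=Arrival.LATER,
            homogeneity=Homogeneity.HETEROGENEOUS,
            pattern=Pattern.CENTRIPETAL,
        ),
        pathology=Pathology.MALIGNANT,
        age=35,
    )


@pytest.fixture(scope="session")
def fixture_result():
    return build_fixture()


@pytest.fixture(scope="session")
def fixture_frame(fixture_result):
    return apply_model(fixture_result.cohort)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220630)
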