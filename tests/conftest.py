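import numpy as np
import pytest

from dfcalff import (DfcAlffExtractor, GeneratorConfig, LinkIndex,
                     NetworkPartition, generate_cohort, nested_loocv)
from dfcalff.contributions import DEFAULT_NETWORKS
from dfcalff.variability import FeatureTable

# Six networks over 30 ROIs, sized so one pair (CON-FPN) can host ten
# ROI-disjoint planted links; the standard strong-effect test cohort.
SIX_NETS_30 = (10, 10, 3, 3, 2, 2)
PLANTED_NEG = tuple((i, 10 + i) for i in range(10))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """12-ROI, 10-subject cohort with one planted negative-effect link."""
    config = GeneratorConfig(n_subjects=10, n_rois=12, effect_links_neg=((0, 2),),
                             seed=42)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def effect_cohort():
    """30-ROI, 60-subject cohort, ten planted CON-FPN negative-effect links."""
    config = GeneratorConfig(
        n_subjects=60, n_rois=30, network_sizes=SIX_NETS_30,
        effect_links_neg=PLANTED_NEG, seed=0,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def planted_links():
    index = LinkIndex(30)
    return sorted(index.link_of(*pair) for pair in PLANTED_NEG)


@pytest.fixture(scope="session")
def six_net_partition():
    return NetworkPartition.from_sizes(dict(zip(DEFAULT_NETWORKS, SIX_NETS_30)))


@pytest.fixture(scope="session")
def effect_features(effect_cohort):
    """z-scored dFC-ALFF feature table of the strong-effect cohort."""
    stacked = effect_cohort.stacked()
    values = DfcAlffExtractor().fit(stacked).transform(stacked)
    return FeatureTable(values, "dfc_alff", LinkIndex(30),
                        effect_cohort.subject_ids, effect_cohort.scores,
                        effect_cohort.control_scores)


@pytest.fixture(scope="session")
def effect_cpm_result(effect_features):
    """Nested-LOOCV result on the strong-effect cohort (computed once)."""
    return nested_loocv(effect_features)
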