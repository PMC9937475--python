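import numpy as np
import pytest
from hypothesis import settings

# property tests must behave identically on every run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from lrobserver import (
    GaussianDensity,
    Group,
    Hemisphere,
    LRObserverModel,
    MTL,
    Region,
    SubjectRecord,
)

# Published construction-cohort summaries used throughout the tests.
MTL_AD = (14697.2, 2511.1)
MTL_NC = (17943.8, 2052.8)
HIPPO_AD = (5962.1, 1025.3)
HIPPO_NC = (7238.4, 870.0)
AMYG_AD = (2340.9, 548.1)
AMYG_NC = (2957.1, 476.6)


@pytest.fixture
def mtl_model() -> LRObserverModel:
    """LR observer for total MTL volume built from the published summaries."""
    return LRObserverModel(
        normal_density=GaussianDensity(*MTL_NC),
        diseased_density=GaussianDensity(*MTL_AD),
        measure=MTL,
    )


def make_record(
    subject_id: str = "s1",
    group: Group = Group.AD,
    value: float = 1.0,
) -> SubjectRecord:
    """A complete record with every (region, hemisphere) volume equal to value."""
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        volumes={(r, h): value for r in Region for h in Hemisphere},
    )


def mann_whitney_auc(pos, neg) -> float:
    """Brute-force pairwise AUC oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)
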