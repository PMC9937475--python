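"""Published summary statistics of the ADNI construction cohorts.

These are the reported per-group volumetric summaries (mm^3) of the
263 AD / 263 NC ADNI-derived construction cohorts: hippocampal left/right
means, SDs and left-right Pearson correlations, and bilateral means/SDs for
each MTL sub-region and the total MTL.  They parameterise the synthetic
cohort generator and allow the binormal detectability index to be computed
without subject-level data.
"""
from __future__ import annotations

from dataclasses import dataclass

from .cohort import Group, Hemisphere, Region

#: Construction-cohort sizes (AD, NC).
ADNI_N = (263, 263)
#: Held-out test-cohort sizes (AD, NC).
MIRIAD_N = (46, 23)


@dataclass(frozen=True)
class GroupSummary:
    """Mean and standard deviation of a volumetric measure, mm^3."""

    mean: float
    sd: float


#: Hippocampal volumes by hemisphere.
HIPPOCAMPUS_BY_SIDE: dict[tuple[Group, Hemisphere], GroupSummary] = {
    (Group.AD, Hemisphere.LEFT): GroupSummary(2933.4, 540.1),
    (Group.AD, Hemisphere.RIGHT): GroupSummary(3030.7, 539.7),
    (Group.NC, Hemisphere.LEFT): GroupSummary(3562.9, 431.1),
    (Group.NC, Hemisphere.RIGHT): GroupSummary(3679.4, 476.1),
}

#: Pearson correlation between left and right hippocampal volumes.
HIPPOCAMPUS_LR_CORRELATION: dict[Group, float] = {
    Group.AD: 0.798,
    Group.NC: 0.841,
}

#: Bilateral (left + right) sums per MTL sub-region.
BILATERAL: dict[Region, dict[Group, GroupSummary]] = {
    Region.HIPPOCAMPUS: {
        Group.AD: GroupSummary(5962.1, 1025.3),
        Group.NC: GroupSummary(7238.4, 870.0),
    },
    Region.AMYGDALA: {
        Group.AD: GroupSummary(2340.9, 548.1),
        Group.NC: GroupSummary(2957.1, 476.6),
    },
    Region.ENTORHINAL: {
        Group.AD: GroupSummary(3036.7, 813.7),
        Group.NC: GroupSummary(3912.4, 763.3),
    },
    Region.PARAHIPPOCAMPAL: {
        Group.AD: GroupSummary(3355.5, 616.6),
        Group.NC: GroupSummary(3834.9, 518.2),
    },
}

#: Total MTL (all four regions, both hemispheres).
MTL_TOTAL: dict[Group, GroupSummary] = {
    Group.AD: GroupSummary(14697.2, 2511.1),
    Group.NC: GroupSummary(17943.8, 2052.8),
}
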