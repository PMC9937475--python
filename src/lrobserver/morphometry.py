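"""Descriptive volumetry: left/right asymmetry, group reductions, pairing.

Percent differences use the midpoint-mean convention
100 * |a - b| / ((a + b) / 2): the difference is expressed relative to the
mean of the two quantities, the convention under which hippocampal
asymmetry and AD-vs-NC reduction percentages are mutually consistent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .cohort import CohortTable, Group, Hemisphere, Region
from .errors import IncompleteRecordError, InsufficientDataError

__all__ = [
    "AsymmetrySummary",
    "percent_difference",
    "group_reduction",
    "paired_correlation",
    "asymmetry_summary",
    "mean_percent_asymmetry",
    "format_p",
]


def percent_difference(a: float, b: float) -> float:
    """100 * |a - b| relative to the midpoint mean (a + b) / 2."""
    if not (a > 0 and b > 0):
        raise ValueError(f"inputs must be positive, got ({a!r}, {b!r})")
    return 100.0 * abs(a - b) / ((a + b) / 2.0)


def group_reduction(nc_mean: float, ad_mean: float) -> float:
    """Percent volume reduction of AD relative to NC (midpoint convention)."""
    return percent_difference(nc_mean, ad_mean)


def paired_correlation(left, right) -> tuple[float, float]:
    """Pearson r between paired left/right volumes with two-sided p-value."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right must be paired (equal length)")
    if left.size < 3:
        raise InsufficientDataError("paired correlation needs at least 3 subjects")
    if np.std(left) == 0 or np.std(right) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = pearsonr(left, right)
    return float(r), float(p)


@dataclass(frozen=True)
class AsymmetrySummary:
    """Per-group left/right summary for one region.

    ``mean_diff`` is signed (left - right; negative when the left hemisphere
    is the smaller); ``percent_asymmetry`` is its magnitude relative to the
    midpoint of the two hemisphere means.  ``pearson_r``/``p_value`` are NaN
    below 3 subjects.
    """

    group: Group
    n: int
    mean_left: float
    mean_right: float
    mean_diff: float
    sd_diff: float
    percent_asymmetry: float
    pearson_r: float
    p_value: float


def asymmetry_summary(
    cohort: CohortTable, region: Region
) -> dict[Group, AsymmetrySummary]:
    """Left/right asymmetry statistics per group for one region."""
    out: dict[Group, AsymmetrySummary] = {}
    for group in (Group.AD, Group.NC):
        recs = [r for r in cohort if r.group is group]
        if not recs:
            continue
        lefts, rights = [], []
        for rec in recs:
            for hemi, store in ((Hemisphere.LEFT, lefts), (Hemisphere.RIGHT, rights)):
                try:
                    store.append(rec.volumes[(region, hemi)])
                except KeyError:
                    raise IncompleteRecordError(
                        f"subject {rec.subject_id!r} lacks ({region.value}, {hemi.value})"
                    ) from None
        left = np.asarray(lefts)
        right = np.asarray(rights)
        diffs = left - right
        mean_left = float(left.mean())
        mean_right = float(right.mean())
        if left.size >= 3 and np.std(left) > 0 and np.std(right) > 0:
            r, p = paired_correlation(left, right)
        else:
            r, p = float("nan"), float("nan")
        out[group] = AsymmetrySummary(
            group=group,
            n=int(left.size),
            mean_left=mean_left,
            mean_right=mean_right,
            mean_diff=float(diffs.mean()),
            sd_diff=float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0,
            percent_asymmetry=(
                percent_difference(mean_left, mean_right) if mean_left != mean_right else 0.0
            ),
            pearson_r=r,
            p_value=p,
        )
    return out


def mean_percent_asymmetry(summaries: dict[Group, AsymmetrySummary]) -> float:
    """Arithmetic mean of the per-group asymmetry percentages."""
    values = [s.percent_asymmetry for s in summaries.values()]
    if not values:
        raise InsufficientDataError("no group summaries")
    return float(np.mean(values))


def format_p(p: float, decimals: int = 3) -> str:
    """Display p-values to 3 decimals, flooring at '< 0.001'."""
    floor = 10.0 ** (-decimals)
    if p < floor:
        return f"< {floor:.{decimals}f}"
    return f"{p:.{decimals}f}"
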