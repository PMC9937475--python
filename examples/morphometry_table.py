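"""Hippocampal left/right asymmetry on a synthetic construction cohort.

Reproduces the descriptive volumetry: per-group hemisphere means, the
signed left-minus-right difference, its percentage of the midpoint mean,
and the paired left-right Pearson correlation.
"""
from lrobserver import (
    Region,
    asymmetry_summary,
    default_recipe,
    generate_cohort,
    group_reduction,
    mean_percent_asymmetry,
)
from lrobserver.morphometry import format_p

cohort = generate_cohort(default_recipe("adni_like", seed=7))
summaries = asymmetry_summary(cohort, Region.HIPPOCAMPUS)

for group, s in summaries.items():
    print(
        f"{group.value}: left {s.mean_left:7.1f}  right {s.mean_right:7.1f}  "
        f"diff {s.mean_diff:+7.1f} +/- {s.sd_diff:.1f} mm^3  "
        f"asymmetry {s.percent_asymmetry:.2f}%  r={s.pearson_r:.3f} "
        f"(p {format_p(s.p_value)})"
    )

print(f"\nmean asymmetry across groups: {mean_percent_asymmetry(summaries):.2f}%")
ad, nc = summaries[list(summaries)[0]], summaries[list(summaries)[1]]
reduction = group_reduction(
    nc.mean_left + nc.mean_right, ad.mean_left + ad.mean_right
)
print(f"AD bilateral hippocampal volume is {reduction:.1f}% below controls.")
print("The left hemisphere is slightly smaller than the right in both groups,")
print("but the asymmetry itself does not distinguish AD from controls.")
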