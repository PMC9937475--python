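"""Score a single subject with the likelihood-ratio ideal observer.

The observer compares the subject's total MTL volume x against the diseased
and normal Gaussian densities via y = log f_d(x) - log f_n(x) and calls
"diseased" when y > 0.  The decision boundary (inner root of y = 0) sits
between the two group means.
"""
from lrobserver import (
    GaussianDensity,
    LRObserverModel,
    MTL,
    decision_boundaries,
    log_likelihood_ratio,
)

model = LRObserverModel(
    normal_density=GaussianDensity(17943.8, 2052.8),    # controls
    diseased_density=GaussianDensity(14697.2, 2511.1),  # AD patients
    measure=MTL,
)

inner, outer = decision_boundaries(model)
print(f"decision boundary: MTL volume below {inner:.0f} mm^3 is called diseased")
print(f"(a second, clinically irrelevant root lies at {outer:.0f} mm^3)\n")

for x in (13000.0, 14697.2, 16170.0, 17943.8, 20000.0):
    score = log_likelihood_ratio(model, x)
    print(f"  MTL volume {x:8.1f} mm^3 -> y = {score.y:+.3f} -> {score.decision}")

print("\ny is the log odds of disease relative to equal priors: +1.05 at the")
print("AD mean volume, -1.04 at the control mean, ~0 at the boundary.")
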