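# Methods

## The decision model

The package implements a one-dimensional likelihood-ratio ideal observer
for a volumetric measure x (mm³). Class-conditional densities f_n (normal
controls, NC) and f_d (Alzheimer's disease, AD) are fitted per cohort; a
subject is scored by the natural-log likelihood ratio
y = log f_d(x) − log f_n(x) and called diseased when y > 0. The rule
assumes (i) the measure is approximately Gaussian within each group, (ii)
subjects are independent draws from their group populations, and (iii)
equal misclassification costs and priors — the y = 0 threshold is the
equal-prior Bayes rule. No gender, brain-size or age normalization is
applied to the volumes; the analysis deliberately uses the raw mm³ measure
alone.

Scores of exactly zero are called normal. Only y > 0 is defined as
diseased and y < 0 as normal; the tie is adjudicated to the null
(non-diseased) class, the conservative clinical convention. The decision is
invariant to the logarithm base; natural log is used because it simplifies
the Gaussian algebra.

All Gaussian evaluation is in the log domain: logpdf differences are exact
where linear-domain pdfs would underflow (|z| ≳ 37), so extreme volumes
still receive finite scores and the correct sign.

For the Gaussian backend, y(x) is the quadratic A x² + B x + C with
A = 1/(2σ_n²) − 1/(2σ_d²); its real roots are the decision boundaries,
computed by the numerically stable quadratic formula and verified to give
|y| < 1e-9. With σ_d > σ_n (the AD group is more dispersed) there are two
roots; only the inner one, between the group means, is clinically relevant.
Identical densities are reported as degenerate rather than returning an
empty root set, because y ≡ 0 is not "no boundary" but "no information".

## Density estimation

`fit_gaussian` uses the arithmetic mean and the n−1 sample standard
deviation (the estimator choice is immaterial at n = 263). Densities are
untruncated despite volumes being positive: at brain-volume scale the mass
below zero is < 1e-8. A Gaussian-kernel density estimate
(`scipy.stats.gaussian_kde`, Silverman bandwidth — the default of R's
`density()`) is available as a nonparametric cross-check backend; the test
suite verifies KDE/Gaussian agreement on large normal samples. Model
serialization stores μ and σ as decimal strings (`repr`), which round-trips
IEEE doubles bit-exactly.

## ROC analysis

The empirical ROC sweeps thresholds over unique score values (tied scores
collapse to single vertices) and integrates by the trapezoidal rule, which
equals the Mann–Whitney statistic P(score_D > score_N) + ½P(tie); the test
suite checks this identity exactly against a brute-force pairwise count.
The construction is delegated to scikit-learn's `roc_curve`/`auc`.
The binormal closed form Az = Φ(|μ_n − μ_d|/√(σ_n² + σ_d²)) is exposed
separately; both routes are reported because summary tables are naturally
desk-checked via the binormal form while subject-level data support the
empirical one. Confidence bounds use the Hanley–McNeil standard error with
a normal approximation, clipped to [0, 1]; a bootstrap oracle in the tests
confirms its accuracy at the 46/23 test-cohort size.

## Morphometry conventions

Percent differences use the midpoint-mean denominator
100·|a − b| / ((a + b)/2), the only convention that makes the hippocampal
asymmetry and AD-reduction percentages mutually consistent (e.g. a
629.5 mm³ left-hippocampus reduction on a 3248.15 mm³ midpoint is 19.4%,
where a max-denominator convention would give 17.7%). Left-minus-right
differences are stored signed (negative = left smaller); the percentage
reports the magnitude. Paired left–right association is the Pearson
product-moment correlation with a two-sided t-test p-value, displayed to
three decimals and floored at "< 0.001". The cross-group asymmetry figure
is the arithmetic mean of the per-group percentages.

## Synthetic cohorts

The generator emulates the study's two cohorts: an ADNI-like construction
cohort (263 AD / 263 NC) and a MIRIAD-like held-out test cohort
(46 AD / 23 NC) drawn from the same densities. Per subject and region,
(left, right) volumes are drawn from a bivariate normal. Hippocampal
parameters (means, SDs, left–right correlations 0.798/0.841) come directly
from the published by-hemisphere summaries. The other regions are published
only as bilateral totals; their means are split 50/50 and the
per-hemisphere SD is sd_bilateral/√(2(1+ρ)) at a default left–right
correlation ρ = 0.8, so the bilateral sum reproduces the published
bilateral mean and SD exactly.

Regions within a subject are **not** independent: the published total-MTL
SD (2511 mm³ AD, 2053 mm³ NC) is far larger than independent region sums
would produce (≈1546 mm³ AD), reflecting globally correlated atrophy. The
generator therefore adds a shared per-subject atrophy factor: standardized
hemisphere volumes are √ρ_x·u + √(1−ρ_x)·w with u common to all regions,
inducing a single cross-region correlation ρ_x per group. The default
recipes calibrate ρ_x in closed form against the published MTL SD
(ρ_x ≈ 0.53 for AD, 0.42 for NC); ρ_x = 0 recovers independent regions.
Within-region left–right correlations are preserved by compensating the
residual pair correlation.

Positivity is enforced by rejection (whole-subject redraw), which at these
parameters rejects ~1e-8 of draws and leaves moments essentially exact.
Generation is deterministic given the recipe seed (documented default
20230); identical recipes serialize to byte-identical CSVs.

What the generator does **not** emulate: age/gender structure and
covariate effects, scanner/site heterogeneity between the construction and
test cohorts, non-Gaussian tails, and inter-region correlation structure
beyond the single shared factor. Passing synthetic tests therefore
demonstrates the pipeline's statistical correctness under the model's own
assumptions, not robustness to real-cohort violations of them. In
particular, the real held-out test cohort is easier than the construction
densities predict (its empirical AUC of ~0.93 exceeds the construction
Az ≈ 0.84); the synthetic twin, drawn from the construction densities,
reproduces the predicted operating point (sensitivity ≈ 0.72,
specificity ≈ 0.81 for the MTL measure), not the published test rates.

## Pipeline and problem sizes

`run_experiment` resolves cohort sources (CSV paths or `simulate:` recipe
references), fits per-measure models, writes model JSON, ROC CSV and a
JSON report, and logs cohort sizes, seed, backend and measure per stage;
all randomness derives from the config seed. Test-suite simulations use
cohort sizes chosen for tight-but-fast Monte-Carlo bounds: 263/263 for
parameter recovery (the construction size), 5 000–20 000 draws per class
where an empirical area must pin down Az to ±0.005–0.01, and 2×10⁷ draws
for the ranking-probability oracle behind the binormal form.

## Known limitations

- Single-measure observers only; no joint multivariate likelihood ratio.
- Equal-prior, equal-cost threshold only; no prevalence weighting.
- The KDE backend has no decision-boundary solver and is not serializable.
- FreeSurfer parsing covers the standard aseg/aparc stats layout
  (Desikan-Killiany names) and nothing else.
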