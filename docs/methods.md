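# Methods

## Model and assumptions

The ¹⁵N natural-abundance estimate of symbiotic N₂ fixation treats a
legume's shoot N as a two-source mixture: soil mineral N, proxied by the
mean δ¹⁵N of non-fixing reference plants grown in the same plots, and
atmospheric N₂, whose plant signature is the B value — the δ¹⁵N of the
same legume grown with N₂ as its only N source. %Ndfa is the lever-rule
position of the legume's δ¹⁵N between those two endpoints. The method
assumes (i) reference plants and legumes explore the same soil N pool over
the same period, (ii) the glasshouse B value transfers to the field
(same symbiont strain and growth stage help), and (iii) isotopic
fractionation within the plant is captured by using shoot values
throughout — the B value is computed from **shoot** δ¹⁵N only, because it
calibrates field *shoot* samples. Whole-plant δ¹⁵N (organ δ¹⁵N weighted by
organ N content) is computed and reported for glasshouse experiments but
never substituted for B.

N budgets are per-area: shoot N content (mg·plant⁻¹) = dry matter (g) ×
%N × 10; N-fixed (kg·ha⁻¹) = (%Ndfa/100) × shoot N content × plant
density; soil N uptake is defined by difference, so the budget closes
exactly by construction and the pipeline asserts that identity for every
plot. Root and rhizodeposited N are not measured by this design, so all
quantities are shoot-based and conservative.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| atmospheric ¹⁵N/¹⁴N | 0.0036765 | – | standard air ratio; configurable per run |
| within-row spacing | 0.20 | m | the emulated trial's planting geometry |
| between-row spacing | 0.60 | m | idem |
| plants per hole | 2 | – | idem; together → 166 666.7 plants·ha⁻¹ |
| α for tests | 0.05 | – | conventional; Duncan letters are protected by the omnibus F at the same α |
| SSR min repeats | 8 (1-mers), 5 (2-mers), 4 (3-mers), 3 (4–6-mers) | – | 1- and 2-mer thresholds follow the emulated study's reporting scale; longer-motif thresholds follow common scanner practice |

Plant density is derived from geometry rather than hard-coded: back-scaling
the per-hectare N quantities in the emulated study's tables against its
per-plant N contents confirms the 2/(0.20 × 0.60 m²) density was the one
used.

%Ndfa outside [0, 100] (possible when a legume's δ¹⁵N exceeds the
reference mean, e.g. under negligible fixation plus fractionation) is
returned raw with a `NdfaRangeWarning` and flagged in the JSON summary; an
optional clamp mode truncates to the interval but is off by default, since
the raw value is the honest estimate and summaries should reveal, not
hide, such cells.

## Aggregation order

Per-plot (replicate) symbiosis values are computed first and averaged per
treatment cell afterwards; cell SEs are SD/√n over replicates. This is the
order implied whenever published tables carry per-cell SEs, and it is why
recomputing a table cell from the *published marginal means* can deviate
by a few percent: the mean of per-plot DM × %N products is not the product
of the mean DM and mean %N. The reproduction tests therefore pin %Ndfa
(which is linear in δ¹⁵N and immune to this) for every printed cell at
±0.5 percentage points, but pin the budget quantities only where the
printed row is internally consistent under product-of-means (±3%).

## Statistics

The ANOVA is the classical balanced fixed-effects decomposition: a term's
sum of squares is the replication-weighted squared deviation of its
marginal means from the grand mean minus all its sub-term sums of squares;
under balance Type I and Type III coincide and the decomposition is exact,
which the tests assert against an observation-level inclusion–exclusion
oracle and against an independent OLS fit. Unbalanced data raise an
explicit error rather than a silent approximation. An additive block
factor (RCBD) is accepted as an extra model term. With zero residual
variance, F is reported as +∞ with p = 0 rather than raising.

Duncan's multiple range test computes the critical range for a span of p
ordered means from the studentized-range quantile at the protection level
α_p = 1 − (1 − α)^(p−1), numerically (scipy's distribution), not from
embedded tables; a handful of published table values serve as a test
cross-check. Letters come from maximal homogeneous spans: a span is
homogeneous when its range does not exceed its own critical range, and
spans inside a homogeneous span inherit homogeneity, so the compact-letter
display needs exactly the maximal passing spans. Ties in means are broken
by level label for determinism. In the pipeline the test runs only after a
significant omnibus F for that factor (protected use); unprotected calls
are available directly.

## Synthetic data

The generator emulates the 2-site × 5-landrace × 2-inoculation × 4-replicate
structure with independent Gaussian within-cell noise. True cell means are
per-(site, landrace) trait means, shifted by ± half an additive per-site
inoculation effect, so the configured marginals match the landrace-level
and inoculation-level summaries they emulate; two landrace δ¹⁵N means not
recoverable from the emulated study's summaries are set to plausible
mid-range values. Within-cell SDs are sized as twice the published cell
SEs (n = 4). Masses and percentages are truncated at zero, a negligible
distortion at the default means. Correlation between shoot dry matter and
shoot N content arises structurally (content = DM × %N), not from an
explicit covariance. Reference-plant δ¹⁵N values are Gaussian draws per
species around the site mean; the glasshouse B experiment draws organ
δ¹⁵N and N contents around their true values.

What the generator does *not* emulate: spatial field trends, block
effects, season/rainfall structure, measurement-device drift, or any
non-Gaussian error. Tests passing on synthetic data therefore demonstrate
the correctness of the arithmetic, the estimators and their calibration
under the stated noise model — not robustness to real-field artefacts.

SSR test sequences are uniform random backgrounds with exact planted
tandem arrays; the flanking bases are forced to differ from the repeat's
continuation so every planted array is maximal and must be recovered at
exactly its planted count.

## Numerical and design choices

- **Canonical units**: mg N·plant⁻¹ per plant, kg·ha⁻¹ per area; the single
  conversion lives in `mg_per_plant_to_kg_per_ha`.
- **δ notation round-trip**: `ratio_from_delta15n` inverts `delta15n` to
  machine precision; the atmospheric ratio is fixed per analysis run.
- **Degenerate inputs**: reference mean equal to B aborts with an explicit
  division-by-zero diagnosis; zero total organ N makes whole-plant δ¹⁵N
  undefined; zero residual df in ANOVA raises.
- **SSR conventions**: 1-based inclusive coordinates everywhere; motifs
  are reported as found (no rotation canonicalization), so a repeat on the
  reverse strand may surface under a rotated phase shifted by up to one
  unit; overlap between reported runs resolves to the longer run. Gaps and
  N never enter hits. In consensus counting a gap never matches nor forms
  consensus — a gap under a base consensus scores a mismatch — and tied
  columns are excluded; this is the most conservative reading of
  "nucleotide mismatch differences", which could alternatively be defined
  against a designated reference sequence or as summed pairwise distances.
- **Monte-Carlo calibration tests** use fixed seeds; the type-I error of
  the ANOVA under the null is required to sit in [0.035, 0.065] at
  α = 0.05 over 1 000 simulations, and the %Ndfa 2-SE coverage check uses
  the t(3) expectation (≈0.86 for n = 4 replicates) rather than the normal
  0.95, asserting the observed share stays above 0.75 across 200 cells.
- **Problem sizes** in the default test run are the study's own scale
  (80 plots, 9 reference species per site) for pipeline checks, 1 000
  replicates for null-calibration and scanner-oracle sweeps, and 500
  trials for the power property — sizes chosen so the full suite exercises
  every calibration claim while completing in a couple of minutes.

## Known limitations

- Whole-plant δ¹⁵N values published without organ N contents cannot be
  verified; the pipeline reports them as not computable when contents are
  absent.
- The B value transfers glasshouse fractionation to the field unchanged;
  any genotype × environment effect on B propagates directly into %Ndfa.
- Grain moisture is taken as reported (air-dried); no further moisture
  correction is applied to yields.
- The three-way (across-site) ANOVA pools residuals across sites; site ×
  block structure is not modelled beyond an optional additive block term.
- The SSR scanner reports perfect tandem repeats only; interrupted or
  compound microsatellites are reported as their perfect sub-arrays.
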