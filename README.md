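# ndfa

Quantification of symbiotic N₂ fixation in field-grown legumes by the ¹⁵N
natural-abundance method, with the factorial field-trial statistics that
usually accompany such studies and a small SSR (microsatellite) scanner for
the marker work done alongside them.

The package is aimed at plant–microbe symbiosis and agronomy researchers
who have shoot δ¹⁵N, biomass and %N measurements from an inoculation trial
and want a tested, reproducible route from those raw plot measurements to
%Ndfa, N-fixed per hectare, and treatment comparisons.

## The method

Soil N and atmospheric N₂ differ slightly in their ¹⁵N/¹⁴N ratio. A
non-fixing reference plant grown in the same soil carries the soil
signature δ¹⁵N_ref, while a legume fixing all of its N from air would carry
the (slightly fractionated) signature *B*, measured in a glasshouse on
plants grown with N₂ as their sole N source. A field legume sits between
the two, and its shoot δ¹⁵N locates it on that mixing line:

    δ¹⁵N (‰)   = 1000 × (R_sample − R_atm) / R_atm
    %Ndfa      = 100 × (δ¹⁵N_ref − δ¹⁵N_legume) / (δ¹⁵N_ref − B)
    N fixed    = (%Ndfa / 100) × shoot N content × plant density
    soil N     = total shoot N − N fixed

δ¹⁵N_ref is the arithmetic mean over all reference species at a site; *B*
is the mean **shoot** δ¹⁵N of the glasshouse landraces (whole-plant δ¹⁵N,
the N-content-weighted organ mean, is computed for reporting but never
used as *B*). Shoot N content is dry matter × %N; per-hectare scaling uses
the plant density implied by the planting geometry (default 20 cm × 60 cm
with two plants per hole → 166 666.7 plants·ha⁻¹).

The statistics layer implements balanced fixed-effects factorial ANOVA
(two- or three-way, optional additive block term) and Duncan's multiple
range test with compact-letter display, plus Pearson correlation and
simple linear regression. The SSR module finds maximal 1–6 nt tandem
repeats and counts per-sequence mismatches against a majority-rule
alignment consensus. A synthetic-data generator reproduces the whole input
world — factorial trial, reference plants, glasshouse B experiment, SSR
sequences with planted repeat arrays — so every stage is testable without
field data.

## Worked example

Using the packaged summary tables of a two-site Kersting's groundnut
(*Macrotyloma geocarpum*) inoculation trial in northern Ghana:

```python
from ndfa import (TrialDesign, ndfa_percent, n_fixed, plant_density,
                  mg_per_plant_to_kg_per_ha, soil_n_uptake)
from ndfa.pipeline import (bvalue_table, packaged_fixture, read_bvalue_csv,
                           read_references_csv, reference_mean_table)

refs = read_references_csv(packaged_fixture("reference_plants"))
ref_means = reference_mean_table(refs)["mean_delta15n"]
_, b = bvalue_table(read_bvalue_csv(packaged_fixture("bvalue_glasshouse")))

ndfa = ndfa_percent(ref_means["Nyankpala"], 1.03, b)   # Puffeun cell
density = plant_density(TrialDesign())                 # 20 x 60 cm, 2 seeds/hole
fixed = n_fixed(ndfa, 567.09, density)                 # shoot N: 567.09 mg/plant
total = mg_per_plant_to_kg_per_ha(567.09, density)
```

prints, with the `print` statements spelled out:

```
reference mean d15N: Nyankpala 3.95 permil
B value:             -3.835 permil
%Ndfa:               37.51 %
plant density:       166666.7 plants/ha
N fixed:             35.45 kg/ha
soil N uptake:       59.06 kg/ha
```

Reading: the Puffeun landrace at Nyankpala derived 37.5% of its shoot N
from the atmosphere; at this planting density that is ~35 kg N·ha⁻¹ fixed,
with the remaining ~59 kg N·ha⁻¹ taken up from the soil.

The same pipeline runs from the shell:

```
ndfa simulate --seed 4 --out sim/          # synthetic trial CSVs
ndfa run --samples sim/samples.csv --references sim/references.csv \
         --bvalue sim/bvalue.csv --out report/
ndfa ssr-scan sequences.fasta              # SSR hits as TSV
```

`ndfa run` writes per-plot and per-cell symbiosis tables (mean ± SE),
ANOVA tables with Duncan letters, a correlation panel and a deterministic
JSON summary; the N-budget identity (N fixed + soil N = total shoot N) is
checked for every plot and any %Ndfa outside [0, 100] is flagged in both
the log and the summary.

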