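# lnwire

Statistics for single-neuron wiring variability in the fly antennal lobe.

An identified olfactory local interneuron can be labeled once per brain
hemisphere and scored for which of the ~55 antennal-lobe glomeruli its
processes enter. Those binary **innervation profiles** — collected across
hundreds to thousands of hemispheres with sex, mating-status and rearing
metadata — are the raw material for a set of questions this package
answers quantitatively:

- How variable is the wiring? (distinct-pattern counts, per-glomerulus
  innervation frequencies and frequency classes, hierarchical clustering
  of profiles under a correlation distance)
- Is a neuron more similar to its contralateral twin than to the same
  neuron in another animal? (a Jaccard **symmetry index**
  `x/y` = |intersection| / |union| of innervated sets, compared between
  same-brain pairs and randomly re-matched hemispheres from different
  brains)
- Which glomeruli are innervated at different frequencies between sexes
  or mating states? (per-glomerulus chi-square tests with family-wise
  Bonferroni correction over the eligible glomeruli)
- How dense is the arbor inside each glomerulus? (voxel-based
  **neurite density** from a confocal stack and glomerulus masks:
  background-adjust by a never-innervated reference glomerulus (DM5),
  normalize by a densely innervated trio (VA1d, VA1v, DA1), divide by
  voxel count)
- Does wiring correlate with feeding? (**feeding-event detection** from
  capacitive food-interaction traces — a run of ≥5 consecutive 200 ms
  samples at ≥25 AU after baseline subtraction — binned hourly and
  analysed by factorial ANOVA with optional HC3 heteroscedasticity
  correction)

Every stage has a matching generator in `lnwire.synthetic` that emits
data with carried ground truth (Bernoulli cohorts, concordant hemisphere
pairs, ellipsoidal glomerulus phantoms, rectangular feeding bouts), so
the whole pipeline is testable end to end without any raw imaging or
behavioral data.

## Worked example

```python
from lnwire import synthetic as synth, dimorphism as dim, symmetry as sym
import numpy as np

# A sexed cohort with a planted VL2a frequency difference
coll, truth = synth.gen_profiles(synth.CohortSpec(seed=11, groups=[
    synth.GroupSpec(n=2268, sex="female", overrides={"VL2a": 0.349}),
    synth.GroupSpec(n=496, sex="male", overrides={"VL2a": 0.093})]))
report = dim.dimorphism_screen(coll, group_col="sex")
row = report.set_index("glomerulus").loc["VL2a"]
print(f"VL2a: female {row.freq_female:.1%}, male {row.freq_male:.1%}, "
      f"adjusted p = {row.adjusted_p:.2e} (m = {int(row.m_tests)} tests)")

# Bilateral symmetry vs the random-pairing null
paired, _ = synth.gen_paired_cohort(synth.CohortSpec(
    n_profiles=200, n_left_only=90, pair_concordance=0.9, seed=12))
intra = [p.index for p in sym.enumerate_intra_pairs(paired)]
rand = sym.random_pairing(paired, "r_based", seed=13).indices
rep = sym.compare_symmetry_groups({"intra": intra, "r_based": list(rand)})
print(f"median symmetry index: intra {np.median(intra):.3f}, "
      f"random {np.median(rand):.3f}; Kruskal-Wallis p = {rep.kruskal_p:.2e}")
```

prints

```
VL2a: female 33.4%, male 7.3%, adjusted p = 2.76e-30 (m = 12 tests)
median symmetry index: intra 1.000, random 0.750; Kruskal-Wallis p = 5.78e-65
```

The screen recovers the planted sexual dimorphism of VL2a (observed
frequencies are within binomial error of the generating 34.9% / 9.3%;
the adjusted p-value is Bonferroni-corrected over the 12 glomeruli whose
pooled frequency is strictly between 0 and 1 in this cohort). Hemisphere
pairs generated with 0.9 concordance are far more symmetric than pairs
re-matched across brains — intraindividual variability below
interindividual variability.

A `lnwire` command-line tool wraps the same functions
(`lnwire simulate …`, `lnwire profiles stats/cluster`, `lnwire symmetry`,
`lnwire dimorphism`, `lnwire density`, `lnwire flic detect/anova`); run
`lnwire --help` for the full surface.

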