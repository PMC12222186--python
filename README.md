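# saltmeta

Cross-setting dose–response meta-analysis of wheat salt-stress studies.

Field trials, outdoor pots, greenhouse pots and climate-chamber pots report
very different responses of bread wheat to the same salinity stress.
`saltmeta` implements the full analysis pipeline needed to compare these
experimental settings across a heterogeneous study corpus, plus the
factorial analysis used for a companion multi-setting experiment.  It is
aimed at meta-analysts and agronomists who have (or simulate) study-level
observation tables — one row per (study, experiment, setting, variable,
salinity level) with control and stress means.

## The method

1. **Unit normalization.** Every salinity measurement is converted to
   electrical conductivity: 1 M NaCl ≡ 98 dS/m, 1000 ppm NaCl ≡ 1.66 dS/m
   (linear in both factors).  The stress intensity of an observation is the
   *relative EC*, EC_stress − EC_control, which sets every study's control
   baseline to zero.
2. **Effect size.** The response is the *relative value*
   r = x̄_stress / x̄_control (1 = no effect, < 1 = decrease).  Growth
   variables measured at the vegetative stage use the *stress integral*
   (relative EC × stress duration, dS·day/m) as their stress axis instead
   of relative EC.  Genotype/year replicate rows are averaged unweighted,
   and only salinity levels where shoot dry weight or grain yield actually
   decreased are analyzed.
3. **Adaptive binning.** Per variable, the stress axis is partitioned so
   that every covered setting keeps ≥ 5 points in every bin and the
   per-setting mean stress within each bin is as comparable as possible;
   explicit user-supplied edges override the search.
4. **Robust filtering.** Within each bin × setting cell, a single-pass
   Hampel filter excludes points beyond k = 3 (scaled) median absolute
   deviations of the cell median.
5. **Gated pairwise tests.** For each pair of settings, retained values are
   pooled across their overlapping bins.  If both samples pass Shapiro–Wilk
   normality (raw or log scale) and Brown–Forsythe variance homogeneity, a
   two-sided **permutation t-test** (pooled-variance t over label
   relabelings, exhaustive when feasible) is run on that scale; otherwise a
   **Mann–Whitney U** test (exact for small tie-free samples).
6. **Factorial arm.** A stress × setting two-way ANOVA (type-II SS) whose
   residual-normality gate falls back to the **Scheirer–Ray–Hare** rank
   test, H_effect = SS_effect(ranks) / [SS_total(ranks)/(N−1)] against
   chi-square.

A synthetic-corpus generator (`saltmeta.simulate`) produces study corpora
with setting-specific sigmoidal dose–response curves
r(x) = 1/(1 + (x/c50)^shape), multiplicative noise, outlier contamination
and greenhouse-heavy study counts, so the whole pipeline is testable and
calibratable without external data.

## Worked example

```python
from saltmeta import RunConfig, analyze_records, default_config, generate_corpus
from saltmeta.compare import comparisons_table

records = generate_corpus(default_config(seed=1))   # 1076 records
result = analyze_records(records, RunConfig(seed=1))
va = result.variables["grain_yield"]
print(comparisons_table(va.comparisons)[
    ["setting_a", "setting_b", "n_a", "n_b", "test", "p_value"]
])
```

prints (abridged):

```
      setting_a    setting_b  n_a  n_b          test  p_value
climate_chamber        field   43   97  mann_whitney  0.00000
climate_chamber   greenhouse   43  287  mann_whitney  0.20224
          field   greenhouse   97  287  mann_whitney  0.00000
          field outdoor_pots   97   63 permutation_t  0.00010
     greenhouse outdoor_pots  287   63  mann_whitney  0.00000
```

The tiny field-vs-greenhouse p-value recovers the generating truth: the
field response curve (c50 = 30 dS/m) is much flatter than the greenhouse
one (c50 = 12 dS/m) — field crops are the least affected by the same added
salinity.  Each `examples/*.py` script demonstrates one capability
(unit conversion and effect sizes, Hampel filtering, the two-sample tests,
the end-to-end pipeline, the factorial analysis) and prints what the
numbers mean.

A thin CLI wraps the same functions:

```sh
saltmeta simulate --out corpus.csv --seed 1
saltmeta analyze corpus.csv --out-dir out --seed 1
saltmeta factorial experiment.csv --out-dir out
```

Every command writes a JSON manifest (inputs, parameters, seed, filtering
decisions) from which the run can be reproduced exactly.

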