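# Methods

This note documents the statistical procedure `saltmeta` implements, the
choices made where the design was genuinely open, and what the synthetic
corpus generator does and does not emulate.

## Data model and normalization

An observation is a study-level pair of means — a variable measured under a
low-salinity control and under a saline treatment — with the salinity of
both treatments, the experimental setting (field, outdoor pots, greenhouse,
climate chamber), the developmental stage for growth variables, and
optional stress duration.  Salinity units are converted linearly to
electrical conductivity: 98 dS/m per mol/L NaCl and 1.66 dS/m per 1000 ppm
NaCl.  The single-point factors are extrapolated linearly across the whole
range, which is standard for NaCl at field-relevant concentrations.

Validation is strict at ingestion: control means must be positive (ratios
must exist), stress EC must exceed control EC (the analysis is of *added*
salinity), and unknown setting/variable/stage labels are rejected.  Rejected
rows are returned in a report — never silently dropped — so
`len(records) + len(rejections)` always equals the number of input rows.
Metabolite concentrations (Na⁺, proline, chlorophyll) reported per fresh
weight are ingested but flagged excluded from analysis: salt stress changes
tissue water content, which confounds per-fresh-weight concentrations.

Three derived quantities drive the analysis:

* **relative EC** = EC_stress − EC_control (dS/m), zeroing every study's
  control baseline;
* **stress integral** = relative EC × duration (dS·day/m), the stress axis
  for vegetative-stage growth variables, where exposure time matters as
  much as intensity; duration runs from stress onset to measurement unless
  an explicit value is given (salt is assumed to persist once applied);
* **relative response** = stress mean / control mean, dimensionless.

Replicate rows (genotypes, repeated years) are averaged with an unweighted
arithmetic mean; rows within a group must agree on the salinity unit.
Finally the *effective-stress gate* keeps a (study, experiment, salinity
level) group only if shoot dry weight **or** grain yield decreased
(ratio < 1).  The gate runs after aggregation, at the row granularity that
is actually analyzed.  Groups carrying neither anchor variable are kept
with a warning by default (configurable to drop), since a curated corpus
guarantees at least one anchor by collection design.

## Binning and outlier filtering

To compare settings along the dose–response curve, each variable's stress
axis is partitioned into bins.  A usable scheme must retain at least
`min_count = 5` points per covered setting in every bin; a *good* scheme
also makes bins comparable — within a bin, the per-setting mean stress
should be similar, otherwise a between-setting contrast partly reflects a
different dose mix.  The search enumerates quantile-seeded and equal-width
edge sequences for 1–6 bins, greedily merges adjacent bins until the count
constraint holds, and ranks feasible candidates by (1) most bins — the
finest feasible dose resolution — then (2) smallest worst-bin spread of
per-setting mean axis values, then (3) lexicographically smaller edges.
The search is fully deterministic.  Settings that cannot reach `min_count`
even in a single all-spanning bin are dropped from coverage with a warning;
fewer than two coverable settings is an error.  Because published analyses
of this kind chose bins by hand, explicit user edges always override the
search.

Bins are half-open `[e_i, e_{i+1})` with the last bin closed — the standard
histogram convention; a value on an interior edge belongs to the upper bin.
A degenerate corpus whose axis values are all identical yields the
single-value scheme `[v, v]`.

Within each bin × setting cell, a **single-pass Hampel filter** excludes
points with |v − median| > k·s·MAD, where the median and MAD are computed
once on the full cell (not iterated), k = 3, and s is the MAD scale.  The
default s = 1.4826 follows the Hampel-filter convention in which the scaled
MAD estimates a Gaussian σ, so the rule reads "beyond 3 robust standard
deviations"; s = 1.0 gives the literal "3 median absolute deviations"
reading and is exposed as a configuration switch, with reports recording
which was used.  When MAD = 0 (at least half the cell identical) nothing is
excluded — the literal rule would otherwise discard every non-median point.

## Pairwise setting comparisons

For each unordered pair of settings sharing at least one bin with retained
data, values are pooled across those overlapping bins and a two-sample test
is chosen by a gate at α = 0.05 (configurable):

1. Shapiro–Wilk per group on the raw values; if both pass, the candidate
   scale is raw.  Otherwise, if all values are positive, Shapiro–Wilk on
   the logs; if both pass, the candidate scale is log.
2. With a normal candidate scale, variance homogeneity is tested on that
   scale.  A pass selects the permutation t-test on that scale; any failure
   (including no normal scale) selects Mann–Whitney U on the raw data.

The homogeneity test is Brown–Forsythe (median-centred Levene) by default —
robust to the non-normality that is common here.  Shapiro–Wilk is applied
per group, both groups must pass.  Groups smaller than 3 skip the gate and
go straight to Mann–Whitney.

**Permutation t-test.**  The statistic is the pooled-variance Student t
(the permutation null assumes exchangeability, i.e. equal variances — which
the gate has just checked).  When C(n_a+n_b, n_a) ≤ 20 000 the null is
enumerated exhaustively and p is the exact fraction of label assignments
with |t*| ≥ |t_obs|; otherwise B = 9999 (configurable) random relabelings
are drawn and p = (1 + #{|t*| ≥ |t_obs|})/(1 + B), so a sampled p is never
zero.  Given a seed the result is exactly reproducible; each comparison's
seed is derived from the run seed and the comparison identity by stable
hashing, so any single comparison can be re-run in isolation.

**Mann–Whitney U.**  U = #{(i,j): a_i > b_j} + ½·ties, computed from
mid-ranks.  For tie-free samples with at most 20 000 rank splits the
two-sided p is exact: the fraction of splits whose U deviates from
n_a·n_b/2 at least as much as observed.  Otherwise a normal approximation
with mid-rank tie correction and 0.5 continuity correction is used.

No multiplicity correction is applied by default, matching how such
pairwise panels are usually reported; a Holm adjustment is available as a
flag.

## Factorial analysis of the experimental arm

The companion experiment is a stress (control/salt) × setting factorial.
The primary analysis is a two-way ANOVA with interaction using type-II sums
of squares — the design can lose plants and become mildly unbalanced, and
type-II reduces to the classical decomposition on balanced data.  The
Shapiro–Wilk p-value of the residuals is recorded; `gated_factorial`
discards the ANOVA when that p ≤ 0.05 and returns the **Scheirer–Ray–Hare**
rank test instead: all values are replaced by mid-ranks, sums of squares
are taken from the same two-factor model on ranks, and each effect's
H = SS_effect / [SS_total/(N−1)] is referred to chi-square on the effect's
df.  Computing the total mean square from the observed mid-ranks applies
the standard tie correction implicitly.  Degenerate inputs (constant
response, all values tied) are reported as such rather than producing
spurious statistics.

## The synthetic corpus generator

The generator emulates the statistical structure the meta-analysis assumes,
not wheat physiology.  Per setting it draws a configured number of studies;
each study has a control EC ~ U(0, 2) dS/m, one to three stress levels with
relative EC ~ U(4, 30) dS/m, a stress duration ~ U(14, 60) days, and a
per-study lognormal baseline per variable.  The true mean response follows
the modified discount curve r(x) = 1/(1 + (x/c50)^shape) — the standard
sigmoidal salt-tolerance form with r(0) = 1 and r(c50) = ½.  Any strictly
decreasing r(0)=1 family would serve; the form is configuration-visible so
tests do not overfit to it.  Observed stress values are
control × r(axis) × exp(σZ) with σ = 0.2 by default (≈20% multiplicative
noise, typical of between-study scatter in response ratios), and with
probability 0.05 a value is multiplied or divided by 4 to create the gross
outliers the Hampel filter targets.  For vegetative-stage growth variables
the curve lives on the integral axis, with the effective c50 scaled by the
mean duration.  Every fifth study reports salinity in mM rather than dS/m
to exercise unit conversion.  All randomness flows from one seed through
per-stage derived streams; identical configs are byte-identical.

Default conditions: c50 = 30 (field), 20 (outdoor pots), 12 (greenhouse),
14 (climate chamber) dS/m with shape 2 — field crops least affected,
greenhouse most, the ordering reported for this literature; study counts
58/38/148/25, which at ~2 levels per study reproduce a corpus composition
of ≈117/77/296/49 stress observations per variable, the documented
greenhouse-heavy imbalance of the real corpus.  `null_config()` gives all
four settings identical parameters for calibration experiments.

What the generator does *not* emulate: within-study replicate data,
study-level random effects on the response ratio (noise is independent per
row, so ratios carry no between-study correlation), correlations between
variables of one study, measurement-method heterogeneity, and any soil or
plant dynamics.  Passing calibration on these corpora therefore shows the
pipeline is internally consistent under its own assumptions — not that
real corpora, which violate some of them, would calibrate equally well.

A scale note: at much smaller corpus sizes only one or two very wide bins
are feasible; cells then mix widely different doses, the Hampel filter
clips genuine dose structure group-specifically, and the pairwise type-I
error drifts upward (≈0.07 at one-eighth scale versus ≈0.05 at the default
scale).  Outlier-filter-then-test procedures are mildly anti-conservative
whenever the filter removes real structure; keeping bins narrow (feasible
at realistic corpus sizes) is what contains the effect.

## Numerical choices and limitations

* Exact-test tail comparisons use a 1e-12 relative tolerance on |t*| ≥
  |t_obs| so enumeration is not sensitive to float rounding of tied
  statistics.
* Zero-variance permutations: when a relabeling makes both groups constant
  with different means, the t statistic is treated as ±∞ and counted as
  extreme; all-values-equal inputs return p = 1.
* The Mann–Whitney normal approximation clamps p away from exact zero.
* Monte-Carlo experiment sizes (500 null corpora for calibration, 200 for
  recovery, B = 499 permutation resamples within those loops) were chosen
  so each experiment's Monte-Carlo standard error (~0.004 on a rate) is
  well below the decision margins while a full run stays in the
  few-minutes range.
* Stage labels are inputs; no growth-stage inference from dates.  No
  meta-regression, no precision weighting, no dose–response curve fitting
  to the binned means — the pipeline compares unweighted study-level
  ratios, as the underlying procedure does.
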