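# Methods

`peony` re-implements, as a tested pipeline, the demographic-inference and
population-genetics workflow behind a three-species tree peony system
(*Paeonia jishanensis* = PJ, *P. qiui* = PQ, *P. rockii* = PR): coalescent
ABC over divergence scenarios on nuclear microsatellites, nSSR and
chloroplast-haplotype statistics, neutrality and mismatch demography, and a
background-vs-observed climate niche-divergence test.  This note documents
the models, the numerical choices, and what the synthetic data generator
does and does not emulate.

## Demographic model and coalescent simulation

The demography is a three-population tree: backwards in time, one species
pair merges at `t1` and the remaining pair at `t2 >= t1` (times in
generations, continuous; one generation = 10 years for calendar
conversion).  Current diploid effective sizes are `NJ`, `NQ`, `NR`; the
lineage ancestral to the first merge has size `A2` on `[t1, t2)` and the
final ancestor `A1` above `t2`.  Pairwise coalescence rate is `1/(2N)`
(diploid msprime convention).

**Scenario table.** Only the best-supported history ("PQ split from PJ at
t1, PR split from PJ at t2") and its two deep-split variants are described
explicitly in the source study; the full six-scenario set is *reconstructed*
as the three labeled pair-first topologies of {PJ, PQ, PR}, each in two
variants: the merged-pair lineage is the ancestor at `t2`, or the outgroup
is.  In the outgroup-ancestor variant the outgroup carries the ancestral
size `A1` from its first event (`t1`) onward; this is the one reading under
which the two step-2 scenarios differ in distribution at all (exactly when
`A1 != NR`), and it is what the simulator implements.  Users should treat
scenario ids 3-6 (step 1) as a documented convention, not a published
specification.

**Microsatellite mutation.** Ancestry comes from msprime (one independent
genealogy per locus, `num_replicates`); the mutation overlay is
implemented in-package so the reference-table loop works on integer allele
arrays.  Mutations are Poisson on branches at per-locus rate `mu`; under the
strict stepwise model (SMM) each mutation moves the repeat count +-1 with
equal probability, and under the optional generalized model (GSM) by a
+-Geometric(1 - 0.22) step.  The net displacement per branch is drawn in
closed form (difference of up/down step counts) and lineage path sums are
reflected into +-40 repeats around the ancestral state by image folding.
Folding at the lineage level reproduces the reflected walk's marginal
endpoint distribution exactly; it ignores the small correlation effect that
boundary hits induce between relatives, which is negligible at the
parameter ranges used here (the boundary is 40 repeats, walks rarely exceed
+-20).  The overlay is validated two ways: mean expected heterozygosity over
loci matches the Ohta-Kimura SMM equilibrium `He = 1 - 1/sqrt(1 + 8 N mu)`
within Monte-Carlo error, and it agrees with `msprime.SMM` on the same
demography.

**Priors.** `mu ~ U(1e-4, 1e-3)` as in the study.  Size and time priors are
not printed there; the package defaults are log-uniform `N, t ~ LogU(10, 1e5)`
(diploid sizes, generations) with `t1 < t2` by rejection, and
`scale_kind="uniform"` switches to flat priors on the same bounds.
Log-uniform is the standard non-informative shape for positive scale
parameters spanning four decades, and it matters in practice: a flat prior
on `[10, 1e5]` puts ~90% of its mass at `N > 1e4`, where simulated
heterozygosities sit near 0.9, so a reference table of desk-scale size
contains essentially no rows in the regime of the published estimates
(sizes and times all between 1e2 and 1e4) and every rejection neighborhood
around realistic data is an extrapolation.  Under the log-uniform default
the published-median regime is well covered by the reference table.

**Truth parameters for recovery suites.**  The published posterior medians
(`NJ=1690, NQ=4910, NR=5090, t1=2430, t2=5030, mu=1.74e-4`) are used as
generating values.  The median table omits `A1`/`A2`; the companion text
reports `A2 = 9.52e3` and `A1` slightly below `NR`, so the suites use
`A2 = 9520` and `A1 = 5000`.  Note the text's current-size figures disagree
with the median table; the table is treated as canonical wherever both give
a value.

## ABC (DIYABC-style)

Twelve summary statistics in a fixed order: per species the mean number of
alleles per locus and mean Nei unbiased gene diversity; per species pair the
multi-allelic Weir-Cockerham theta and Goldstein's `(delta mu)^2` (squared
difference of mean allele size, averaged over loci).  The same theta
estimator is used here as in the population statistics module, for internal
consistency.

* **Rejection:** statistics are normalized by their median absolute
  deviation over the reference table (SD fallback for degenerate columns) —
  MAD keeps the heavy-tailed `(delta mu)^2` columns from washing out the
  distance; the closest `tolerance` fraction (default 1%) by Euclidean
  distance is retained.
* **Scenario choice:** multinomial logistic regression of the scenario
  indicator on the retained statistics centered at the observation
  (statsmodels MNLogit, Newton), evaluated at the observation; 95% CIs from
  500 parametric draws on the coefficient vector using the asymptotic
  covariance.  On separation or non-convergence the estimator falls back to
  direct rejection frequencies with a binomial CI — with ~100 retained rows
  and 12 covariates this fallback is common and intentional.
* **Parameter estimation:** Beaumont local-linear adjustment with
  Epanechnikov weights; parameters are logit-transformed to their prior
  bounds (on the log axis for the scale parameters under the log-uniform
  prior) before the weighted regression and back-transformed after; the
  weighted solve carries a small ridge penalty (1e-3 times the mean
  diagonal of X'WX, intercept unpenalized) because the retained set is
  small relative to the twelve statistics; reported quantiles (median,
  2.5%, 97.5%) are weight-aware.
* **Confidence:** type I error is the fraction of prior-drawn pods from the
  chosen scenario not assigned to it (highest posterior probability rule);
  type II the fraction of pods from the other scenarios assigned to it.
* **Model checking:** posterior-predictive two-sided tail probabilities per
  statistic from datasets simulated at posterior draws.

A caveat the user should understand: at the published medians the two
step-2 scenarios are nearly observationally equivalent (`A1 ~ NR`), so the
scenario posterior at desk scale reflects which scenario's prior predictive
sits closer to the observation — a stable property of the scenario priors,
mirroring the weak separation (posterior probability ~0.61, type I ~0.3)
the study itself reports.

## Population statistics

* `H_E` is Nei's unbiased gene diversity `(2n/(2n-1))(1 - sum p^2)` per
  locus, averaged over loci; `H_O` the fraction of heterozygotes.
* Allelic richness uses hypergeometric rarefaction to `g` gene copies;
  `g="auto"` takes the smallest per-locus, per-population sample so every
  locus supports the rarefaction.  The published table's rarefaction size is
  not stated, so those values are not a target; the report records the `g`
  used.
* F_ST is Weir & Cockerham's theta (1984), summed over alleles and loci as
  a ratio of variance components; pairwise estimates are reported as
  computed (possibly negative) and clamped to zero only for Slatkin
  linearization `F_ST/(1 - F_ST)`.
* AMOVA follows Excoffier's sums of squares over squared inter-unit
  distances with the standard unequal-size coefficients.  For nSSR the unit
  is the gene copy and the distance is allele identity per locus (F_ST-like,
  matching the study's choice of F-statistics over R-statistics); for cpDNA
  the unit is the individual and the distance the haplotype pairwise
  difference count.  Negative components are clamped to zero post hoc and
  percentages renormalized.  Permutation p-values (default 10,000): units
  among populations (phi_ST), units among populations within species
  (phi_SC), whole populations among species (phi_CT), all with the +1
  correction.
* Isolation by distance: Mantel correlation between `F_ST/(1-F_ST)` and
  great-circle distance (haversine, R = 6371.0088 km), one-tailed
  permutation p with 999 permutations by default.  The Mantel test is
  implemented in-package because the scikit-bio version exposes no seed.
* The shared-allele distance is `1 - (multiset genotype intersection)/2`
  averaged over co-typed loci; the NJ tree uses scikit-bio's neighbor
  joining.
* Genotype PCA works on per-allele dosages (0/1/2), mean-imputed at missing
  calls, column-centered, via SVD.
* Directional relative migration follows the divMigrate logic: for an
  ordered pair, a hypothetical pool with the average allele frequencies of
  the two groups; the differentiation (two-deme Nei G_ST, or Jost's D)
  between the *receiving* group and the pool is converted to
  `Nm = 0.25 (1/d - 1)` and the matrix scaled to maximum 1.

## cpDNA statistics

Indel recoding: every maximal run of gap-containing alignment columns
becomes one binary character (A = absent, T = present), so a multi-base
indel counts once; which state denotes the gap does not affect any
statistic.  Ambiguity codes are treated as missing in difference counts.
Haplotype ids are assigned in order of first appearance.

G_ST and N_ST use the Pons & Petit estimators (frequency-only
vs distance-weighted, harmonic-mean sample-size correction); with all
haplotypes equidistant the two are identical by construction.  The
permutation null shuffles haplotype identities in the distance matrix,
keeping G_ST fixed; p is one-tailed for `N_ST > G_ST`.  Species-level
diversity pools individuals across populations — pooling, not averaging,
reproduces the published species values (0.473 / 0.634).  One published
per-population value (SBL, 0.677) is inconsistent with its own printed
counts (which give 0.667) and is treated as a typo.

The haplotype network is a minimum-spanning network: every edge that occurs
in some minimum spanning tree (weight equal to the minimax path weight
between its endpoints), a deliberate simplification of median-joining that
adds no inferred median vectors.

## Neutrality and mismatch demography

Tajima's D uses the canonical 1989 constants; `S = 0` is flagged undefined.
Fu's Fs computes `S' = P(K >= k_obs)` from the Ewens sampling formula with
unsigned Stirling numbers of the first kind evaluated in log space
(stable to n of several hundred).  Simulated p-values for both are
`P(stat_sim <= stat_obs)` under a constant-size neutral coalescent at
`theta = theta_pi`, so small p flags expansion-like signal — matching the
convention under which the study's large positive values carry p near 1.

The mismatch distribution is fit with the sudden-expansion curve
`F_i = F(i; theta1) + e^-tau sum_j tau^j/j! [F(i-j; theta0) - F(i-j; theta1)]`
by least squares on relative frequencies over the observed difference range
(bounded Nelder-Mead, 10 seeded random restarts; the curve is clamped
non-negative — the approximation dips fractionally below zero in the far
tail).  SSD and Harpending's raggedness (including the terminal step to
zero) get parametric-bootstrap p-values: replicates are simulated under the
fitted expansion with a haploid coalescent (per-sequence mutation rate 1/2,
so `N = theta` and `T = tau` in simulator units), each replicate refit with
two restarts; 1000 replicates by default.

## Niche divergence

The correlation filter drops, while any |r| >= 0.8 remains, the variable
with the largest mean absolute correlation (deterministic order tie-break).
PCA is z-scored over occurrences and background jointly, per species pair.
On each retained axis: `d_n = |mean score A - mean score B|` over
occurrences; the `d_b` null resamples background points with replacement at
the occurrence sample sizes (1000 resamples by default) and reports the
0-95% envelope.  Divergence requires both `d_n` above the 95% bound and a
species-label permutation p <= 0.05 for `d_n` itself; conservatism is
flagged when `d_n` falls below the background median.  Correlations of PC
scores with latitude/longitude/altitude are Pearson r, flagged at p < 0.001.

## Synthetic data: what it emulates, what it does not

The generator produces (i) microsatellite datasets under the scenario tree
(plus island-pair and stepping-stone helpers for migration and IBD tests),
(ii) cpDNA alignments realizing an exact per-population haplotype count map
on a random genealogy — every haplotype carries at least one private
substitution, one single indel lineage optional — and (iii) climate tables
where species occurrences are multivariate normal with centroids shifted
along a fixed direction (SD 1) inside a shared, wider background
climate distribution (SD 2, common mean); geographic background points are
uniform over each species' occurrence bounding box inflated by 25%.
Zero shift is therefore an exact null for the divergence test, and a 3-SD
shift a strong alternative.

Not emulated: genotyping artifacts (null alleles, allele dropout, missing
data patterns), within-species population structure beyond what the
scenario tree implies, selection or linkage on any locus, spatially
explicit landscapes, indel evolution beyond a single presence/absence
character, and any climate-geography coupling (background climate is drawn
independently of coordinates).  Passing tests therefore demonstrate
correctness of the estimators and calibration of the tests under these
idealized conditions, not robustness to real-data artifacts.

## Problem sizes in the test suite

The shipped suite runs everything at desk scale, chosen as the package's
own operating envelope: the ABC recovery suite uses 5,000 reference rows
per step-2 scenario, 22 loci and the study's full species sample sizes
(255/118/214 diploids) with 20 pods; calibration suites use 200 null
replicates (Mantel at 99 permutations on 6 demes; NST/GST at 99
permutations on 8 haplotypes x 5 demes) and 50 zero-shift niche replicates
at 200 resamples.  Larger runs only sharpen the same comparisons.

## Known limitations

* Step-1 scenarios 3-6 are a reconstruction (see above); only their
  topology-level behavior is tested.
* The logistic-regression CI is asymptotic and the rejection fallback
  binomial; neither accounts for reference-table Monte-Carlo error.
* The mismatch bootstrap refits with fewer restarts than the primary fit,
  trading a slightly conservative p for speed.
* Relative-migration values are relative by construction; only ratios and
  orderings are interpretable, not absolute migration rates.
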