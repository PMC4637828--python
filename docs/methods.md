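# Methods

This note documents the statistical machinery, default parameters, and the
design choices made where the design was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

A *DNA profile* is one individual: sex (F/M/unknown), an mtDNA control-region
haplotype label referencing an aligned `HaplotypeSet` (equal-length A/C/G/T/N
sequences, ~500 bp), and a diploid multi-locus microsatellite genotype.
Alleles are integer fragment sizes; a genotype is an unordered pair, stored
sorted, and a locus is either fully typed or absent — half-typed loci are a
parse error, not data.  Missing-data codes in sample tables are configurable
(`""`, `"NA"`, `"0"` by default; `"0"` is the conventional microsatellite
missing code) and normalise to a single canonical missing state.  The locus
set of a collection is the union over individuals; per-stratum analyses use
whatever loci are typed there.

Individuals stratify by sampling **location**, **habitat** (calving ground vs
migratory corridor) and **management unit** (locations pooled, e.g.
VIC+TAS+NSW+QLD → SEA, SA+WA → SWA).  A `StratificationScheme` maps every
location to its habitat and management unit; partitions are checked to be
disjoint and exhaustive.

## Genotype QC

* **Per-allele error rate** is the error count over the repeat-amplification
  control count, reported as proportion and percent.
* **P_ID** uses the standard unrelated-individuals formula per locus,
  `Σp_i⁴ + Σ_{i<j}(2p_ip_j)²`, multiplied across loci.  The sib-adjusted
  variant is not implemented.
* **Duplicate detection** flags pairs typed together at ≥ `min_shared_loci`
  (default 8) with ≤ `max_mismatch` (default 1) disagreeing loci, reporting
  the P_ID of the matched profile from the sample's own allele frequencies.
  Flagged pairs are reported, never auto-merged; `dedupe` then keeps one copy
  per duplicate cluster *within each stratum* (default scope: location — the
  same genotype sampled in two locations is retained twice, deliberately),
  preferring the most-typed profile, ties broken by sample id.  Dedupe is
  idempotent.
* **HWE exact test**: gene copies at a locus are pooled and randomly
  re-paired, which samples genotype tables exactly from the conditional null
  given the allele counts; the p-value is the add-one-smoothed fraction of
  tables with conditional probability ≤ the observed table's
  (`P(table) ∝ 2^H/Π n_ij!`).  Default 100,000 re-pairings with an explicit
  seed; the suite cross-checks full enumeration on ≤ 8 gene copies and the χ²
  approximation in the large-sample tail.  Monomorphic loci return p = 1 with
  a warning.

## Differentiation statistics

* **Diversity**: unbiased haplotype diversity `h = n(1−Σp̂²)/(n−1)`; π is the
  mean pairwise sequence difference over all pairs of sampled sequences,
  per site when the alignment length is supplied.  Unbiased expected
  heterozygosity uses the 2n/(2n−1) small-sample factor.
* **AMOVA** decomposes squared pairwise distances between individuals'
  haplotypes.  Supplied pairwise difference counts are treated directly as
  squared distances (the Arlequin convention).  With the identity distance
  (0 same, 1 different) the resulting Φ_ST *equals* the conventional
  frequency-based F_ST, which the suite asserts exactly; with sequence
  distances it is Φ_ST.  The distance model for Φ_ST is raw pairwise
  difference counts — the simplest model consistent with haplotype distances;
  no substitution-model correction is applied.  A three-level decomposition
  (groups of strata) is available.  Multi-locus or multi-system estimates
  combine by summing variance components.
* **Weir–Cockerham F_ST** (1984 θ̂): per-locus variance components a, b, c
  summed over alleles, multi-locus estimate `Σa/Σ(a+b+c)`; missing genotypes
  drop out per locus.  Verified against an independent ANOVA-sums-of-squares
  route to 1e-12.
* **Jost's D**: per-locus `D = (r/(r−1))(H_T−H_S)/(1−H_S)` from Nei–Chesser
  unbiased heterozygosities with harmonic-mean sample size; the multi-locus
  value is the arithmetic mean over loci (the GENODIVE dialect).  Negative
  estimates from the unbiased machinery are reported as computed, never
  truncated — this matters for near-zero comparisons.
* **Permutation p-values** shuffle individuals (not haplotype labels) among
  strata and use add-one smoothing, `p = (#{perm ≥ obs}+1)/(n_perm+1)`.
  Default 10,000 permutations.
* **Exact test of differentiation**: Metropolis Markov chain over
  allele/haplotype × population tables with fixed margins (±1 checkerboard
  moves), p = chain fraction of tables no more probable than the observed
  one, with a batch-means standard error.  Desk-scale defaults are 100,000
  steps / 10,000 dememorization; survey-scale values (10⁶/10⁶) are reachable
  by argument.  Agrees with Fisher's exact test on 2×2 tables within
  Monte-Carlo error.

## Correspondence analysis

Genotypes are encoded as 0/1/2 allele-copy counts (the Genetix convention);
missing loci contribute zero counts rather than imputed row mass — a
documented limitation, acceptable at the ≤ 17-locus, low-missingness scale
this targets.  The CA is the χ²-metric SVD of the centred row-profile matrix;
axis inertias sum to χ²/N (asserted in the suite), and each axis's sign is
fixed by making its largest-|coordinate| entry positive so plots reproduce.

## Isotope–matriline association

A **matriline** is operationalised as (haplotype × management unit): a common
haplotype spanning two management units almost certainly contains multiple
maternal lineages, and the management unit is the finest defensible split.

* Kruskal–Wallis uses average ranks with tie correction and the χ²
  approximation.
* Model ranking fits Gaussian linear models by least squares for every subset
  of {haplotype, sex, state} plus every subset of two-way interactions among
  the included mains (18 candidates with three factors), computes full
  Gaussian-ML AIC (AICc switchable), and reports Akaike weights and each
  factor's summed weight.  "State" is the sampling location's state.  Aliased
  designs are dropped with a warning.  AIC differences are verified against
  statsmodels OLS in the suite.
* The **matriline randomization test** compares the observed
  between-/within-group mean-square F-ratio with its distribution under
  random relabelling; its p-value is the *plain proportion* of randomized F
  at least as extreme — deliberately different from the add-one rule of the
  permutation engine, because that is how this test is conventionally
  defined.  Zero within-group variance gives F = ∞, and ∞ counts as an
  extreme tie.
* **Relatedness**: Ritland (1996), per locus
  `r̂ = 2/(k−1)(Σ_i f_xi f_yi/p_i − 1)` with k−1 locus weights, and
  Lynch & Ritland (1999), the reference/proband form with its own locus
  weights, averaged over the two orderings.  Reference allele frequencies
  default to the full analysed sample including each pair (the COANCESTRY
  convention).  Pedigree simulations recover mean r̂ of 0 / 0.25 / 0.5 for
  unrelated / half-sib / parent–offspring pairs within simulation error.
* **Mantel tests** correlate off-diagonal entries and permute one matrix's
  rows and columns simultaneously (10,000 permutations by default, add-one
  smoothing).  Relatedness is converted to a dissimilarity as `max(r̂) − r̂`
  — a monotone decreasing transform chosen for simplicity; it is a
  configuration point, not a claim about the uniquely correct transform.  The
  one-sided alternative is "higher relatedness ↔ smaller isotopic distance".
  δ15N analyses run identically but are secondary (the generator deliberately
  gives δ15N no matriline structure, and the tests confirm no association is
  detected).

## θ → historical abundance

θ is interpreted on the per-site scale with μ per site per year — the only
reading that brings the supplied θ values and effective sizes to the same
order of magnitude.  Per draw: G ~ U(18.1, 28.8) yr, μ_gen = μ·G,
N_e(f) = θ/(2μ_gen), N_T(f) = 2·N_e(f), c ~ U(2.5, 4.71) independent of θ and
G, N_C = c·N_T(f).  Means and percentile 95% CLs are reported over 2,000
draws (the CL construction is a percentile interval; the draw-wise identities
N_T = 2N_e and 2.5 ≤ N_C/N_T ≤ 4.71 hold exactly).

When a sampler's posterior θ vector is available it is resampled directly;
otherwise draws come from a **log-normal stand-in** with median = point
estimate and σ fitted by least squares to the log HPD bounds.  For strongly
log-asymmetric HPD intervals the median and both bounds cannot all be matched
— the fit keeps the median exact and splits the interval misfit; the stand-in
is a documented dialect, not a reconstruction of the unavailable posterior,
and it makes the implied mean substantially exceed the median (visible in the
README example).

**Monte-Carlo design.**  By default the uniform factors are sampled in
antithetic pairs: each (θ, G) base draw is used twice, with c and its
reflection 2.5+4.71−c.  All marginal distributions are unchanged, but the
c-dependence of the mean N_C cancels exactly within pairs, so the reported
means satisfy mean(N_C) = 7.21·mean(N_e(f)) (twice the mean maturity factor)
without residual noise from the heavy-tailed θ draws.  Plain iid sampling is
available via `antithetic=False` and is used in the suite to verify the same
identity within 3 Monte-Carlo standard errors.

## Synthetic data: what it emulates, and what it does not

The generator's defaults describe a two-management-unit survey: 2 regions ×
40 whales, 17 loci with 8 alleles each, target F_ST 0.05, 6 haplotypes of
500 bp at ~5 expected pairwise differences, δ13C base −21.5 ‰ with
between-matriline spread 1.2 ‰ over within-matriline noise 0.5 ‰, and
δ15N ~ N(9.0, 0.7) common to everyone.  The isotope variances are *choices on
the ‰ scale typical of baleen-whale skin*, documented here precisely because
no field estimate of within-matriline δ13C variance was available to copy;
passing tests demonstrate estimator correctness under the assumed structure,
not the effect size in real whales.

Microsatellite and haplotype frequencies per region follow a Balding–Nichols
construction (Dirichlet around ancestral frequencies with concentration
(1−F)/F), chosen because the differentiation parameter then *is* the expected
F_ST, making estimator-recovery tests quantitative.  Genotypes assume HWE
within regions; sexes are 50/50; haplotype sequences accumulate Poisson
substitutions on a common ancestral sequence (no substitution-model realism
beyond the expected pairwise difference).  Pedigree pairs are produced by
Mendelian transmission from HWE founders.  QC artifacts: duplicates are exact
re-sampled copies (optionally with loci dropped); allele errors hit calls
independently at the configured rate and move one ladder step.

Not emulated: linkage between loci, null alleles and allelic dropout
structure, age/reproductive-state effects on isotopes, isotopic covariance
between δ13C and δ15N, within-region population substructure, and temporal
variation across a 20-year sampling window.

## Numerical and scale choices

Every stochastic routine requires an explicit seed and is reproducible
byte-for-byte.  Desk-scale defaults (10⁴ permutations/randomizations, 10⁵
MCMC/HWE steps, 2×10³ abundance draws) keep a full synthetic pipeline run
under a few minutes on one CPU; the suite uses smaller resampling counts and
simulation sizes (e.g. 100-locus, 50-per-deme island models; 500-replicate
calibration loops; 200 pedigree pairs per class) chosen as the smallest
designs whose simulation error is comfortably inside the asserted tolerances.
Ties in resampling comparisons are counted as extreme (≥ with a 1e-12
absolute guard).  Degenerate inputs are defined rather than accidental:
monomorphic loci give p = 1 (HWE) or D = 0 (Jost) or NaN (all-monomorphic
F_ST, flagged); empty strata and half-typed loci are errors; constant Mantel
matrices raise.

## Known limitations

* The exact-test Markov chain reports a batch-means SE but no convergence
  diagnostic; very sparse tables may need more dememorization than the
  default.
* P_ID is the unrelated-individuals variant only.
* The log-normal θ stand-in understates fit quality for asymmetric HPDs (see
  above); supplying the posterior vector is always preferred.
* CA treats missing genotypes as zero mass, which slightly shrinks
  high-missingness individuals toward the origin.
* The three-level AMOVA follows the standard unbalanced-design coefficients;
  variance components can be negative in small samples and are reported as
  computed.
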