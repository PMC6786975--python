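# Methods

This note documents the models behind each genokit stage, the defaults
that matter, what the synthetic-data generator does and does not emulate,
and the numerical and design choices a maintainer would want explained.
Nothing here states an empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohorts (`genokit.simdata`)

The generator exists so that every pipeline stage can be exercised, with
known truth, at desk scale.

**Panel model.** Reference haplotypes are *founder mosaics*: per site,
allele frequencies are drawn from Beta(0.8, 0.8) (U-shaped, so both rare
and common markers occur); founder haplotypes are Bernoulli draws at
those frequencies; each panel haplotype copies a uniformly chosen founder
and switches founders at each site with probability
`mosaic_switch_rate` (default 0.01).  This induces linkage
disequilibrium with a tunable correlation length — sufficient to exercise
copying-model imputation — but it is *not* a population-genetic
simulator: there is no coalescent genealogy, no recombination map
heterogeneity, no mutation-age structure.  Cohort haplotypes are drawn
from the panel by the same mosaic process, so cohort allele frequencies
converge to panel frequencies (a tested invariant).

**Genotype errors and artifacts.** Calls are the sum of the two true
haplotypes with symmetric errors at rate `genotype_error_rate` (default
0.1%).  Batch artifacts operate on *calls* (e.g. "flip a fraction of
heterozygotes to hom-ref in batch B at markers M"), not on probe
intensities — intensity-level genotype calling is outside the package's
scope.  Artifact defaults in the tests (flip fraction 0.5, batches of
~1,600 samples, common markers) are chosen for test power: the marginal
distribution of real batch artifacts is not something the package claims
to model.

**Pedigrees.** Gene-dropping on explicit small pedigrees (duplicate,
parent–offspring, full-sib, half-sib, grandparent, avuncular,
first-cousin, unrelated), with per-site independent transmissions.
Ignoring within-gamete linkage leaves all single-locus expectations
(kinship, IBS0, heterozygosity) correct, which is all the relatedness
stage consumes; it would be wrong for IBD-segment methods, which the
package does not implement.

**Intensity clusters.** One isotropic Gaussian (sd 0.07) per karyotype in
the (mean L2R X, mean L2R Y) plane.  Centres follow copy number: one X
copy at −0.55, two at 0.0, three at +0.4 on the X axis; zero Y copies at
−1.4, one at 0.0, two at +0.55 on the Y axis.  Real intensity data show
mosaicism, batch shifts and heavier tails; passing the ≥99% recovery test
therefore shows the caller is correct under well-separated clusters, not
that it would resolve mosaic aneuploidy.

**Phenotypes.** Additive polygenic trait: `n_causal` markers with
Gaussian effects rescaled so the genetic share of (genetic + noise)
variance equals `h2`; optional fixed effects of sex, age, array and
supplied PC scores on top.

## Marker QC (`genokit.markerqc`)

Per marker and batch: 2×2 allele-count homogeneity tests of one stratum
against the pooled remainder for batch, plate, array and inferred sex,
plus the exact conditional Hardy–Weinberg test.  Fisher's exact test is
used when any expected cell count is below 5, chi-square (no continuity
correction) otherwise — standard practice; the crossover does not affect
the extreme-threshold regime.  The HWE p-value sums Levene–Haldane
probabilities over heterozygote counts no more probable than observed,
evaluated by the stable ratio recurrence with one final normalization
(checked to 1e-12 against log-gamma enumeration).

Default fail threshold: p < 1e-12 per test per batch.  At hundreds of
thousands of markers times ~100 batches, an extreme threshold is the only
way to bound the volume of genuinely fine calls set to missing; the value
is configurable.  Cross-batch exclusion: a marker failing any test in
more than 50% of batches, or failing the array comparison (which has no
batch locality), is dropped entirely.  Both rules are package defaults —
published pipelines of this kind state the structure ("set the failing
batch to missing; exclude markers unreliable across batches") but not
portable numeric thresholds.  Tests may be restricted to an
ancestry-homogeneous sample subset (from `pca.select_homogeneous_subset`)
to attenuate structure-driven false positives; one caveat of the
stratum-vs-rest design is that a very strong artifact in one batch leaks
into the pooled remainder of the other batches' comparisons, which is
another reason the default threshold is extreme.

## Sample QC (`genokit.sampleqc`)

Missing rate and heterozygosity over a supplied marker subset;
heterozygosity is regressed (OLS, intercept) on the first 6 PCs and the
residual used for outlier detection, making the metric insensitive to
ancestry gradients (residuals are exactly orthogonal to the fitted PCs).
Outlier rule: missing rate > 5% (an explicit, conventional cut) OR
residual heterozygosity above median + 5×MAD (sigma-consistent MAD).  The
heterozygosity rule is one-sided high because contamination inflates
heterozygosity; a low-side rule would mostly catch consanguinity, which
is biology, not artifact.  Flags annotate samples; nothing is removed.

Karyotype calling is nearest-centre assignment against the fixed
simulator centres with an unclassified margin of 0.35 (about half the
smallest inter-centre distance): deterministic, order-invariant and
testable, at the cost of not adapting to shifted real-data clusters.

## PCA (`genokit.pca`)

Standardization `(g − 2p)/sqrt(2p(1−p))` with `p` the fitting-set
frequency (clipped away from 0/1); missing calls mean-imputed, i.e. zero
after centering.  Randomized range-finder: Gaussian test matrix with 10
oversampling columns, 10 power iterations with QR re-orthonormalization,
then an exact SVD of the small projected matrix.  Ten power iterations is
deliberately conservative — at desk scale the cost is negligible and the
result matches a dense eigensolver to 1e-6 on test problems.  Component
signs are fixed by making each component's largest-magnitude loading
positive.  Fitted scores are defined as the projection of the fitting
samples through the loadings, so projection of the fitting set reproduces
them exactly.

LD pruning is greedy within sliding windows (default 50 markers, step
25): remove the lower-MAF member of the worst pair above the r²
threshold, ties to the higher position.  Subset selection: robust
ellipsoid (per-PC median ± k·MAD semi-axes, default k = 7 on PCs 1–6)
within a self-report label, or distance ≤ 5 robust SDs from a labelled
reference cluster.  These radii are package defaults; the analogous
published rules are not printed with portable numbers.

## Relatedness (`genokit.relatedness`, `genokit.clique`)

The KING-robust within-family estimator (see README formula) with IBS0 =
opposite-homozygote fraction.  Counts are accumulated blockwise with
indicator-matrix products for all-pairs mode, or per pair in linear time
when a pair list is given; results are block-size-independent by
construction and by test.  Pairs whose smaller heterozygote count is zero
are skipped (the estimator divides by it).  Samples with > 5% missingness
on the kinship marker subset are excluded from estimation.  Markers for
kinship should be only weakly ancestry-informative;
`select_kinship_markers` drops the top 1% by absolute leading-PC loading.
Only pairs with φ̂ ≥ 2^−4.5 (the lower edge of the third-degree band) are
reported by default.

Classification: degree d when φ̂ ∈ (2^−(d+3/2), 2^−(d+1/2)]; duplicates
above 2^−1.5; parent–offspring vs full-sib split at IBS0 = 0.0012 (a few
opposite-homozygote calls per ten thousand markers tolerate genotype
error while excluding true siblings, whose expected IBS0 is larger by
orders of magnitude).

**Second-degree cliques.** For a network in which all k members are
pairwise second-degree, the three admissible relationship types pin the
generation gap (half-sib 0, avuncular 1, grandparent 2), so members
occupy at most three consecutive generations, and all same-generation
pairs must be half-siblings sharing exactly one parent.  The search in
`genokit.clique` enumerates generation compositions (exploiting the full
symmetry of the clique), all within-generation parent-sharing structures
(pairwise-intersecting distinct parent pairs — stars and the parent
triangle, enumerated by backtracking, not assumed), and all role
assignments of latent parents (full-sibling-of-uncle vs
child-of-grandparent, which are mutually exclusive because an uncle's
full sibling has the uncle's all-latent parents).  Realizability
constraints: acyclic generations, at most two parents each, implied
parent links, and no first-degree pair inside the clique.  The reported
quantity is the minimum over realizable configurations of the largest
number of clique pairs sharing one single parent, with a witnessing
configuration.  The search is exact at any clique size; the historical
`max_exact` parameter is kept for interface stability.

`expected_sibling_pairs` uses E[pairs] = S_pop · n(n−1)/(N(N−1)) with
S_pop = N·Σ_s q_s(s−1)/2: each individual in a size-s sibship accounts
for (s−1)/2 pairs, and uniform sampling without replacement retains each
pair with probability n(n−1)/(N(N−1)).

Trio detection requires two parent–offspring edges to an opposite-sex
pair, a 12-year default parent–child age margin, and parents not
first-degree related; quartets are parent pairs with two full-sibling
children.

## Imputation (`genokit.imputation`)

Haploid Li–Stephens HMM per pre-phased target haplotype; phasing itself
is out of scope (targets come phased from the simulator or external
tools).  Transition between adjacent typed sites: stay with probability
`exp(−r)`, else jump uniformly, `r = 4·Ne·c/N_hap` with `c` the genetic
distance in Morgans.  Defaults: Ne = 20,000 and a constant 1 cM/Mb map
when none is supplied (IMPUTE-family conventions); miscopy probability
λ = θ/(2(N_hap+θ)), θ = 1/Σ_{i<N} 1/i.  All defaults configurable.

The two performance devices are contracts, not approximations:

* emissions multiply the state vector by one scalar plus an O(carriers)
  sparse correction through the per-site minor-allele carrier index;
* copying marginals are computed at typed sites only and linearly
  interpolated at untyped sites (on the marginals, not on final dosages),
  the imputed allele probability being the interpolated carrier mass.

Both are verified to 1e-10 against a dense forward–backward oracle on
randomized instances.  Per-site renormalization guards underflow and
cancels in the posteriors.  Chunked execution (markers per chunk with a
250 kb physical buffer, sample blocks) reproduces unchunked interior
posteriors once the buffer spans enough expected recombinations for
dependence through the boundary to decay below tolerance; the tests set
Ne so the default buffer spans ~50 expected recombinations.  Typed sites
pass through with posterior mass ≥ 1 − 2λ on the observed genotype when
the target has a firm copying anchor (exact panel copies); near mosaic
switch points the anchor weakens and the mass can dip a few percent —
the test states the contract in the exact-copy regime.

Diploid posteriors are products of the two haploid allele distributions;
the info score is `1 − Σ(f_i − e_i²)/(2Mθ̂(1−θ̂))`, clipped to [0, 1],
with α = 1 at monomorphic θ̂.  X-chromosome handling: samples with called
sex aneuploidy are excluded; XY samples are haploid outside the PAR
(posterior collapses to hom-ref/hom-alt) and diploid inside it.
Site matching between target and panel is exact on position + allele
pair; mismatches are reported and dropped, never strand-flipped.

## BGEN v1.2 (`genokit.bgen_io`)

Supported profile: layout 2, biallelic, haploid/diploid, unphased or
phased, B ∈ [1, 32] bits (default 8), zlib or no compression — the
practical profile of released biobank imputed data.  zstd is declined at
decode with an explicit unsupported-feature error.  Quantization:
round-down to `p·(2^B−1)` then largest-remainder distribution of the
deficit (ties to the earlier genotype), so stored integers sum exactly to
2^B−1 per sample (per haplotype when phased) and round-trip error is at
most 1/(2^B−1) elementwise.  The last probability of each sample is
implied and omitted; values are packed little-endian in one continuous
bitstream.  Missing samples set the ploidy-byte missing bit and write
zero probabilities.

The companion index is a sorted plain TSV (chrom, pos, id, rsid, byte
offset, block size) rather than the community SQLite convention: no
database dependency, bit-exactly testable, rebuilt by a full scan when
absent.  Region queries are 1-based inclusive on position and decode only
the indexed blocks.  A golden-bytes test hand-encodes a minimal file from
the published layout description and compares byte-for-byte.

## Association and fine-mapping (`genokit.assoc_finemap`)

The scan residualizes phenotype and dosages against the covariates
(intercept always included; rank-deficient covariate matrices are
reduced with a warning) and runs per-marker simple regression on the
residuals — numerically identical to full-design OLS by Frisch–Waugh
(tested to 1e-8) — with residual degrees of freedom n − c − 2 and normal
p-values (adequate at the sample sizes the scan targets; an exact-t
variant would only matter at very small n).  The linear model is a
deliberate stand-in for mixed-model association: relatedness must be
handled by analyzing an unrelated subset
(`relatedness.unrelated_subset`), not by the scan itself.

Wakefield ABFs use prior W = 0.2² on standardized effects, with optional
rescaling of β and SE by the residual phenotype SD (computed after
covariate projection) to put studies on a common scale.  Credible sets
assume exactly one causal marker per region: posteriors BF_i/ΣBF, sorted
descending with position tie-breaks, shortest prefix reaching 0.95.
Regions: greedy ±500 kb around the most significant remaining hit with
overlap merging (radius configurable — the published region lists of this
kind do not print their exact parameters); window counting tiles 1 Mb
from position 1.  HLA risk models build the documented design columns and
fit logistic IRLS (statsmodels) with Wald tests; detected separation
(non-convergence or runaway estimates) falls back to a flagged
L2-penalized IRLS with unpenalized intercept.

## Problem sizes used in the checks

The package's own verification runs at deliberately small scale: panels
up to 1,000 haplotypes × 2,000 sites (imputation recovery), 50 haplotypes
× 200 sites × 200 instances (sparse/dense agreement), 1,400 pedigree
pairs at 50,000 markers (kinship classification), 10,000-variant BGEN
files, cohorts of 5,000–10,000 for sample QC, and 10,000-marker null
scans.  Passing at these sizes demonstrates correctness of the
algorithms, not performance or robustness at the hundreds-of-thousands-
of-samples scale the methods were designed for, and demonstrates behaviour
under the generator's assumptions (no intensity-level artifacts, no
coalescent LD, no mosaic aneuploidy) rather than on real array data.

## Known limitations

* No probe-intensity modelling anywhere: genotype calling, cluster-plot
  inspection and mosaic-aneuploidy fractions are out of scope.
* No phasing algorithm; trio-based truth phasing and switch-error
  evaluation only.
* No IBD-segment detection; kinship is single-locus.
* The linear scan is not a mixed model; no FDR machinery beyond the fixed
  genome-wide threshold.
* BGEN support is the stated subset (no layout 1, no multi-allelics, no
  zstd).
* The clique search's relationship vocabulary is half-sib /
  grandparent / avuncular; double first cousins (also kinship 1/8) are
  outside its assignment alphabet.
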