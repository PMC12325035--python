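# Methods

## The synthetic study and what it emulates

The generator produces the statistical situation the audit machinery is
built for: an admixed cohort of many small populations genotyped on two
platforms — whole-genome-sequencing-like (all simulated variants) and a
SNP-array-like subset ascertained in a European discovery panel.

**Ancestral frequencies.** Each variant's ancestral frequency `p0` is drawn
from Beta(0.2, 0.2) truncated to [0.001, 0.999] (inverse-CDF truncation).
This U-shaped spectrum supplies the rare-variant excess that the
ascertainment experiment needs, without coalescent machinery. Three ancestry
components (NAT, EUR, AFR) drift from `p0` under Balding–Nichols
`p_k ~ Beta(p0(1−F_k)/F_k, (1−p0)(1−F_k)/F_k)` with defaults
F = 0.20 / 0.12 / 0.08: the Native American component is modelled as the
most drifted of the three sources, and the magnitudes are in the range of
continental-scale FST. Variants are laid across the 22 autosomes in
proportion to approximate chromosome lengths, with transitions at
probability 2.1/3.1 so a clean call set shows the genome-wide high-quality
Ts/Tv of ~2.1.

**Populations and genotypes.** A population is (n, q, F, region, altitude
band). Its per-ancestry frequencies drift once more under Balding–Nichols
with the population's own F (default 0.005–0.08; higher for isolated native
populations), then each individual's two allele copies independently draw an
ancestry from `q` and an allele Bernoulli(p). Realized per-sample ancestry
fractions over all 2m copies are stored as truth. The per-copy (haploid)
draw is the simplest model in which admixture proportions act as
allele-frequency mixtures.

The default layout has 26 populations with sizes on a 10..80 grid (8:1
largest:smallest, total 1,170): 16 native populations (NAT ancestry
0.80–0.95, mostly Amazonian/Andean) and 10 admixed ones (NAT 0.60–0.74, EUR
up to ~0.31, AFR up to ~0.09, Andean/coastal). Sample metadata uses a 1:2
female:male ratio and a 2/45/37/16% BMI-class mix, matching the cohort
design this layout emulates. The library default is m = 50,000 variants.

**Array ascertainment.** The discovery sample is `discovery_n = 120`
haplotypes drawn Bernoulli from the discovery ancestry's panel frequency
(EUR by default); variants polymorphic in that sample with discovery MAF ≥
0.05 form the array panel. Commercial arrays rarely document their
discovery design, so these two values are free parameters: they
reproduce the *direction* of ascertainment bias (rare depletion, common
enrichment) but are deliberately not calibrated to any particular published
capture rate.

**Artifact injection.** Exactly `round(err_rate · m)` biallelic SNVs
(default err_rate 0.0059) are flagged and their substitution class redrawn
with transition probability `R_err/(1+R_err)` (default R_err = 0.4), keeping
the ref base; genotypes are set missing i.i.d. at `miss_rate` (default
0.002). Exact-count flagging rather than i.i.d. Bernoulli flagging makes the
injected fraction the estimand rather than a random quantity. Error
injection is site-level (substitution class), not genotype-level, because
the Ts/Tv error model it feeds is a site-level argument.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium (sites are independent),
recombination and phased haplotypes, indels/SVs, genotype-error modes that
preserve the site's class, batch effects, and relatedness structure beyond
what random drift induces. Real cohorts would also violate the
cross-platform frequency-comparability assumption (the two platforms here
share the same simulated individuals unless configured otherwise).

## QC

HWE uses the exact conditional (Levene–Haldane) test: the p-value sums the
probabilities of all heterozygote counts, given the allele counts, that are
no more probable than the observed one. The implementation builds the
distribution outward from its mode by ratio recurrence (numerically stable);
tests compare it to an exact-integer enumeration oracle at 1e-12.
Monomorphic sites return p = 1 (no deviation is expressible) — by the same
convention, they pass. No mid-p correction is applied.

Relatedness uses the classic method-of-moments on IBS sharing: observed
IBS0/1/2 counts per pair are equated to their expectations under IBD state
probabilities computed from cohort-estimated allele frequencies, and
pi-hat = P(IBD=2) + P(IBD=1)/2. PLINK's finite-sample correction factors are
omitted — the bias is O(1/n) and irrelevant at the tolerances used. For
large cohorts the estimator subsamples to 20,000 MAF-filtered variants with
a deterministic stride. Pruning removes, per flagged pair (pi-hat > 0.185 by
default; the threshold sits between second- and third-degree expected
values), the member with the lower call rate, ties broken toward keeping the
lexicographically smaller ID; the procedure is idempotent.

Summary percentages round half away from zero (0 decimals for audit
percentages, 1 for categorical tables).

## Ascertainment metrics

Variants match across platforms by `(chrom, pos, sorted uppercased
alleles)`; IDs are ignored because rsID vocabularies differ across
platforms, and orientation is ignored by sorting alleles. Spectrum fractions
are computed over each platform's own polymorphic variant list — the only
reading under which per-bin percentage-point differences are well defined —
with monomorphic sites excluded and counted. Default bin edges
{0, 0.005, 0.01, 0.05, 0.10, 0.5}: the outer cutpoints are the rare/common
definitions, interior edges are conventional MAF thresholds.

## The Ts/Tv mixture error bound

The call set is modelled as a mixture of true variants at ratio
R_exp (default 2.1, the midpoint of the 2.0–2.2 high-quality band) and
artifacts at R_err (default 0.4, the ratio of a near-uniform substitution
process). Two estimators are shipped:

- **ratio-linear** (default): `e = (R_exp − R_obs)/(R_exp − R_err)`. This
  interpolates linearly on the ratio scale.
- **proportion-mixture**: solves `p_obs = (1−e)·p_exp + e·p_err` with
  `p = R/(1+R)`. Because a site mixture is linear in transition
  *proportions*, this is the statistically consistent inversion.

The two disagree by a predictable factor: near R_obs ≈ R_exp,
`e_linear / e_true ≈ (p_exp − p_err) / ((1−p_obs)² (R_exp − R_err)) ≈ 2.2`
at the defaults. The recovery experiment (10⁶ sites, injected fractions
0.001–0.02) confirms the proportion-mixture recovers the injected fraction
within a few percent while ratio-linear overestimates ~2.2-fold — i.e. it is
strictly conservative. Ratio-linear remains the default because the
toolkit's reporting convention is an *upper bound* ("no more than e% of
calls are artifacts"), for which conservatism is the desired property. Both
bounds are clipped to [0, 1] and reported as percentages at 2 significant
figures.

## Weighted PCA and bootstrap stability

Weights are `w_i = 1/n_{g(i)}` normalized to sum 1 (or uniform). The
weighted allele frequency `p̂_j = Σ w_i g_ij / 2Σ w_i` (over non-missing
calls) centers (2p̂) and scales (√(2p̂(1−p̂))) the genotypes, with missing
calls mean-imputed at 2p̂; the decomposition is of X^T W X. Weights enter
both the frequency estimate and the covariance — otherwise large groups
would still dominate the centering and defeat the correction. Monomorphic
(zero-variance) columns are dropped and reported. Components are computed by
SVD of diag(√w)·X — exact LAPACK below 2·10⁶ matrix cells, seeded randomized
SVD (7 power iterations) above — and each component's sign is fixed so its
largest-magnitude loading is positive. Sample scores are the projections
X·V; under the weight metric they are orthogonal with squared norms equal to
the eigenvalues, and with k full the eigenvalues sum to the total weighted
variance.

The stratified bootstrap resamples individuals with replacement within each
population (B = 100 by default), re-runs the weighted PCA, and aligns each
replicate to the full-data solution by Procrustes with translation,
rotation/reflection *and scaling* — eigenvalue scale varies between
resamples and only shape stability is claimed. Reported: mean Procrustes
RMSD, per-sample SD of aligned coordinates across replicates, and per
population the fraction of replicates in which its nearest-centroid
neighbour is unchanged ("cluster consistency" — the nearest-centroid
operationalization is this package's choice). Size-1 populations resample
as themselves and are flagged.

**Known limitation.** Cluster consistency is sensitive to centroid noise in
very small groups: with populations spaced closely along an admixture
gradient, the n≈10 groups' centroids move enough under resampling to flip
nearest neighbours, and inverse-size weighting cannot repair this — it
corrects covariance domination, not centroid estimation variance. In
measured comparisons an 8:1-imbalanced layout showed consistency 0.2–0.4
below a size-balanced cohort of the same total n. Consistency values for
populations below ~30 samples should be read as descriptive, not as
evidence of robustness; well-separated populations reach consistency 1.0
regardless of imbalance.

## Hudson FST and polygenic scores

Per variant, with sample allele frequencies p₁, p₂ and allele counts n₁, n₂:
numerator `(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)`, denominator
`p₁(1−p₂) + p₂(1−p₁)`. The mean is the ratio of summed numerators to summed
denominators (ratio-of-averages — the standard recommendation for combining
per-site estimates); sites monomorphic in both populations are excluded and
counted, negative per-site values are retained. On two populations drifted
F from a common ancestor the estimator recovers F (tested within 15% at
n=100, m=10⁴).

The unweighted GRS counts risk alleles over a supplied variant list (risk
allele must match ref or alt; mismatches are errors, absent variants are
reported). Missing genotypes contribute the sample's population expected
dosage, 2× the population risk-allele frequency. Per-population means are
compared with a Kruskal–Wallis rank test.

## Pipeline and problem sizes

Stage seeds derive deterministically from the global seed and the stage name
(blake2s, < 2³¹), so a configuration is a complete description of a run;
outputs are written atomically and contain no timestamps, making report
bundles byte-identical across runs. The bundled demo configuration uses
m = 8,000 variants, 26 populations (total n = 1,170) and B = 30 bootstrap
replicates — sizes chosen so the full pipeline, including the pairwise
26×26 FST matrix and kinship over ~680k pairs, completes in minutes on a
single CPU while exercising every stage at full cohort width. The library
defaults (m = 50,000, B = 100) are the intended analysis scale.

## Numerical conventions

- Dosage matrix int8 with −1 for missing; dosages outside {0,1,2,missing}
  are schema errors at construction.
- Transitions are {A↔G, C↔T}; other single-base changes are transversions;
  multi-base or symbolic alleles are "other" and excluded from Ts/Tv (but
  counted). Multiallelic records decompose per alt for Ts/Tv and count once
  for the multiallelic rate.
- MAF is computed on non-missing genotypes and is invariant to ref/alt
  orientation; all-missing sites have undefined metrics and fail QC.
- Percent rounding is half away from zero; two-significant-figure rounding
  likewise.
- HWE p-value tie comparison uses a 1+1e−12 relative guard on the observed
  probability.
- The degenerate Procrustes case (zero-variance replicate) aligns to the
  reference centroid and reports the reference's dispersion as RMSD.
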