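# Methods

This package re-implements, as one tested pipeline, the inference chain
used in seascape-genetic studies of continuously distributed marine
mammals: diversity and differentiation estimators for microsatellite
and mtDNA data, sample-size standardisation by rarefaction,
bathymetry-constrained marine distances, isolation-by-distance (IBD)
regressions contrasting maternally and biparentally inherited markers,
directional migration networks, ordination, and a trapezoidal
environmental-envelope habitat model.  Every stage runs on synthetic
data from a forward-time simulator, so all claims below are testable
without any external download.

## Estimators

**Heterozygosity and F-statistics.** Expected heterozygosity uses the
small-sample estimator He = (2n/(2n−1))(1 − Σp²), averaged over loci.
F_IS and F_ST follow Weir & Cockerham (1984): per locus and allele the
among-group (a), among-individual (b) and within-individual (c)
variance components are computed from group sizes, allele frequencies
and heterozygote frequencies; multilocus estimates are ratios of
summed components (θ = Σa/Σ(a+b+c); F_IS = 1 − Σc/Σ(b+c)).  Negative
estimates are reported as-is; they are truncated to zero only inside
the IBD transform F/(1−F).

**Permutation tests.** The MCMC "exact" tests of the classical tools
are replaced by direct permutation tests of the same nulls, all seeded:
HWE shuffles gene copies among individuals within locus (statistic
|F_IS|), pairwise differentiation reallocates individuals between the
two groups (statistic θ or Φ_ST), linkage permutes one locus's
genotypes among individuals (statistics: G on the two-locus genotype
table; the standardised index of association RbarD).  p-values are
(k+1)/(B+1) and never zero.  For the HWE statistic the permutation
distribution carries substantial tie mass at realistic sample sizes
(the statistic is a function of small heterozygote counts), which makes
the conventional "count ties as exceedances" rule visibly conservative;
the HWE test therefore reports the Lancaster mid-p (ties half-weighted),
which restores uniform type-I behaviour.  All other permutation
statistics are effectively continuous and use the conservative rule.

**Rarefaction.** Allelic richness Ar and private allelic richness pAr
are the combinatorial expectations in a standardised subsample of g
gene copies (default 18): Ar = Σ_alleles [1 − C(N−N_i, g)/C(N, g)], and
pAr multiplies each allele's presence probability in the focal group by
its joint absence probability in every other retained group.  Groups
with fewer than g typed copies at any locus are dropped and flagged.
The individual-level rarefaction re-computes any registered statistic
on 1000 random draws of a fixed number of individuals (14 for
microsatellite statistics, 5 for mtDNA); the reported SE is the SD
across replicates (it describes subsampling spread; a flag switches to
SD/√reps).  Replicates on which a statistic is undefined are dropped
and counted, not redrawn, to avoid biasing toward polymorphic
subsamples.

**Sequence statistics.** Site-frequency statistics (S, η, singletons,
π, θ_W, Tajima's D, Fu & Li's D*) use complete deletion (columns with
any N/gap dropped, count reported); distances use pairwise deletion.
D* uses total mutations η and singleton mutations (variant alleles seen
once, capped at alleles−1 per site) with the corrected variance
constants.  Nominal cutoffs for D come from the scaled-beta
approximation with mean 0 and variance 1 on the attainable range; this
test is known to be mildly conservative (empirical rejection 2–4% at
the nominal 5% level, confirmed here against coalescent simulations),
which the calibration test acknowledges by accepting rejection rates in
[0.5%, 9%].

**Distances.** JC69 is −(3/4)ln(1−4p/3); TN93 uses empirical base
frequencies with separate purine/pyrimidine transition classes and was
checked against the R `ape` implementation to 1e-6.  Saturated pairs
(log argument ≤ 0) are flagged infinite.  A transition class with zero
stationary mass contributes nothing (its term vanishes in the limit).

**Φ_ST (AMOVA).** Model distances are treated as squared Euclidean
distances in the sums of squares (the convention of the standard
sequence-AMOVA tools); Φ_ST = σ²_a/(σ²_a+σ²_w) with negative components
reported as computed.

**Snn.** Hudson's nearest-neighbour statistic splits ties fractionally:
each sequence contributes the fraction of its equally-nearest
neighbours that share its group.

**Median-joining network.** ε = 0; candidate median (Steiner) vectors
are majority consensi of triplets connected in the minimum spanning
network and are accepted when they shorten the spanning structure;
medians of final degree ≤ 2 are pruned.  The construction guarantees a
connected network and recovers chains without medians and stars with
one central median on the worked examples.

**Wang (2002) relatedness.** Implemented as the method-of-moments
estimator on the three dyad-similarity categories (identical; hom–het
sharing; het–het sharing one allele).  The category probabilities under
0, 1 or 2 pairs of genes IBD are exact polynomials in the reference
allele-frequency moments a2, a3, a4; the three moment equations are
solved for (φ, δ) by weighted least squares with locus weights
1/(2a2−a3), and r = φ/2 + δ.  Reference frequencies come from the
pooled sample.  Pedigree simulations recover r ≈ 0.5 for
parent–offspring and r ≈ 0 for unrelated dyads within Monte-Carlo
error; identical multilocus genotypes give r ≈ 1.

**LD-Ne.** Burrows' composite disequilibrium over all locus pairs after
filtering alleles below p_crit = 0.02 (one allele per locus dropped as
the redundant complement; near-perfect associations r² > 0.98 excluded
as duplicated loci).  The drift component subtracts the Waples (2006)
sampling expectation (1/S + 3.19/S² for S ≥ 30; the small-S
coefficients below), and Ne inverts the corresponding quadratic.
Non-positive drift r² reports infinity (no detectable drift LD).  The
CI is a delete-one jackknife over locus pairs on drift r², mapped
through the Ne inversion.  On isolated Wright–Fisher populations with
true Ne = 100 and S = 50, the CI covers the truth in ≈90% of
replicates.

**Marine distances.** Bathymetry cells inside the habitable depth
window (−650 m to −10 m by default) form a graph with 8-neighbour
connectivity; edge weights are true great-circle distances between cell
centres (not √2 × cell size, limiting distortion at high latitude), and
the ±180° seam is joined when the grid spans the full circle.  Sample
coordinates snap to the nearest habitable cell within 50 km (ties to
the deeper cell); shortest paths are Dijkstra.  Disconnected pairs are
infinite and excluded (with a count) from regressions.

**IBD.** Ordinary least squares of F/(1−F) (or Φ_ST/(1−Φ_ST)) on marine
distance in km, with the one-tailed Mantel permutation p (default 10⁶
permutations in the study configuration; smaller counts in the drivers).
Relatedness-versus-distance uses the same machinery without the
transform and tests the lower tail (nearby groups are expected to be
more related).

**Directional migration.** For each ordered pair a hypothetical migrant
pool averages the two demes' allele frequencies; Nei's G_ST of the
receiving deme against the pool, transformed by the Wright island
relation m ∝ ((1/G)−1)/4, gives the relative migration into that deme,
normalised by the global maximum.  Bootstraps resample individuals
(diploid genotypes) within demes; an ordered pair is significantly
asymmetric when the two directed 95% percentile CIs do not overlap.
Both pre- and post-normalisation values are exported.  The percolation
threshold is computed on the undirected graph with edge weight = mean
of the two directions; it equals the bottleneck of the
maximum-bottleneck spanning tree, hence is invariant under monotone
transforms of the weights.

**Ordination.** Genotypes are coded as centred allele-dosage columns
(0/1/2).  PCA mean-imputes missing calls; DAPC and sPCA use complete
cases (mirroring the conventions of the standard R implementations).
DAPC reduces to n_pca axes then applies LDA with equal priors; the
alpha-score (observed minus permuted self-assignment) guides n_pca.
sPCA decomposes (1/2n)Xᵀ(L+Lᵀ)X with L the row-normalised Delaunay
(or Gabriel/kNN) connection network; the global/local permutation
statistic is the sum of positive (resp. |negative|) eigenvalues under
row shuffles — a spectral-sum simplification of the original
multi-statistic test, validated by its type-I behaviour and by power on
clinal fixtures.  nMDS minimises Kruskal stress-1, seeded by classical
scaling plus random restarts.

**Habitat model.** Suitability per variable is a trapezoid over
(abs_min, pref_min, pref_max, abs_max) — zero at and beyond the
absolute bounds, one on the preferred range, linear ramps between; cell
suitability is the product over variables (geometric-mean aggregation
is available but off by default).  Core habitat is P ≥ 0.3.  Areas sum
exact spherical cell areas R²Δλ(sin φ_top − sin φ_bot).  Latitudinal
comparisons use a two-sided Mann–Whitney U on suitable-cell latitudes,
area-weighted by default (plain cell-count mode gives exact recovery of
constructed shifts).  The shipped envelope parameters (depth
−650…0 m with preference −200…−10 m; SST −2…20 °C with preference
2…14 °C; ice 0–0.8 with preference ≤ 0.4) are a documented placeholder
for a cold-temperate coastal odontocete, used for testing; real
analyses must supply their own envelope table.

## The synthetic-data generator

Forward-time, individual-based, on a 1-D lattice of demes ("a coastal
corridor").  Each offspring draws a mother from a deme chosen by a
discretised Gaussian kernel of SD σ_f (renormalised at the coastline
ends) and a father likewise with SD σ_m; each deme holds half females,
half males, so the maternal (mtDNA) effective size is half the deme
size.  Microsatellites mutate stepwise (±1 repeat unit, rate 1e-3 per
copy); mtDNA is a finite-sites sequence (600 bp default, a scaled
stand-in for the study's 4465 bp fragment) inherited maternally with
per-site rate 5e-5–1e-4.  The nuclear G_ST trajectory is monitored
every 50 generations and a warning is raised if the last snapshots have
not plateaued.

The default preset emulates the study conditions: ~925 individuals
(31 × 30 subgroups nested in 10 regions along the corridor), 10 loci,
~4% missing calls, an mtDNA subsample, and female philopatry
σ_f/σ_m = 0.2.  The absolute kernel scale matters as much as the
ratio: σ_f must allow some female exchange between neighbouring demes
(σ_f ≈ 1 deme) or demes fix private haplotypes and the *gradient*
disappears, while σ_m ≈ 5 demes makes male-mediated gene flow nearly
global so the nuclear IBD signal sits at the estimation-noise floor —
which is exactly the regime the markers show in the real system (strong
mtDNA IBD, marginal nuclear IBD).  The replicated-contrast preset uses
20 demes × 40 diploids, 1600 generations of burn-in (≈4× the total
maternal population size), and measures mtDNA IBD between *regions*
(pooling subgroups stabilises single-locus haplotype frequencies) and
nuclear IBD between *subgroups* (where a weak biparental signal is best
detected) — the same two-level design as the study.

What the generator does **not** emulate: real coastline geometry and
2-D habitat, selection, overlapping generations, age structure,
genotyping artefacts beyond missingness (no null alleles or size
shifts), and recombination (irrelevant for unlinked loci).  Passing
tests therefore demonstrate the correctness and calibration of the
estimators and the qualitative sex-biased-dispersal logic, not
quantitative agreement with any real porpoise data set.

## Calibration experiments (problem sizes)

- **IBD contrast**: 100 replicates at σ_f/σ_m = 0.2 (expectation: mtDNA
  r² exceeds nuclear r² in ≥95) and 100 at σ_f = σ_m (expectation:
  symmetric).  Mean r² ≈ 0.5 (mtDNA) vs ≈ 0.04 (nuclear), a ratio of
  roughly ten.
- **Type-I calibration**: 200 replicates per permutation test at small
  instance sizes (15–30 individuals, 99 permutations), KS uniformity at
  α = 0.01.
- **Neutrality**: 500 single-deme replicates (haploid size 100, 1000
  generations ≈ 10N burn-in, n = 20 sampled); mean D within ±0.15 of 0.
- **LD-Ne**: 50 replicates, true Ne = 100, 12 loci initialised with
  standing allelic diversity, 100 generations.
- **Habitat**: closed-form area and a constructed 10° shift with both
  suitable bands interior to the grid.

## Numerical choices and degenerate inputs

Missing genotype calls are whole-call (half-missing promoted); QC drops
individuals under 6 typed loci and is idempotent.  Monomorphic loci:
He = 0, F_IS undefined (flagged), M = 1 by convention.  Saturated
distances are infinite, never clamped.  Permutation p-values are never
0.  All random streams are NumPy Generators seeded explicitly; derived
seeds stay below 2³¹.  Duplicate coordinates break the Delaunay
triangulation and raise unless jitter is requested.  The Genepop
2- vs 3-digit ambiguity is resolved per-token by width (or an explicit
``digits`` flag); the long-form CSV dialect is canonical for fixtures.

## Known limitations

Single-locus mtDNA inference is genealogically noisy: even under strong
philopatry a few percent of simulated replicates show weak mtDNA IBD
(r² < 0.1), which is why the acceptance property is stated over
replicates rather than per data set.  The divMigrate-style migration
values are *relative*; only their pattern, not their scale, is
interpretable, and the 2·Ne·m products inherit the LD-Ne infinities.
The Wang estimator omits the finite-reference-sample bias correction
(negligible for the pooled references used here, by simulation).  The
habitat model ignores proximity to land and primary production.
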