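# Methods

## Model and assumptions

`gravikin` estimates the *effective dispersal distance kernel* of an insect
population from spatially indexed genotypes.  Effective dispersal is the
distance between an individual's birthplace and its own breeding site —
dispersal filtered through one generation of successful reproduction, which is
the quantity that matters for gene flow and for release-program design.

The close-kin method rests on three assumptions:

1. Each one-generation link in a pedigree contributes one kernel-distributed
   displacement.  A close-kin pair of category *c* is separated by a chain of
   *m* such displacements, where *m* lies in a category-specific set:
   parent-offspring {2}, full siblings {2, 3} (3 when the mother splits the
   egg batch across two sites, "skip oviposition"), 2nd-degree {2, 3, 4, 5},
   3rd-degree {2, 3, 4, 5}.  These sets are data (`DecompositionRule`), not
   code, and can be extended to other categories.
2. Dividing the observed pair separation *d* by each plausible *m* yields
   candidate per-generation distances; pooling candidates across pairs and
   categories gives a sample that is treated as i.i.d. for fitting.  The
   within-pair dependence (one pair contributes up to four candidates) and
   the vector-sum geometry (the chain is not collinear, so *d*/*m*
   underestimates the per-step length) are acknowledged, not modeled; the
   isotropic-simulation tests quantify the resulting downward bias at roughly
   15–20% of the kernel mean, within the tolerance used for validation.
3. Pairs captured in the same trap (zero separation) carry no usable distance
   and are excluded, with their count reported.

Distances are Euclidean 3-D: horizontal separation on a local metric plane
plus the height difference of the traps.  Longitude/latitude are projected by
rotating WGS84 ECEF coordinates into the east-north frame at the data
centroid; for extents under 5 km this agrees with geodesics to well below
0.1% (verified against an independent Vincenty implementation in the tests).

## Kernel fitting

Exponential, Weibull and lognormal families are fitted by maximum likelihood
(exponential and lognormal in closed form; Weibull via `scipy`'s constrained
fit with location pinned to zero).  Reported per fit: log-likelihood,
AIC = 2p − 2ℓ, BIC = p·ln n − 2ℓ, and the Kolmogorov–Smirnov statistic
against the fitted CDF.  The KS value is reported as a distance only — a
p-value would be invalid with parameters estimated from the same sample
unless bootstrap-calibrated, which is out of scope.  Parameter intervals are
parametric-bootstrap (resample from the fitted kernel, refit; median and
2.5/97.5 percentiles; 1000 replicates by default).  The exponential MLE
λ̂ = n/Σx is cross-checked against a numeric score-equation solver to 1e-8
relative in the tests.

The distance kernel k_D relates to the location kernel k_L by
k_D(r) = 2πr·k_L(r) in 2-D and 4πr²·k_L(r) in 3-D;
`distance_to_location_kernel` returns k_L as an evaluable density.

## Null ensemble and density comparison

The null for "no spatial kin structure" resamples pair distances (with
replacement) from the recorded non-close-kin distances, assigns categories to
match the observed per-category counts, and pushes each of 100 replicates
through the same decomposition.  Observed and null candidate samples are
compared with a permutation test of equality of two densities: the statistic
is the integrated squared difference between Gaussian KDEs on a shared grid,
with a single normal-reference bandwidth computed from the pooled sample so
the statistic is symmetric; p = (1 + #{perm ≥ obs})/(n_perm + 1).  The test's
type-I error is verified at 5% (±3 points) over 500 null repetitions.

## Kinship classification

Pairwise statistics are computed on called genotypes over pairwise-complete
sites (minimum 500 by default; fewer → UNASSIGNED): KING-robust kinship
φ = (n11 − 2·n_opp)/(het_i + het_j), R0 = n_opp/n11, and R1 = n11 over
discordant-genotype sites.  None require population allele frequencies.
Classification uses geometric-midpoint bands on φ (≥2^−1.5 duplicate;
[2^−2.5, 2^−1.5) 1st degree; [2^−3.5, 2^−2.5) 2nd; [2^−4.5, 2^−3.5) 3rd;
below, unrelated), with the 1st degree split into parent-offspring when
R0 < 0.005 (PO pairs cannot produce opposite homozygotes barring error).  All
bands are configurable.  Known limitation: kinship is biased downward under
local population structure; no correction is applied.  At 10k SNPs the tests
demonstrate ≥95% full-sib recall and <1% unrelated→close-kin false positives
on independent simulated pairs; in small closed populations, background
relatedness (4th degree and beyond) genuinely blurs the unrelated/3rd-degree
boundary, which is a property of the data, not the classifier.

## IBD and sigma

PCA genetic distance: per-site mean imputation of missing calls, centering,
SVD; with all axes retained the rotation preserves Euclidean distances
exactly, which the tests lock against a brute-force eigendecomposition.
Mantel r is the Pearson correlation of lower-triangle entries, with p from
1000 joint row/column permutations and a bootstrap-over-individuals CI; the
partial Mantel controls temporal distance via the standard three-correlation
formula with the same permutation scheme.  The IBD slope is OLS on pairs with
normal-theory CIs (pair non-independence acknowledged; the Mantel test, not
the OLS p-value, is the significance arbiter).

σ = √(1/4π*Db*) with the 95% interval from the cross-combination
[σ(b_hi, D_hi), σ(b_lo, D_lo)] — conservative, monotone-correct, and matching
the interval style of the study tables.

## Effective size and density

* **PWoP**: full-sib dyads are union-found into sibships (two parent slots
  each); half-sib dyads merge father slots (half sibs taken as paternal,
  since females of this species rarely re-mate).  The reconstructed
  offspring-count vector k feeds the Crow–Denniston inbreeding form
  N̂e = (k̄·Np − 2)/(k̄ − 1 + Vk/k̄).  The CI follows the printed procedure
  (100 resamples, each replacing one random individual with a duplicate of
  another); a conventional bootstrap would also be defensible but is not what
  the study reports.
* **LD-Ne**: mean squared dosage correlation over locus pairs (loci
  mean-imputed, MAF ≥ 0.05, random locus subsample above 400 for tractability),
  Waples (2006) random-mating bias constants (1/S + 3.19/S² for S ≥ 30),
  quadratic inversion to N̂e, delete-one-locus jackknife CI.  r̂² at or below
  its sampling expectation raises an explicit "unbounded" signal.
* **Trap survey**: D = 2 × monthly females / area, acre = 4046.8564224 m²;
  the monthly catch is treated as one generation's breeding females.

## Spatial autocorrelation

Squared genetic distances are Gower double-centered into covariance form C;
per 50-m class (half-open (lo, hi], ends on the class boundary),
r = Σ c_ij / Σ (c_ii + c_jj)/2 over pairs in the class.  Published variants of
this multivariate coefficient differ in normalization; this variant is locked
by brute-force oracle tests to 1e-10.  The null envelope is the 25th/975th
ranked values of 1000 location shuffles; the observed-r CI is 1000 bootstrap
draws of individuals.  The x-intercept bracket runs from the last class-end
with bootstrap-significantly-positive r to the first later class-end with
r ≤ 0 or envelope-significantly-negative r; the patch is reported as "at
least L × L" with L the lower bracket bound.  Classes with fewer than 10
pairs are reported as missing.

## Simulator

The generator emulates the study conditions: a square grid of multi-storey
buildings (default 25 buildings at 70 m spacing — typical high-rise
housing-block geometry — 12 floors at 3 m), traps at ground/mid/high floors
of every building, an exponential kernel with rate 0.022/m (mean ≈ 45 m),
skip-oviposition probability 0.2, Poisson families (mean 6) with a
carrying-capacity cap holding the census near the founder count, three
non-founder generations, founder allele frequencies Uniform(0.1, 0.9) at
20,000 SNPs with 10% missingness, and up to 100 gravid females captured by
their nearest trap within an 8-day window.  Dispersal directions are uniform
with the vertical component confined to the building height range by redrawing
the direction (never the length), so the drawn kernel length is exactly the
realized 3-D displacement.  Mate choice is distance-weighted
(exp(−d/kernel mean)), keeping half-sib and cousin chains spatially coherent.
All randomness flows through one seeded generator; a fixed seed reproduces the
output bitwise.

What the simulator does *not* emulate: male-specific biology, survival and
density dependence, linked loci, genotyping error beyond uniform missingness,
and anisotropic movement along corridors.  Passing tests therefore show the
estimators are correct under the stated model, not that real data meet the
model.

## Problem sizes used in the test suite

Validation runs are sized for quick iteration while keeping the statistics
meaningful: kinship accuracy at 10,000 SNPs and 100 pairs per category;
kernel recovery at 1,000 close-kin pairs (collinear construction, 10%
tolerance) and a 2,500-founder isotropic simulation with 1,000 captures (25%
tolerance, reflecting the vector-sum approximation); type-I error of the
density and Mantel tests over 500 nulls at 999 permutations each; LD-Ne on
six Wright–Fisher replicates at Ne = 100, S = 50, 2,000 SNPs; IBD emergence
over six simulated landscapes per arm.
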