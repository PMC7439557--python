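# gravikin

Spatial-genetics estimation of mosquito dispersal kernels from close-kin
pairs, isolation by distance and spatial autocorrelation.

Urban *Aedes aegypti* control programs (Wolbachia releases, SIT/IIT) need the
dispersal distance kernel of the local population: how far does a female get,
per generation of successful breeding, from her birthplace to her oviposition
site?  Mark-release-recapture is laborious and ethically fraught for disease
vectors.  `gravikin` implements a genetics-only alternative for populations
sampled with sticky oviposition traps (gravitraps) across high-rise buildings
and genotyped at genome-wide SNPs.

## What it computes

**Close-kin kernel decomposition.**  Each close-kin category carries a set of
plausible counts of one-generation dispersal events separating the pair:
PO = {2}, FS = {2, 3}, 2nd degree = {2, 3, 4, 5}, 3rd degree = {2, 3, 4, 5}.
Dividing each pair's 3-D separation distance *d* by every element of its set
yields candidate effective dispersal distances (for a 3rd-degree pair,
{*d*/2, *d*/3, *d*/4, *d*/5}); pooled over all pairs these are fitted by
maximum likelihood with exponential, Weibull and lognormal kernels
(AIC/BIC/KS comparison, 1000 parametric bootstraps), and tested against a
resampled non-kin null with a permutation test of density equality.

**IBD sigma.**  With close kin removed, the slope *b* of pairwise PCA genetic
distance on geographic distance (Mantel and partial-Mantel tested) combines
with the effective density *D* as

&nbsp;&nbsp;&nbsp;&nbsp;σ = √(1 / 4π*Db*)

to give the dispersal kernel spread.  *D* = *N*e / area comes from three
estimators: sib-frequency (PWoP, Crow–Denniston form), linkage-disequilibrium
*N*e (Waples small-sample correction, jackknife CI), or gravitrap counts
(monthly females × 2 for a 1:1 sex ratio, per m²).

**Genetic patch size.**  A multivariate spatial autocorrelation correlogram in
50-m classes with a 1000-permutation null envelope and bootstrap CIs; the
x-intercept brackets the side of the "genetic patch" of localized breeding.

**Simulator.**  A 3-D high-rise landscape with pedigree-structured dispersal,
Mendelian SNP genotypes, skip oviposition, local mate choice, and capture of
gravid females by the nearest trap — with full ground truth, so every
estimator can be validated against known parameters.

## Worked example

```python
from gravikin import simulate as sim, closekin_kernel as ck, ibd_sigma as ibd

cfg = sim.SimConfig(seed=42, n_snps=5000, n_founders=600, max_captures=120)
out = sim.simulate_population(cfg)                 # true kernel: rate 0.022/m
pairs, n_same = sim.truth_kin_pairs(out)           # 125 close-kin pairs
fit = ck.bootstrap_fit(ck.pool_candidates(pairs), "exponential",
                       n_boot=1000, seed=1)
print(fit.params, ck.kernel_summary(fit))
est = ibd.sigma_from_slope_density(0.0037, 0.0074, (0.0024, 0.0050),
                                   (0.0074, 0.0095))
print(est.sigma, est.ci)
```

prints (abridged):

```
exponential rate: 0.0267 per m (boot median 0.0267, 95% CI 0.0245-0.0294)
kernel mean = sd = 37.5 m; median 26 m; 95th percentile 112 m
sigma = 53.9 m (95% CI 40.9-66.9 m)
```

The fitted rate of 0.0267/m corresponds to a mean effective dispersal of
37.5 m against a simulated truth of 45.5 m — the decomposition treats each
pair's separation as a chain of collinear steps, so isotropic simulations
recover the mean with a modest downward bias (quantified in the tests).  The
σ line evaluates the IBD formula for a slope of 0.0037 per m at an effective
density of 0.0074 breeders/m², with the CI from the cross-combination of
both input intervals.

A CLI wraps the same functions:

```bash
gravikin simulate --out data/ --seed 21
gravikin full --traps data/traps.csv --captures data/captures.csv \
    --vcf data/genotypes.vcf --area-m2 490000 --out report.json
```

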