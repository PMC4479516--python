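# Methods

This note documents the models implemented in `ibrscape`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer should know.

## Landscape model and georeferencing

The landscape is a two-class raster (natural vegetation / agricultural
land / nodata) in the ESRI ASCII grid dialect. Site coordinates
(WGS84 decimal degrees) are projected with a local equirectangular
projection about the mean site latitude: x = R·Δlon·cos(lat̄),
y = R·Δlat with R = 6 371 000 m. Over a ~100 km extent the distance
error against great-circle (haversine) values is below 0.3%, which the
test suite checks; no external projection library is needed at this
scale. Analysis rasters cover the sites' bounding box plus a
configurable buffer (default 10 km) to limit boundary artifacts in the
circuit solves; the buffer matters because effective resistance is a
whole-domain quantity.

Habitat proportion around a site counts raster cells whose centres fall
within the disc (default radius 1 km); cell-centre membership converges
to the area fraction as resolution grows and keeps the operation exact
and order-independent.

## Circuit-theory resistance distances

Each usable cell is a node; neighbours are joined by a resistor with
resistance equal to the mean of the two cell resistances, multiplied by
√2 for diagonal neighbours (centre-to-centre distance), matching the
raster-connection convention of the standard circuit-analysis tools.
The effective resistance between focal cells is obtained by grounding
one node, factorizing the reduced graph Laplacian once
(`scipy.sparse.linalg.splu`) and solving one right-hand side per focal
node; all pairwise distances then come from the Green's-function
identity R_ij = G(i,i) + G(j,j) − 2G(i,j). A dense cross-check solves
(L + J/n)x = e_s − e_t, using the exact identity
(L + J/n)⁻¹ = L⁺ + J/n on a connected graph — deliberately avoiding
`pinv`, whose singular-value truncation loses accuracy when cell
resistances span decades. Sparse and dense routes agree to 1e−8 on
random surfaces, and to 1e−10 on closed-form cases (series chain 2.0;
4-neighbour square 1.0; 8-neighbour square 2−√2).

Focal sites snap to the nearest usable cell centre (ties broken by row,
then column). Disconnected pairs are reported as `inf` and excluded
from regressions with a warning. Because every pairwise resistance is
homogeneous of degree 1 in the cell resistances, a scenario
(c·n, c·a) yields c times the matrix of (n, a); the scenario scan
exploits this and caches one factorization per distinct
agricultural:natural ratio.

Scan resolutions: tests and examples run at 250–500 m cells. The
flat-landscape null model for the 18-site design uses 500 m cells;
refining the grid changes individual resistances by a near-constant
offset (the lattice Green's function scales with log cell size) and
leaves correlations essentially unchanged.

### Flat landscape vs Euclidean distance

On a uniform lattice, effective resistance grows approximately
logarithmically with separation (2-D lattice Green's function), so its
Pearson correlation with straight-line distance depends on the domain
shape and the spread of inter-site distances. For the packaged 18-site
design on a rectangular bounding box + 10 km buffer the correlation is
r ≈ 0.97 (Spearman 0.99); the handful of site pairs closer than ~5 km
sit well below the linear trend. Values of 0.99 arise when the domain
is shaped like the site band itself (quasi-one-dimensional current
flow); since the original study's raster extent is not published, the
package reports what the stated rectangular construction gives.

## Microsatellite statistics

* **Rarefied allelic richness**: E[alleles among g genes] =
  Σ_a [1 − C(N−N_a, g)/C(N, g)]; the default rarefaction depth is twice
  the smallest per-locus typed-individual count over populations
  (standardizing to the worst-sampled locus), exposed as a parameter.
  Population values average over loci.
* **Gene diversity**: per locus Ĥ = n/(n−1)(1 − Σp̂²) with n typed
  genes; the population value is the unweighted mean over loci (the
  per-locus weighting convention of the classic implementations is not
  documented; unweighted is the simplest defensible choice and is
  flagged here).
* **Differentiation**: Weir–Cockerham variance components a (among
  populations), b (among individuals within), c (within individuals),
  computed per locus and allele from sample sizes, allele frequencies
  and heterozygote proportions; multilocus θ is the ratio of summed
  components and may be slightly negative — it is reported as-is
  because downstream regressions need unbiased inputs. F_IS = 1 −
  Σc/Σ(b+c) from the same components.
* **Missing data** are handled by locus-wise deletion everywhere; no
  imputation.
* **Permutation conventions**: all randomization tests use the add-one
  estimator p = (1 + #{T* ≥ T})/(n_perm + 1), never returning 0, and a
  seeded generator so identical seeds give identical results.

### Null alleles and the ENA correction

Null alleles fail to amplify: visible/null heterozygotes are scored as
visible homozygotes and null/null genotypes as missing. Per locus ×
population (≥5 typed individuals) an EM algorithm treats apparent
homozygote counts as mixtures of true homozygotes and visible/null
heterozygotes under Hardy–Weinberg proportions. Because null/null
blanks are indistinguishable from ordinary missing data, they are not
counted as observations; instead the likelihood is conditioned on
observing a visible genotype by augmenting each E-step with the
expected unobserved null-homozygote class n·p_n²/(1−p_n²). Without this
truncation term the estimate is biased low by roughly p_n/(1+p_n)
scaling (≈ −0.05 at p_n = 0.2); with it the estimate is unbiased to
within ~0.002 in the test simulations. Convergence is declared when the
total frequency change falls below 1e−9 (at most 10 000 iterations);
data with no observed homozygote excess take the boundary estimate 0
directly, since the EM approaches 0 only geometrically.

The ENA-corrected pairwise θ recomputes the variance components using
the EM's visible-allele frequencies (which sum to 1 − p̂_n), augments
per-allele heterozygote counts with the expected visible/null
heterozygotes hidden among apparent homozygotes, and excludes the null
allele itself from the summation over alleles. With p̂_n = 0 this is
algebraically identical to the uncorrected estimator. In simulations
where one allele lineage per locus drifts like any other but fails to
amplify (frequency 0.25), the uncorrected matrix is biased upward and
roughly 60% noisier; the corrected matrix is closer to the
complete-genotype truth in ≈95% of simulated multi-population datasets.

### Exact HWE test

The Markov-chain exact test explores genotype tables with fixed allele
counts by swapping gene copies between two random individuals. A
uniformly random pairing of the 2n gene copies induces exactly the
conditional table distribution under Hardy–Weinberg, and the swap chain
preserves uniformity over pairings, so states are sampled from the null
without a Metropolis correction. The p-value is the proportion of
visited tables whose conditional probability does not exceed the
observed table's (log-scale comparison with a 1e−9 tie tolerance;
default 900 000 steps, 10% burn-in). A full-enumeration oracle covers
the two-allele case.

### Sex-biased dispersal

The corrected assignment index AIc is the log10 Hardy–Weinberg
probability of an individual's multilocus genotype at its own
population's leave-one-out allele frequencies (floor 0.01 for alleles
unobserved after leaving the individual out), centred within
populations. The randomization test compares male and female F_ST,
F_IS, mAIc and vAIc, permuting sex labels within populations;
populations containing a single sex are excluded with a warning.

## MMRR

Distance matrices are unfolded to their lower triangles in a fixed
(i<j) label order and z-scored, so coefficients are standardized and
invariant to affine rescaling of any input — which is what makes R²
comparable across resistance scenarios whose raw scales differ by five
orders of magnitude. OLS provides β, t and R²; significance comes from
jointly permuting rows and columns of the response matrix only
(predictors fixed), with add-one p-values on |t| and F. Reported
degrees of freedom use n(n−1)/2 − k − 1 but inference rests solely on
the permutations, because matrix entries are not independent.
Predictor sets with design condition number above 1e10 are rejected
naming the most correlated pair.

## Scenario scan and ratio profile

The scan evaluates 21 standard scenarios — (1,1) up to (1, 100 000)
plus inverse and intermediate pairs — and two baselines (Euclidean
distance; uniform resistance-1 raster on the same grid). The R² profile
is taken over the natural = 1 arm, and the stabilization ratio is the
smallest ratio whose R² is within a tolerance (default 0.005) of the
maximum over all larger ratios.

A structural caveat documented here because it shapes what the scan can
conclude: beyond roughly the stabilization ratio, the scenario
resistance matrices become nearly collinear (on patchy test landscapes
corr(R at 1000, R at 100 000) > 0.9999), because every inter-site path
must cross agricultural cells whose cost dominates and scales linearly
with the ratio. Consequently R² differences along the plateau are of
order 1e−4 — far below the sampling noise of a few dozen microsatellite
loci — and the location of the literal argmax on the plateau is not
identifiable; the scientifically supported statement is a lower bound:
the ratio at which the fit stabilizes. The profile shape (rising, then
flat) is reproducible; the argmax is not.

## Weighted GLMs, AICc, model averaging

Diversity responses are fitted by weighted least squares (statsmodels
WLS) over all 2⁴ subsets of {habitat proportion, mean pairwise F_ST,
latitude, longitude}; A_R models are weighted by sample size (estimate
precision varies with n), H_E models are unweighted. The normal
log-likelihood uses per-observation variance σ²/wᵢ with σ² at its MLE,
so rescaling all weights leaves everything unchanged; a perfect fit
caps the log-likelihood with a warning. k counts intercept, slopes and
σ², keeping AICc comparable across subsets. Averaging over the
ΔAICc ≤ 2 set renormalizes Akaike weights, uses natural averaging (over
models containing the term), unconditional SE
Σw̃ᵢ√(var(θ̂ᵢ)+(θ̂ᵢ−θ̄)²), a 1.96 CI multiplier (configurable; the
t-quantile alternative is a one-line change), and Σωi as relative
importance. Significance is "CI excludes zero".

## Synthetic-data generator

`generate_landscape` stamps n_patches random natural discs (radius 4
cells by default) on an agricultural background and places one
population site at the centre of each of n_pops distinct patches;
`simulate_genotypes` runs a forward-time island model on allele
frequencies: Dirichlet(1) ancestral frequencies per locus, each
generation a migration-weighted mixture of deme gene pools with weights
m_ij ∝ exp(−R_ij/λ) (rows normalized, self-weight floored at 0.5),
then multinomial drift at size N_e, and finally HWE genotype draws.
Null alleles are injected by marking each gene copy null with the
locus' null frequency (visible/null → apparent homozygote, null/null →
missing), plus an independent missing-at-random rate.

Defaults mirror the emulated sampling design where stated — 18
populations of 20 individuals, 10 loci — and otherwise are chosen once
on biological and structural grounds: 8 alleles per locus (enough
polymorphism for assignment and richness statistics at tolerable cost;
real microsatellites with 12–40 alleles are reachable via config),
N_e = 100 (small patch demes), G = 200 generations (near drift-migration
equilibrium for the migration rates involved), and
λ = P90(pairwise R)/10, which makes migration common between the
closest patches and rare (~e⁻⁹) across the 90th-percentile resistance.
Under these defaults pairwise θ spans roughly 0–0.3 and rank-correlates
with the generating resistance (Spearman > 0.5 over seeds), which is
the structure the scan must detect. What the generator does **not**
emulate: mutation (frequencies only drift), linkage, uneven sampling
effort, allele-size homoplasy, spatially continuous (non-deme)
structure, and natural corridors between patches — its discs are
isolated, which makes the high-ratio collinearity discussed above even
stronger than in real landscapes. Passing tests therefore demonstrate
internal consistency of the pipeline under a known monotone
resistance–differentiation link, not calibration to any particular
empirical system.

## Numerical and testing choices

* Permutation counts in tests (99–999) trade Monte-Carlo resolution
  against suite runtime; calibration checks use 500 replicates per test
  with fixed seeds and accept type-I error 0.05 ± 0.02.
* The HWE chain in calibration uses 2000 steps — the statistic is
  near-continuous with ≥5 alleles, so short chains are adequate there;
  the production default stays at 900 000 steps.
* Simulation sizes in tests (60×60 grids, 12 demes, 10 loci, 50
  replicates) are the package's chosen desk-scale study conditions.
* Distance matrices are validated on construction (symmetry to 1e−12,
  zero diagonal); F_ST matrices may carry negative entries by design.
* All seeds derive from `numpy.random.default_rng`; every stochastic
  public function takes an explicit seed.
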