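# ibrscape

Landscape genetics of fragmented two-class habitats: from a classified
habitat raster and multilocus microsatellite genotypes to circuit-theory
resistance distances, isolation-by-resistance model fits, and
model-averaged predictors of genetic diversity.

## The problem

In chronically fragmented agricultural landscapes — the motivating system
is a habitat-specialist grasshopper of Mediterranean esparto grasslands,
sampled at 18 sites in central Spain — remnant patches of semi-natural
vegetation may act as corridors for gene flow while the surrounding
cultivated matrix impedes it. Two questions follow:

1. **Is genetic differentiation shaped by distance or by resistance?**
   Pairwise F_ST between populations is regressed on (a) Euclidean
   distance (isolation by distance, IBD) and (b) effective-resistance
   distances computed on resistance surfaces that assign a cost to each
   habitat class (isolation by resistance, IBR). Scanning the
   agricultural:natural resistance *ratio* over 21 scenarios (0.01 to
   100 000) and profiling the regression R² against the ratio estimates
   how much more resistant cultivated land is than natural habitat.
2. **Does fragmentation erode local genetic diversity?** Per-population
   allelic richness (A_R, rarefied to a common sample size) and gene
   diversity (H_E) are modelled as normal-error GLMs of habitat cover
   around the site, isolation (mean pairwise F_ST), latitude and
   longitude, with AICc ranking over all 2⁴ predictor subsets and
   model averaging of the near-best set (ΔAICc ≤ 2).

## What is inside

| module | contents |
| --- | --- |
| `ibrscape.raster` | ESRI ASCII habitat grids, resistance surfaces, habitat proportion around a site |
| `ibrscape.sites` | site tables, equirectangular projection, packaged 18-site design (`load_lamancha_sites`) |
| `ibrscape.circuit` | grid resistor networks, sparse effective-resistance solver + dense oracle |
| `ibrscape.genotypes` | Genepop / long-CSV diploid genotype IO |
| `ibrscape.diversity` | rarefied allelic richness, unbiased gene diversity |
| `ibrscape.fst` | Weir–Cockerham θ, pairwise matrices, permutation tests |
| `ibrscape.nulls` | null-allele EM estimation, ENA-corrected F_ST |
| `ibrscape.hwe` | Markov-chain exact HWE test, LD permutation test, Holm correction |
| `ibrscape.sexbias` | assignment indices, sex-biased-dispersal randomization |
| `ibrscape.mmrr` | multiple matrix regression with randomization |
| `ibrscape.model_selection` | weighted GLMs, AICc, model averaging |
| `ibrscape.scan` | the 21-scenario IBR scan and R²-ratio profile |
| `ibrscape.simulate` | synthetic landscapes and resistance-structured genotypes |

Key statistics, in the field's notation: effective resistance between
focal cells s, t is `R_st = (e_s − e_t)ᵀ L⁺ (e_s − e_t)` for the graph
Laplacian L of the resistor network (8-neighbour cells, edge resistance
= mean cell resistance, ×√2 on diagonals); differentiation is
Weir–Cockerham θ = Σa / Σ(a+b+c) over loci and alleles; MMRR fits
z-scored unfolded distance matrices by OLS with significance from
jointly permuting rows and columns of the response; AICc =
−2logL + 2k + 2k(k+1)/(n−k−1).

## Worked example

```python
import numpy as np
import ibrscape as ib

# 1. synthetic study system: patchy landscape, 8 populations
cfg = ib.SimulationConfig(nrows=60, ncols=60, n_pops=8, n_patches=14,
                          n_individuals=20, n_loci=10, seed=7)
raster, sites = ib.generate_landscape(cfg)
xy = ib.project_coordinates(sites)

# 2. genotypes shaped by a 1000:1 agricultural:natural resistance ratio
surface = ib.build_resistance_surface(raster, ib.IBRScenario("true", 1, 1000))
rmat = ib.resistance_matrix(surface, xy)
genotypes = ib.simulate_genotypes(rmat, cfg)

# 3. differentiation, then the scenario scan
fst = ib.pairwise_fst_matrix(genotypes)
scan = ib.run_scan(raster, xy, fst, n_perm=999, seed=1)
profile, stabilization = ib.r2_profile(scan)
```

Selected rows of `scan.table` from this exact run:

```
model    ratio  fst_r2  fst_beta  fst_p
  IBD      NaN   0.572     0.756  0.001
 FLAT      NaN   0.468     0.684  0.003
IBR-A      1.0   0.468     0.684  0.001
IBR-K     25.0   0.607     0.779  0.002
IBR-M    100.0   0.620     0.787  0.001
IBR-O   1000.0   0.624     0.790  0.001
IBR-U 100000.0   0.624     0.790  0.001
stabilization ratio: 100
```

Reading it: plain distance (IBD, R² = 0.57) explains differentiation
less well than resistance scenarios that make agricultural land ≥100×
more resistant than natural habitat (R² = 0.62); the fit saturates
beyond that ratio — the landscape, not raw distance, structures gene
flow, but the data bound the ratio only from below. The flat-resistance
baseline (all cells resistance 1) behaves like IBD, and scenario IBR-A
(equal resistances) reproduces it exactly.

The same pipeline runs from the shell:

```sh
ibrscape simulate --seed 7 --n-pops 8 --out-prefix syn
ibrscape resist syn_habitat.asc syn_sites.csv --natural 1 --agricultural 1000 --out R.csv
# fst.csv: a pairwise F_ST matrix CSV, e.g. DistanceMatrix.write_csv(pairwise_fst_matrix(g))
ibrscape scan syn_habitat.asc syn_sites.csv fst.csv --out scan.csv --plot profile.png
ibrscape diversity-glm diversity_table.csv --response A_R
```

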