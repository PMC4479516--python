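"""Per-population diversity statistics: rarefied allelic richness and gene diversity."""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


def _rarefied_richness_from_counts(counts: dict[int, int], g: int) -> float:
    """E[number of distinct alleles in a subsample of g genes].

    counts maps allele -> gene-copy count; uses the hypergeometric
    expectation sum_a [1 - C(N - N_a, g) / C(N, g)].
    """
    n_total = sum(counts.values())
    if g < 1:
        raise ValueError("rarefaction depth g must be >= 1")
    if g > n_total:
        raise ValueError(f"g={g} exceeds the {n_total} typed genes")
    denom = math.comb(n_total, g)
    return float(
        sum(1.0 - math.comb(n_total - na, g) / denom for na in counts.values())
    )


def default_rarefaction_depth(genotypes: GenotypeMatrix) -> int:
    """2 x the smallest per-locus typed-individual count over all populations."""
    m = min(
        int((genotypes.pop_mask(pop) & genotypes.typed(l)).sum())
        for pop in genotypes.populations
        for l in range(genotypes.n_loci)
    )
    if m < 1:
        raise ValueError("some population has a locus with no typed individuals")
    return 2 * m


def rarefied_allelic_richness(
    genotypes: GenotypeMatrix, g: int | None = None
) -> pd.DataFrame:
    """Rarefied allelic richness per population x locus, plus the mean.

    Standardizes richness to a common sample of ``g`` genes so
    populations with different sample sizes are comparable.  Returns a
    DataFrame indexed by population with one column per locus and an
    ``A_R`` column (mean over loci).
    """
    if g is None:
        g = default_rarefaction_depth(genotypes)
    rows = {}
    for pop in genotypes.populations:
        vals = []
        for l in range(genotypes.n_loci):
            counts = genotypes.allele_counts(pop, l)
            n_total = sum(counts.values())
            if g > n_total:
                raise ValueError(
                    f"g={g} exceeds the {n_total} typed genes at locus "
                    f"{genotypes.loci[l]!r} in population {pop!r}"
                )
            vals.append(_rarefied_richness_from_counts(counts, g))
        rows[pop] = vals
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(genotypes.loci))
    out["A_R"] = out.mean(axis=1)
    return out


def gene_diversity(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Unbiased gene diversity (expected heterozygosity) per population.

    Per locus, H = n/(n-1) * (1 - sum p^2) with n typed genes; the
    population value is the unweighted mean over loci.  Loci with fewer
    than 2 typed genes in a population are skipped with a warning.
    """
    rows = {}
    for pop in genotypes.populations:
        vals = []
        for l in range(genotypes.n_loci):
            counts = genotypes.allele_counts(pop, l)
            n = sum(counts.values())
            if n < 2:
                warnings.warn(
                    f"locus {genotypes.loci[l]!r} has <2 typed genes in {pop!r}; skipped"
                )
                vals.append(np.nan)
                continue
            p = np.array(list(counts.values())) / n
            vals.append(n / (n - 1) * (1.0 - float((p**2).sum())))
        rows[pop] = vals
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(genotypes.loci))
    out["H_E"] = out.mean(axis=1, skipna=True)
    return out
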