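"""Null-allele frequency estimation (EM) and ENA-corrected F_ST.

Microsatellite null alleles fail to amplify: a visible/null heterozygote
is scored as a visible homozygote and a null/null genotype as missing,
inflating apparent homozygosity and, with it, uncorrected differentiation
estimates.  Per locus x population the EM algorithm treats apparent
homozygote counts as mixtures of true homozygotes and visible/null
heterozygotes under Hardy–Weinberg proportions; the ENA correction then
recomputes the Weir–Cockerham components from the EM-adjusted visible
allele frequencies, excluding the null allele itself from the summation
over alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .fst import _locus_components
from .genotypes import GenotypeMatrix

MIN_TYPED = 5


@dataclass
class LocusPopNullFit:
    """EM output for one locus x population."""

    null_freq: float
    visible_freqs: dict[int, float]  # allele -> frequency (sums to 1 - null_freq)
    n_typed: int
    converged: bool
    estimated: bool  # False when too few typed individuals


@dataclass
class NullAlleleEstimate:
    """Per locus x population null-allele frequency estimates."""

    fits: dict[tuple[str, str], LocusPopNullFit]  # (locus, pop) -> fit

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "locus": loc,
                "pop": pop,
                "null_freq": f.null_freq,
                "n_typed": f.n_typed,
                "converged": f.converged,
                "estimated": f.estimated,
            }
            for (loc, pop), f in self.fits.items()
        ]
        return pd.DataFrame(rows)

    def mean_by_locus(self) -> pd.Series:
        df = self.to_frame()
        df = df[df.estimated]
        return df.groupby("locus")["null_freq"].mean()


def _em_single(
    hom_counts: dict[int, int],
    het_pairs: list[tuple[int, int]],
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> tuple[float, dict[int, float], bool]:
    """EM for one locus x population.

    ``hom_counts`` maps allele -> apparent homozygote individuals;
    ``het_pairs`` lists observed (distinct-allele) heterozygous genotypes.
    Missing genotypes carry no information (null/null blanks cannot be
    separated from ordinary missing data), so the likelihood is
    conditioned on observing a visible genotype: the E-step augments the
    sample with the expected number of unobserved null homozygotes,
    n·p_n²/(1−p_n²), which removes the truncation bias.
    """
    alleles = sorted(
        set(hom_counts) | {a for pair in het_pairs for a in pair}
    )
    n_ind = sum(hom_counts.values()) + len(het_pairs)
    total_genes = 2 * n_ind
    het_copy = {a: 0 for a in alleles}
    for a, b in het_pairs:
        het_copy[a] += 1
        het_copy[b] += 1
    # observed frequencies as the starting point, with a small null mass
    p = {
        a: (2 * hom_counts.get(a, 0) + het_copy[a]) / total_genes for a in alleles
    }
    # no observed homozygote excess -> the boundary estimate 0 (the EM
    # approaches 0 only geometrically, so decide it up front)
    expected_het = n_ind * (1.0 - sum(v * v for v in p.values()))
    if len(het_pairs) >= expected_het:
        return 0.0, p, True
    pn = 0.1
    p = {a: v * (1 - pn) for a, v in p.items()}
    for _ in range(max_iter):
        exp_null = 0.0
        exp_copy = {}
        for a in alleles:
            pa = p[a]
            o_hom = hom_counts.get(a, 0)
            denom = pa * pa + 2 * pa * pn
            if o_hom and denom > 0:
                w_null = 2 * pa * pn / denom  # P(visible/null | apparent hom)
                exp_null += o_hom * w_null
                exp_copy[a] = o_hom * (2 - w_null) + het_copy[a]
            else:
                exp_copy[a] = 2 * o_hom + het_copy[a]
        hidden = n_ind * pn * pn / (1.0 - pn * pn) if pn < 1 else 0.0
        total = total_genes + 2 * hidden
        pn_new = (exp_null + 2 * hidden) / total
        p_new = {a: exp_copy[a] / total for a in alleles}
        delta = abs(pn_new - pn) + sum(abs(p_new[a] - p[a]) for a in alleles)
        p, pn = p_new, pn_new
        if delta < tol:
            return pn, p, True
    return pn, p, False


def null_allele_em(genotypes: GenotypeMatrix, min_typed: int = MIN_TYPED) -> NullAlleleEstimate:
    """EM null-allele frequency per locus x population.

    Loci/populations with fewer than ``min_typed`` typed individuals are
    flagged not-estimated.  Loci with heterozygote excess converge to a
    null frequency of zero (the EM cannot go negative).
    """
    fits: dict[tuple[str, str], LocusPopNullFit] = {}
    for l, locus in enumerate(genotypes.loci):
        for pop in genotypes.populations:
            mask = genotypes.pop_mask(pop) & genotypes.typed(l)
            n_typed = int(mask.sum())
            if n_typed < min_typed:
                fits[(locus, pop)] = LocusPopNullFit(np.nan, {}, n_typed, False, False)
                continue
            pairs = genotypes.alleles[mask, l, :]
            hom = pairs[:, 0] == pairs[:, 1]
            hom_counts: dict[int, int] = {}
            for a in pairs[hom, 0]:
                hom_counts[int(a)] = hom_counts.get(int(a), 0) + 1
            het_pairs = [tuple(map(int, g)) for g in pairs[~hom]]
            pn, p, converged = _em_single(hom_counts, het_pairs)
            fits[(locus, pop)] = LocusPopNullFit(pn, p, n_typed, converged, True)
    return NullAlleleEstimate(fits)


def zero_null_estimates(genotypes: GenotypeMatrix) -> NullAlleleEstimate:
    """Estimates with every null frequency fixed at zero (observed frequencies).

    Useful as a no-correction baseline: ENA under these estimates equals
    the uncorrected estimator exactly.
    """
    fits: dict[tuple[str, str], LocusPopNullFit] = {}
    for l, locus in enumerate(genotypes.loci):
        for pop in genotypes.populations:
            counts = genotypes.allele_counts(pop, l)
            total = sum(counts.values())
            freqs = {a: c / total for a, c in counts.items()} if total else {}
            fits[(locus, pop)] = LocusPopNullFit(
                0.0, freqs, total // 2, True, total > 0
            )
    return NullAlleleEstimate(fits)


def _corrected_locus_arrays(
    genotypes: GenotypeMatrix,
    estimates: NullAlleleEstimate,
    locus_index: int,
    pops: list[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """(n, p, h) across ``pops`` for one locus using EM-corrected values.

    Visible-allele frequencies come from the EM; heterozygote counts are
    augmented by the expected visible/null heterozygotes hidden among the
    apparent homozygotes.  The null allele itself carries no column, so
    its variance components are excluded.
    """
    locus = genotypes.loci[locus_index]
    per_pop = []
    alleles_union: set[int] = set()
    for pop in pops:
        fit = estimates.fits.get((locus, pop))
        if fit is None or not fit.estimated:
            return None
        alleles_union |= set(fit.visible_freqs)
    alleles = sorted(alleles_union)
    a_index = {a: k for k, a in enumerate(alleles)}
    n = np.zeros(len(pops))
    p = np.zeros((len(pops), len(alleles)))
    h = np.zeros((len(pops), len(alleles)))
    for i, pop in enumerate(pops):
        fit = estimates.fits[(locus, pop)]
        mask = genotypes.pop_mask(pop) & genotypes.typed(locus_index)
        pairs = genotypes.alleles[mask, locus_index, :]
        n[i] = len(pairs)
        if n[i] == 0:
            continue
        pn = fit.null_freq
        for a, freq in fit.visible_freqs.items():
            p[i, a_index[a]] = freq
        het_count = np.zeros(len(alleles))
        for a1, a2 in pairs:
            if a1 != a2:
                het_count[a_index[int(a1)]] += 1
                het_count[a_index[int(a2)]] += 1
            else:
                pa = fit.visible_freqs.get(int(a1), 0.0)
                denom = pa * pa + 2 * pa * pn
                if denom > 0:
                    het_count[a_index[int(a1)]] += 2 * pa * pn / denom
        h[i] = het_count / n[i]
    return n, p, h


def ena_corrected_fst(
    genotypes: GenotypeMatrix, estimates: NullAlleleEstimate | None = None
) -> DistanceMatrix:
    """Pairwise θ corrected for null alleles (ENA).

    With all null frequencies estimated at zero this reduces exactly to
    the uncorrected pairwise estimator.  Loci lacking an estimate in
    either population of a pair are dropped for that pair with a warning.
    """
    if estimates is None:
        estimates = null_allele_em(genotypes)
    pops = genotypes.populations
    nv = len(pops)
    vals = np.zeros((nv, nv))
    for i in range(nv):
        for j in range(i + 1, nv):
            pair = [pops[i], pops[j]]
            a_sum = b_sum = c_sum = 0.0
            used = 0
            for l in range(genotypes.n_loci):
                arrays = _corrected_locus_arrays(genotypes, estimates, l, pair)
                if arrays is None:
                    warnings.warn(
                        f"locus {genotypes.loci[l]!r} lacks null estimates for "
                        f"pair ({pops[i]}, {pops[j]}); dropped"
                    )
                    continue
                comp = _locus_components(*arrays)
                if comp is None:
                    continue
                a, b, c = comp
                a_sum += a.sum()
                b_sum += b.sum()
                c_sum += c.sum()
                used += 1
            if used == 0:
                raise ValueError(f"no usable locus for pair ({pops[i]}, {pops[j]})")
            denom = a_sum + b_sum + c_sum
            vals[i, j] = vals[j, i] = a_sum / denom if denom != 0 else 0.0
    return DistanceMatrix(pops, vals, kind="fst")
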