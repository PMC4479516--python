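"""Weir–Cockerham F-statistics and their permutation tests.

The differentiation estimator is the variance-components θ: per locus
and allele, among-population (a), among-individual-within-population (b)
and within-individual (c) components are computed from sample sizes,
allele frequencies and heterozygote proportions; the multilocus estimate
is the ratio of summed components, which may be slightly negative in
weakly differentiated data and is reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .genotypes import GenotypeMatrix


def _locus_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Per-allele variance components for one locus.

    Parameters
    ----------
    n : (r,) typed individuals per population (populations with data only)
    p : (r, A) allele frequencies
    h : (r, A) proportion of individuals heterozygous for each allele

    Returns per-allele arrays (a, b, c), or None if fewer than two
    populations carry data or the mean sample size is <= 1.
    """
    keep = n > 0
    n, p, h = n[keep], p[keep], h[keep]
    r = len(n)
    if r < 2:
        return None
    nbar = n.mean()
    if nbar <= 1:
        return None
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    if nc <= 0:
        return None
    w = n[:, None]
    pbar = (w * p).sum(axis=0) / (r * nbar)
    s2 = (w * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (w * h).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def _locus_arrays(
    alleles: np.ndarray, pop_idx: np.ndarray, n_pops: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, p, h) for one locus from compact allele codes.

    ``alleles`` is (m, 2) with codes in 0..A-1 for typed individuals
    only; ``pop_idx`` maps each to a population 0..n_pops-1.
    """
    n_alleles = int(alleles.max()) + 1 if alleles.size else 0
    counts = np.zeros((n_pops, n_alleles))
    het = np.zeros((n_pops, n_alleles))
    np.add.at(counts, (pop_idx, alleles[:, 0]), 1)
    np.add.at(counts, (pop_idx, alleles[:, 1]), 1)
    is_het = alleles[:, 0] != alleles[:, 1]
    np.add.at(het, (pop_idx[is_het], alleles[is_het, 0]), 1)
    np.add.at(het, (pop_idx[is_het], alleles[is_het, 1]), 1)
    n = counts.sum(axis=1) / 2.0
    safe_n = np.where(n > 0, n, 1.0)
    p = counts / (2 * safe_n[:, None])
    h = het / safe_n[:, None]
    return n, p, h


def _prepare_loci(
    genotypes: GenotypeMatrix, pops: list[str]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Compact per-locus allele arrays and population indices."""
    pop_index = {p: i for i, p in enumerate(pops)}
    in_pops = np.isin(genotypes.pops, pops)
    per_locus_alleles, per_locus_pidx = [], []
    for l in range(genotypes.n_loci):
        mask = in_pops & genotypes.typed(l)
        raw = genotypes.alleles[mask, l, :]
        _, compact = np.unique(raw, return_inverse=True)
        per_locus_alleles.append(compact.reshape(raw.shape))
        per_locus_pidx.append(
            np.array([pop_index[p] for p in genotypes.pops[mask]], dtype=np.int64)
        )
    return per_locus_alleles, per_locus_pidx


def _theta_components(
    per_locus_alleles: list[np.ndarray],
    per_locus_pidx: list[np.ndarray],
    n_pops: int,
) -> np.ndarray:
    """Summed (a, b, c) per locus; NaN rows for unusable loci."""
    out = np.full((len(per_locus_alleles), 3), np.nan)
    for l, (alleles, pidx) in enumerate(zip(per_locus_alleles, per_locus_pidx)):
        if alleles.size == 0:
            continue
        comp = _locus_components(*_locus_arrays(alleles, pidx, n_pops))
        if comp is None:
            continue
        a, b, c = comp
        out[l] = (a.sum(), b.sum(), c.sum())
    return out


def _theta_from_locus_data(
    per_locus_alleles: list[np.ndarray],
    per_locus_pidx: list[np.ndarray],
    n_pops: int,
) -> tuple[float, np.ndarray]:
    comp = _theta_components(per_locus_alleles, per_locus_pidx, n_pops)
    ok = np.isfinite(comp).all(axis=1)
    if not ok.any():
        raise ValueError("no locus with usable data in >= 2 populations")
    sums = comp[ok].sum(axis=0)
    denom = sums.sum()
    theta = float(sums[0] / denom) if denom != 0 else 0.0
    return theta, comp


@dataclass
class WCFstResult:
    """Multilocus θ with per-locus variance components."""

    theta: float
    per_locus: pd.DataFrame  # columns a, b, c, theta; one row per locus

    @property
    def fis(self) -> float:
        tot = self.per_locus.dropna()
        denom = (tot["b"] + tot["c"]).sum()
        return float(1.0 - tot["c"].sum() / denom) if denom != 0 else 0.0


def wc_fst(genotypes: GenotypeMatrix, pops: list[str] | None = None) -> WCFstResult:
    """Weir–Cockerham θ over a population set (default: all populations)."""
    if pops is None:
        pops = genotypes.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    la, lp = _prepare_loci(genotypes, pops)
    theta, comp = _theta_from_locus_data(la, lp, len(pops))
    df = pd.DataFrame(comp, columns=["a", "b", "c"], index=list(genotypes.loci))
    with np.errstate(invalid="ignore", divide="ignore"):
        df["theta"] = df["a"] / (df["a"] + df["b"] + df["c"])
    return WCFstResult(theta, df)


def pairwise_fst_matrix(genotypes: GenotypeMatrix) -> DistanceMatrix:
    """All pairwise multilocus θ values as a distance matrix (kind='fst')."""
    pops = genotypes.populations
    n = len(pops)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = wc_fst(genotypes, [pops[i], pops[j]]).theta
    return DistanceMatrix(pops, vals, kind="fst")


def mean_pairwise_fst(fst_matrix: DistanceMatrix) -> pd.Series:
    """Average differentiation of each population with all others."""
    vals = fst_matrix.values.copy()
    np.fill_diagonal(vals, np.nan)
    return pd.Series(np.nanmean(vals, axis=1), index=fst_matrix.labels, name="mean_fst")


def fst_permutation_test(
    genotypes: GenotypeMatrix,
    pop_pair: tuple[str, str],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for pairwise θ.

    Individuals are permuted between the two populations; p is the
    add-one proportion of permuted θ* >= observed θ.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    pops = list(pop_pair)
    la, lp_fixed = _prepare_loci(genotypes, pops)
    # individuals shared across loci: build one label vector per locus is
    # needed because missingness differs; permute at the individual level.
    in_pops = np.isin(genotypes.pops, pops)
    idx = np.nonzero(in_pops)[0]
    pop_index = {p: i for i, p in enumerate(pops)}
    base_labels = np.array([pop_index[p] for p in genotypes.pops[idx]], dtype=np.int64)
    # per-locus positions of each typed individual within idx
    locus_pos = []
    for l in range(genotypes.n_loci):
        typed = genotypes.typed(l)[idx]
        locus_pos.append(np.nonzero(typed)[0])
    try:
        theta_obs, _ = _theta_from_locus_data(la, lp_fixed, 2)
    except ValueError:
        return 1.0
    if all(a.size == 0 or np.all(a == a[0]) for a in la):
        return 1.0  # degenerate: no variation at any locus
    count = 0
    labels = base_labels.copy()
    for _ in range(n_perm):
        rng.shuffle(labels)
        perm_pidx = [labels[pos] for pos in locus_pos]
        try:
            theta_perm, _ = _theta_from_locus_data(la, perm_pidx, 2)
        except ValueError:
            theta_perm = np.inf  # a permutation putting everyone in one pop
        if theta_perm >= theta_obs - 1e-15:
            count += 1
    return (1 + count) / (n_perm + 1)
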