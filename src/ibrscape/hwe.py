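"""Exact Hardy–Weinberg and linkage-disequilibrium tests, Holm correction.

The HWE test is the Markov-chain exact test: given the observed allele
counts, genotype tables are explored by repeatedly swapping gene copies
between two random individuals.  A uniformly random pairing of the gene
copies induces exactly the conditional table distribution under HWE, and
the swap chain leaves that pairing distribution uniform, so states are
sampled from the null without any Metropolis correction.  The p-value is
the proportion of visited tables whose conditional probability does not
exceed the observed table's.
"""

from __future__ import annotations

import math

import numpy as np

from .genotypes import GenotypeMatrix


def _table_logprob_part(counts: np.ndarray, logfact: np.ndarray) -> float:
    """Variable part of the log conditional table probability.

    log P(table | allele counts) = const + H log 2 - sum log n_ij!;
    ``counts`` is upper-triangular (i <= j) genotype counts.
    """
    k = counts.shape[0]
    het = sum(counts[i, j] for i in range(k) for j in range(i + 1, k))
    s = het * math.log(2.0)
    for i in range(k):
        for j in range(i, k):
            s -= logfact[counts[i, j]]
    return s


def hwe_exact_test(
    alleles: np.ndarray,
    n_steps: int = 900_000,
    seed: int | None = None,
    burn_in: int | None = None,
) -> float:
    """Markov-chain exact test of Hardy–Weinberg proportions at one locus.

    Parameters
    ----------
    alleles : (m, 2) array of allele codes for the typed individuals.
    n_steps : chain length after burn-in (one swap proposal per step).
    burn_in : discarded initial steps, default ``n_steps // 10``.

    Returns the add-one proportion of visited tables at least as
    improbable as the observed one.  Monomorphic data give p = 1.
    """
    alleles = np.asarray(alleles)
    if alleles.ndim != 2 or alleles.shape[1] != 2:
        raise ValueError("alleles must have shape (m, 2)")
    if n_steps < 1000:
        raise ValueError("n_steps must be >= 1000")
    codes, compact = np.unique(alleles, return_inverse=True)
    k = len(codes)
    if k < 2:
        return 1.0
    geno = compact.reshape(alleles.shape).astype(np.int64)
    geno.sort(axis=1)
    m = geno.shape[0]
    if burn_in is None:
        burn_in = n_steps // 10
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in geno:
        counts[a, b] += 1
    logfact = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, 2 * m + 2)))))
    log2 = math.log(2.0)

    def cell(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a <= b else (b, a)

    s = _table_logprob_part(counts, logfact)
    s_obs = s
    rng = np.random.default_rng(seed)
    total = burn_in + n_steps
    ind_pairs = rng.integers(0, m, size=(total, 2))
    pos = rng.integers(0, 2, size=(total, 2))
    at_most = 0
    sampled = 0
    g = geno  # local alias for speed
    for t in range(total):
        i, j = ind_pairs[t]
        if i != j:
            pi, pj = pos[t]
            ai, aj = g[i, pi], g[j, pj]
            if ai != aj:
                old_i = cell(g[i, 0], g[i, 1])
                old_j = cell(g[j, 0], g[j, 1])
                ds = 0.0
                for c in (old_i, old_j):
                    ds += logfact[counts[c]] - logfact[counts[c] - 1]
                    if c[0] != c[1]:
                        ds -= log2
                    counts[c] -= 1
                g[i, pi], g[j, pj] = aj, ai
                new_i = cell(g[i, 0], g[i, 1])
                new_j = cell(g[j, 0], g[j, 1])
                for c in (new_i, new_j):
                    counts[c] += 1
                    ds -= logfact[counts[c]] - logfact[counts[c] - 1]
                    if c[0] != c[1]:
                        ds += log2
                s += ds
        if t >= burn_in:
            sampled += 1
            if s <= s_obs + 1e-9:
                at_most += 1
    return (1 + at_most) / (sampled + 1)


def hwe_enumerate_two_alleles(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-allele HWE p-value by full enumeration (oracle).

    Enumerates every genotype table compatible with the observed allele
    counts and sums the conditional probabilities of tables no more
    probable than the observed one.
    """
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    logfact = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, 2 * n + 1)))))

    def logp(nab: int) -> float:
        naa = (na - nab) // 2
        nbb = n - naa - nab
        if naa < 0 or nbb < 0:
            return -np.inf
        return (
            logfact[n]
            + nab * math.log(2.0)
            - logfact[naa]
            - logfact[nab]
            - logfact[nbb]
            + logfact[na]
            + logfact[2 * n - na]
            - logfact[2 * n]
        )

    parity = na % 2
    support = [h for h in range(parity, min(na, 2 * n - na) + 1, 2) if np.isfinite(logp(h))]
    probs = {h: math.exp(logp(h)) for h in support}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def _g_statistic(table: np.ndarray) -> float:
    """Likelihood-ratio (G) statistic of independence on a contingency table."""
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / expected[mask])).sum())


def ld_permutation_test(
    genotypes: GenotypeMatrix,
    locus_pair: tuple[int, int] | tuple[str, str],
    pop: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Permutation test of genotypic linkage disequilibrium in one population.

    The statistic is G on the two-locus genotype contingency table; the
    null distribution is obtained by permuting one locus' genotypes
    across individuals, which breaks any association while preserving
    both single-locus genotype distributions.
    """
    l1, l2 = (
        genotypes.loci.index(l) if isinstance(l, str) else int(l) for l in locus_pair
    )
    mask = genotypes.pop_mask(pop) & genotypes.typed(l1) & genotypes.typed(l2)
    if mask.sum() < 5:
        raise ValueError("need >= 5 individuals typed at both loci")
    g1 = genotypes.alleles[mask, l1, :]
    g2 = genotypes.alleles[mask, l2, :]

    def codes(g: np.ndarray) -> np.ndarray:
        pairs = np.sort(g, axis=1)
        _, inv = np.unique(pairs, axis=0, return_inverse=True)
        return inv

    c1, c2 = codes(g1), codes(g2)
    k1, k2 = c1.max() + 1, c2.max() + 1
    if k1 < 2 or k2 < 2:
        return 1.0
    obs_table = np.zeros((k1, k2))
    np.add.at(obs_table, (c1, c2), 1)
    g_obs = _g_statistic(obs_table)
    rng = np.random.default_rng(seed)
    count = 0
    perm = c2.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        table = np.zeros((k1, k2))
        np.add.at(table, (c1, perm), 1)
        if _g_statistic(table) >= g_obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def sequential_bonferroni(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down correction: rejection flags in the input order.

    Sort ascending and reject while p_(i) <= alpha / (k - i + 1); stop at
    the first failure.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    k = p.size
    reject = np.zeros(k, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (k - rank):
            reject[idx] = True
        else:
            break
    return reject
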