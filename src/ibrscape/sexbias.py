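"""Sex-biased dispersal tests from bi-parentally inherited markers.

The dispersing sex is expected to be less differentiated (lower F_ST),
show a heterozygote deficit relative to local Hardy–Weinberg
expectations (higher F_IS), carry genotypes less typical of its sampling
population (lower mean corrected assignment index, mAIc) and mix
residents with immigrants (higher variance of the index, vAIc).  The
test compares the two sexes on each statistic and obtains significance
by permuting sex labels within populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fst import _locus_components, _locus_arrays
from .genotypes import MISSING, GenotypeMatrix

FREQ_FLOOR = 0.01
STATISTICS = ("fst", "fis", "maic", "vaic")


def assignment_indices(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Corrected assignment index (AIc) per individual.

    AI is the log10 probability of the individual's multilocus genotype
    under Hardy–Weinberg proportions at its own population's
    leave-one-out allele frequencies (2pq for heterozygotes); alleles
    unobserved after leaving the individual out take a floor frequency
    of 0.01.  AIc centres AI within each population, so population
    means of AIc are zero by construction and sexes can be compared
    across populations.
    """
    records = []
    pop_counts: dict[tuple[str, int], dict[int, int]] = {}
    pop_totals: dict[tuple[str, int], int] = {}
    for pop in genotypes.populations:
        for l in range(genotypes.n_loci):
            counts = genotypes.allele_counts(pop, l)
            pop_counts[(pop, l)] = counts
            pop_totals[(pop, l)] = sum(counts.values())
    for i in range(genotypes.n_individuals):
        pop = genotypes.pops[i]
        ai = 0.0
        n_loci_used = 0
        for l in range(genotypes.n_loci):
            a1, a2 = genotypes.alleles[i, l]
            if a1 == MISSING:
                continue
            counts = pop_counts[(pop, l)]
            total = pop_totals[(pop, l)] - 2  # leave this individual out
            if total <= 0:
                continue

            def loo_freq(a: int) -> float:
                own = int(a1 == a) + int(a2 == a)
                c = counts.get(int(a), 0) - own
                return c / total if c > 0 else FREQ_FLOOR

            if a1 == a2:
                prob = loo_freq(a1) ** 2
            else:
                prob = 2 * loo_freq(a1) * loo_freq(a2)
            ai += np.log10(prob)
            n_loci_used += 1
        if n_loci_used == 0:
            raise ValueError(f"individual {genotypes.ids[i]} typed at no locus")
        records.append(
            {
                "id": genotypes.ids[i],
                "pop": pop,
                "sex": genotypes.sexes[i],
                "AI": ai,
            }
        )
    df = pd.DataFrame(records)
    df["AIc"] = df["AI"] - df.groupby("pop")["AI"].transform("mean")
    return df


def _per_sex_f_stats(genotypes: GenotypeMatrix, sexes: np.ndarray) -> dict[str, dict[str, float]]:
    """F_ST and F_IS per sex across populations, given a sex-label vector."""
    out: dict[str, dict[str, float]] = {}
    pops = genotypes.populations
    pop_index = {p: k for k, p in enumerate(pops)}
    for sex in ("M", "F"):
        mask = sexes == sex
        a_sum = b_sum = c_sum = 0.0
        for l in range(genotypes.n_loci):
            m = mask & genotypes.typed(l)
            raw = genotypes.alleles[m, l, :]
            if raw.size == 0:
                continue
            _, compact = np.unique(raw, return_inverse=True)
            pidx = np.array([pop_index[p] for p in genotypes.pops[m]], dtype=np.int64)
            comp = _locus_components(
                *_locus_arrays(compact.reshape(raw.shape), pidx, len(pops))
            )
            if comp is None:
                continue
            a, b, c = comp
            a_sum += a.sum()
            b_sum += b.sum()
            c_sum += c.sum()
        denom = a_sum + b_sum + c_sum
        fst = a_sum / denom if denom != 0 else 0.0
        fis = 1.0 - c_sum / (b_sum + c_sum) if (b_sum + c_sum) != 0 else 0.0
        out[sex] = {"fst": fst, "fis": fis}
    return out


def _sex_stats(
    genotypes: GenotypeMatrix, aic: pd.DataFrame, sexes: np.ndarray
) -> dict[str, dict[str, float]]:
    f = _per_sex_f_stats(genotypes, sexes)
    vals: dict[str, dict[str, float]] = {"M": {}, "F": {}}
    for sex in ("M", "F"):
        sub = aic.loc[np.asarray(sexes) == sex, "AIc"]
        vals[sex]["fst"] = f[sex]["fst"]
        vals[sex]["fis"] = f[sex]["fis"]
        vals[sex]["maic"] = float(sub.mean())
        vals[sex]["vaic"] = float(sub.var(ddof=1))
    return vals


@dataclass
class SexBiasResult:
    """Per-statistic values for each sex and two-sided randomization p."""

    values: pd.DataFrame  # index: statistic; columns: male, female, p
    n_perm: int
    seed: int | None = None
    excluded_pops: list[str] = field(default_factory=list)


def sex_bias_randomization(
    genotypes: GenotypeMatrix, n_perm: int = 10_000, seed: int | None = None
) -> SexBiasResult:
    """Randomization test for sex-biased dispersal.

    Observed per-sex F_ST, F_IS, mAIc and vAIc are compared with their
    null distributions obtained by permuting sex labels within
    populations; p is the two-sided add-one proportion of permuted
    |male − female| differences at least as large as observed.
    Populations containing a single sex are excluded with a warning.
    """
    keep_pops = []
    excluded = []
    for pop in genotypes.populations:
        s = genotypes.sexes[genotypes.pop_mask(pop)]
        if ("M" in s) and ("F" in s):
            keep_pops.append(pop)
        else:
            excluded.append(pop)
    if excluded:
        warnings.warn(f"populations with a single sex excluded: {excluded}")
    if len(keep_pops) < 2:
        raise ValueError("need both sexes present in at least two populations")
    g = genotypes.subset(np.isin(genotypes.pops, keep_pops))
    known = np.isin(g.sexes, ("M", "F"))
    g = g.subset(known)
    aic = assignment_indices(g)
    obs = _sex_stats(g, aic, g.sexes)
    obs_diff = {s: obs["M"][s] - obs["F"][s] for s in STATISTICS}
    rng = np.random.default_rng(seed)
    pop_positions = {pop: np.nonzero(g.pops == pop)[0] for pop in g.populations}
    counts = {s: 0 for s in STATISTICS}
    perm_sexes = np.array(g.sexes, dtype=object)
    for _ in range(n_perm):
        for pos in pop_positions.values():
            perm_sexes[pos] = rng.permutation(perm_sexes[pos])
        perm = _sex_stats(g, aic, perm_sexes)
        for s in STATISTICS:
            if abs(perm["M"][s] - perm["F"][s]) >= abs(obs_diff[s]) - 1e-15:
                counts[s] += 1
    rows = []
    for s in STATISTICS:
        rows.append(
            {
                "statistic": s,
                "male": obs["M"][s],
                "female": obs["F"][s],
                "p": (1 + counts[s]) / (n_perm + 1),
            }
        )
    values = pd.DataFrame(rows).set_index("statistic")
    return SexBiasResult(values, n_perm, seed, excluded)
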