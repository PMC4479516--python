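import numpy as np
import pytest

from ibrscape.genotypes import GenotypeMatrix
from ibrscape.raster import ResistanceSurface


def genotypes_from_freqs(
    freqs_per_pop: dict[str, np.ndarray],
    n_per_pop: int,
    n_loci: int = 1,
    rng: np.random.Generator | None = None,
    sexes: bool = False,
) -> GenotypeMatrix:
    """Draw HWE genotypes for each population from given allele frequencies.

    ``freqs_per_pop`` maps pop id -> (n_loci, n_alleles) or (n_alleles,)
    frequency array.
    """
    rng = rng or np.random.default_rng(0)
    pops, rows, sex = [], [], []
    for pop, f in freqs_per_pop.items():
        f = np.atleast_2d(f)
        if f.shape[0] == 1 and n_loci > 1:
            f = np.repeat(f, n_loci, axis=0)
        for i in range(n_per_pop):
            geno = [
                rng.choice(f.shape[1], size=2, p=f[l]) + 1 for l in range(f.shape[0])
            ]
            rows.append(geno)
            pops.append(pop)
            sex.append("M" if (sexes and i % 2 == 0) else "F" if sexes else "U")
    return GenotypeMatrix(
        np.array(rows),
        np.array(pops, dtype=object),
        [f"L{l + 1}" for l in range(len(rows[0]))],
        np.array(sex, dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def uniform_3x3():
    return ResistanceSurface(np.ones((3, 3)), cellsize=1.0)


def random_surface(rng: np.random.Generator, nrows: int, ncols: int) -> ResistanceSurface:
    """A random positive resistance surface (log-uniform over ~2 decades)."""
    res = np.exp(rng.uniform(np.log(0.5), np.log(50.0), size=(nrows, ncols)))
    return ResistanceSurface(res, cellsize=1.0)
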