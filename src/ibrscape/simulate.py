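"""Synthetic landscapes and genotypes structured by effective resistance.

The generator emulates the sampling design of a fragmented Mediterranean
agricultural landscape: an agricultural background dotted with patches
of natural vegetation, one sampled population per patch, and diploid
multilocus microsatellite genotypes whose pairwise differentiation
increases with the effective resistance separating the patches.

Genotypes come from a forward-time finite-island model on allele
frequencies: per locus, ancestral frequencies are Dirichlet(1); each
generation every deme's gene pool is a migration-weighted mixture of all
pools with weight exp(−R_ij/λ) (rows normalized, self-weight floored at
0.5), followed by multinomial drift at size N_e.  Sampled genotypes are
drawn under local Hardy–Weinberg proportions, after which null alleles
and missing data are injected: each gene copy independently fails to
amplify with the locus' null-allele frequency, a visible/null pair is
scored as a visible homozygote and a null/null pair as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix
from .genotypes import GenotypeMatrix
from .raster import AGRICULTURAL, NATURAL, HabitatRaster
from .sites import EARTH_RADIUS_M, PopulationSite

_REF_LAT = 39.7
_REF_LON = -3.2


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the emulated sampling design: 18 populations of ~20
    individuals genotyped at 10 usable microsatellite loci, on a patchy
    two-class landscape, with the true scenario giving agricultural land
    1000 times the resistance of natural vegetation.
    """

    nrows: int = 100
    ncols: int = 100
    cellsize: float = 250.0
    n_patches: int = 24
    patch_radius: int = 4  # cells
    n_pops: int = 18
    n_individuals: int = 20
    sex_ratio: float = 0.5  # expected fraction male
    n_loci: int = 10
    n_alleles: int = 8
    natural_resistance: float = 1.0
    agricultural_resistance: float = 1000.0
    migration_scale: float | None = None  # lambda; None = P90(R)/10
    deme_size: int = 100  # N_e
    generations: int = 200
    null_allele_freq: float | list[float] = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nrows, self.ncols, self.n_patches + 1, self.n_pops,
               self.n_individuals, self.n_loci, self.n_alleles,
               self.deme_size, self.generations) < 1:
            raise ValueError("all counts must be >= 1")
        for rate in np.atleast_1d(self.null_allele_freq).tolist() + [
            self.missing_rate, self.sex_ratio
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def generate_landscape(
    config: SimulationConfig,
) -> tuple[HabitatRaster, list[PopulationSite]]:
    """A patchy two-class raster with one population site per sampled patch.

    The background is agricultural; ``n_patches`` random discs of
    natural vegetation are stamped in, and sites are placed at the
    centres of ``n_pops`` distinct patches.  Deterministic under the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    classes = np.full((config.nrows, config.ncols), AGRICULTURAL, dtype=int)
    margin = config.patch_radius
    if config.nrows <= 2 * margin or config.ncols <= 2 * margin:
        raise ValueError("patches do not fit in the grid")
    centres = []
    rr, cc = np.mgrid[0 : config.nrows, 0 : config.ncols]
    for _ in range(config.n_patches):
        r = int(rng.integers(margin, config.nrows - margin))
        c = int(rng.integers(margin, config.ncols - margin))
        centres.append((r, c))
        classes[(rr - r) ** 2 + (cc - c) ** 2 <= config.patch_radius**2] = NATURAL
    raster = HabitatRaster(classes, config.cellsize)
    if config.n_pops > len(centres):
        raise ValueError(
            f"cannot place {config.n_pops} sites in {len(centres)} patches"
        )
    # keep patches whose centres are far enough apart to map to distinct cells
    chosen: list[tuple[int, int]] = []
    for idx in rng.permutation(len(centres)):
        cand = centres[idx]
        if cand not in chosen:
            chosen.append(cand)
        if len(chosen) == config.n_pops:
            break
    if len(chosen) < config.n_pops:
        raise ValueError("could not place sites in distinct patches")
    sites = []
    gen_xy = []
    for i, (r, c) in enumerate(chosen):
        x = raster.xll + (c + 0.5) * config.cellsize
        y = raster.yll + (config.nrows - 1 - r + 0.5) * config.cellsize
        gen_xy.append((x, y))
        lat = _REF_LAT + np.degrees(y / EARTH_RADIUS_M)
        lon = _REF_LON + np.degrees(
            x / (EARTH_RADIUS_M * np.cos(np.radians(_REF_LAT)))
        )
        n_male = int(np.round(config.n_individuals * config.sex_ratio))
        sites.append(
            PopulationSite(
                id=f"P{i + 1:02d}",
                latitude=float(lat),
                longitude=float(lon),
                n_total=config.n_individuals,
                n_male=n_male,
                n_female=config.n_individuals - n_male,
            )
        )
    # align the raster frame with the (site-mean-centred) projection so
    # projected site coordinates land on their generating cells
    from .sites import project_coordinates

    proj = project_coordinates(sites)
    gen = np.array(gen_xy)
    raster.xll += float((proj["x"].to_numpy() - gen[:, 0]).mean())
    raster.yll += float((proj["y"].to_numpy() - gen[:, 1]).mean())
    return raster, sites


def migration_matrix(
    resistance: np.ndarray, scale: float, self_weight_floor: float = 0.5
) -> np.ndarray:
    """Row-stochastic migration weights m_ij ∝ exp(−R_ij/λ).

    Rows are normalized and the self-weight floored at
    ``self_weight_floor`` (off-diagonal weights rescaled), keeping demes
    well-defined at small λ.
    """
    if not np.isfinite(resistance).all():
        raise ValueError("resistance entries must be finite")
    w = np.exp(-resistance / scale)
    m = w / w.sum(axis=1, keepdims=True)
    for i in range(m.shape[0]):
        if m[i, i] < self_weight_floor:
            off = 1.0 - m[i, i]
            m[i, :] *= (1.0 - self_weight_floor) / off
            m[i, i] = self_weight_floor
    return m


def simulate_genotypes(
    resistance_matrix: DistanceMatrix,
    config: SimulationConfig,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Forward-time island-model genotypes structured by resistance.

    With null-allele frequency 0 and missing rate 0 the observed
    genotypes equal the true ones.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    r = resistance_matrix.values
    n_pops = r.shape[0]
    scale = config.migration_scale
    if scale is None:
        # default: migration common between the closest patches, rare
        # (~e^-9) across the 90th-percentile resistance
        off = r[np.triu_indices(n_pops, k=1)]
        scale = float(np.percentile(off, 90)) / 10.0 if off.size else 1.0
    if scale <= 0:
        raise ValueError("migration scale must be positive")
    m = migration_matrix(r, scale)
    two_ne = 2 * config.deme_size
    # allele frequencies: (n_pops, n_loci, n_alleles)
    ancestral = rng.dirichlet(np.ones(config.n_alleles), size=config.n_loci)
    freqs = np.broadcast_to(ancestral, (n_pops,) + ancestral.shape).copy()
    for _ in range(config.generations):
        mixed = np.einsum("ij,jla->ila", m, freqs)
        np.clip(mixed, 0.0, None, out=mixed)
        mixed /= mixed.sum(axis=2, keepdims=True)
        for i in range(n_pops):
            for l in range(config.n_loci):
                freqs[i, l] = rng.multinomial(two_ne, mixed[i, l]) / two_ne
    null_freqs = np.atleast_1d(np.asarray(config.null_allele_freq, dtype=float))
    if null_freqs.size == 1:
        null_freqs = np.repeat(null_freqs, config.n_loci)
    if null_freqs.size != config.n_loci:
        raise ValueError("null_allele_freq must be scalar or one value per locus")
    n_ind = n_pops * config.n_individuals
    alleles = np.zeros((n_ind, config.n_loci, 2), dtype=np.int64)
    pops = np.empty(n_ind, dtype=object)
    sexes = np.empty(n_ind, dtype=object)
    labels = list(resistance_matrix.labels)
    row = 0
    for i, pop in enumerate(labels):
        n_male = int(np.round(config.n_individuals * config.sex_ratio))
        for j in range(config.n_individuals):
            pops[row] = pop
            sexes[row] = "M" if j < n_male else "F"
            for l in range(config.n_loci):
                pair = rng.choice(config.n_alleles, size=2, p=freqs[i, l]) + 1
                is_null = rng.random(2) < null_freqs[l]
                if is_null.all():
                    pair = np.array([0, 0])
                elif is_null[0]:
                    pair = np.array([pair[1], pair[1]])
                elif is_null[1]:
                    pair = np.array([pair[0], pair[0]])
                if config.missing_rate and rng.random() < config.missing_rate:
                    pair = np.array([0, 0])
                alleles[row, l] = pair
            row += 1
    # guard: an individual missing everywhere is re-typed at one random locus
    wholly_missing = (alleles != 0).sum(axis=(1, 2)) == 0
    for idx in np.nonzero(wholly_missing)[0]:
        i = labels.index(pops[idx])
        l = int(rng.integers(config.n_loci))
        alleles[idx, l] = rng.choice(config.n_alleles, size=2, p=freqs[i, l]) + 1
    return GenotypeMatrix(alleles, pops, [f"L{l + 1}" for l in range(config.n_loci)], sexes)
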