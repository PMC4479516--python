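"""Diploid multilocus genotypes with population and sex labels.

The in-memory container is a (n_individuals, n_loci, 2) integer array of
allele codes with 0 marking a missing gene copy; genotypes are unordered
pairs.  Populations keep file order.  Reading and writing covers the
Genepop dialect (title line, locus names, POP blocks, 2- or 3-digit
alleles with 00/000 as missing) and a tidy long CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = 0
SEXES = ("M", "F", "U")


@dataclass
class GenotypeMatrix:
    """Individuals × loci diploid genotypes.

    ``alleles[i, l]`` holds the two (unordered) allele codes of
    individual ``i`` at locus ``l``; positive integers, with 0 for a
    missing copy (a genotype is missing iff both copies are 0).
    """

    alleles: np.ndarray
    pops: np.ndarray  # population id per individual
    loci: list[str]
    sexes: np.ndarray | None = None
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        self.pops = np.asarray(self.pops, dtype=object)
        if len(self.pops) != self.alleles.shape[0]:
            raise ValueError("pops length must match individuals")
        if len(self.loci) != self.alleles.shape[1]:
            raise ValueError("loci length must match allele array")
        if (self.alleles < 0).any():
            raise ValueError("allele codes must be nonnegative (0 = missing)")
        half_missing = (self.alleles == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("genotypes must be fully typed or fully missing")
        if self.sexes is None:
            self.sexes = np.array(["U"] * self.n_individuals, dtype=object)
        else:
            self.sexes = np.asarray(self.sexes, dtype=object)
            if not np.isin(self.sexes, SEXES).all():
                raise ValueError("sexes must be 'M', 'F' or 'U'")
        if self.ids is None:
            self.ids = [f"ind{i}" for i in range(self.n_individuals)]
        typed_any = (self.alleles != MISSING).any(axis=(1, 2))
        if not typed_any.all():
            raise ValueError("individuals typed at no locus are not allowed")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population ids in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p, None)
        return list(seen)

    def pop_mask(self, pop: str) -> np.ndarray:
        return self.pops == pop

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.alleles[mask],
            self.pops[mask],
            list(self.loci),
            self.sexes[mask],
            [self.ids[i] for i in np.nonzero(mask)[0]],
        )

    def typed(self, locus: int) -> np.ndarray:
        """Boolean mask of individuals typed at locus index ``locus``."""
        return self.alleles[:, locus, 0] != MISSING

    def allele_counts(self, pop: str, locus: int) -> dict[int, int]:
        """Gene-copy counts per allele for one population × locus."""
        mask = self.pop_mask(pop) & self.typed(locus)
        flat = self.alleles[mask, locus, :].ravel()
        alleles, counts = np.unique(flat, return_counts=True)
        return dict(zip(alleles.tolist(), counts.tolist()))


def read_genepop(path) -> GenotypeMatrix:
    """Read genotypes in the Genepop dialect.

    Populations are labelled ``pop1``, ``pop2``, … in file order unless
    individual names before the comma look like shared population codes,
    in which case the last individual's name of each POP block is used
    (the common Genepop convention).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty Genepop file")
    # locus names: either one per line or comma-separated on one line
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        loci.extend(chunk)
        i += 1
    if not loci:
        raise ValueError("no locus names found")
    blocks: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    width: int | None = None
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            if current is not None:
                blocks.append(current)
            current = []
            continue
        if current is None:
            raise ValueError(f"line {lineno + 1}: genotype data before first POP")
        if "," not in line:
            raise ValueError(f"line {lineno + 1}: missing comma after individual name")
        name, geno = line.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise ValueError(
                f"line {lineno + 1}: expected {len(loci)} genotypes, got {len(fields)}"
            )
        for f in fields:
            if len(f) not in (4, 6):
                raise ValueError(
                    f"line {lineno + 1}: genotype field {f!r} is not 4 or 6 digits"
                )
            w = len(f) // 2
            if width is None:
                width = w
            elif w != width:
                raise ValueError(f"line {lineno + 1}: inconsistent allele-code width")
        current.append((name.strip(), fields))
    if current is not None:
        blocks.append(current)
    if not blocks:
        raise ValueError("no POP blocks found")
    assert width is not None
    n_ind = sum(len(b) for b in blocks)
    alleles = np.zeros((n_ind, len(loci), 2), dtype=np.int64)
    pops: list[str] = []
    ids: list[str] = []
    row = 0
    for b_i, block in enumerate(blocks):
        pop_name = f"pop{b_i + 1}"
        last = block[-1][0]
        if all(ind[0] == last for ind in block) or last.isalpha():
            pop_name = last
        for name, fields in block:
            for l_i, f in enumerate(fields):
                a1, a2 = int(f[:width]), int(f[width:])
                if (a1 == 0) != (a2 == 0):
                    a1 = a2 = 0  # half-missing treated as missing
                alleles[row, l_i] = (a1, a2)
            pops.append(pop_name)
            ids.append(name)
            row += 1
    return GenotypeMatrix(alleles, np.array(pops, dtype=object), loci, ids=ids)


def write_genepop(g: GenotypeMatrix, path, title: str = "ibrscape export") -> None:
    """Write genotypes in the Genepop dialect (3-digit allele codes)."""
    if (g.alleles > 999).any():
        raise ValueError("allele codes above 999 cannot be written as Genepop")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in g.loci:
            fh.write(locus + "\n")
        for pop in g.populations:
            fh.write("pop\n")
            for i in np.nonzero(g.pop_mask(pop))[0]:
                codes = " ".join(
                    f"{g.alleles[i, l, 0]:03d}{g.alleles[i, l, 1]:03d}"
                    for l in range(g.n_loci)
                )
                fh.write(f"{pop}, {codes}\n")


def read_long_csv(path) -> GenotypeMatrix:
    """Read tidy long-format genotypes.

    Columns: ``individual, pop, sex, locus, allele1, allele2`` (0 =
    missing copy).
    """
    df = pd.read_csv(path)
    required = {"individual", "pop", "sex", "locus", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise ValueError(f"long CSV must have columns {sorted(required)}")
    loci = list(pd.unique(df["locus"].astype(str)))
    inds = list(pd.unique(df["individual"].astype(str)))
    ind_index = {v: k for k, v in enumerate(inds)}
    loc_index = {v: k for k, v in enumerate(loci)}
    alleles = np.zeros((len(inds), len(loci), 2), dtype=np.int64)
    pops = np.empty(len(inds), dtype=object)
    sexes = np.full(len(inds), "U", dtype=object)
    for r in df.itertuples():
        i = ind_index[str(r.individual)]
        l = loc_index[str(r.locus)]
        alleles[i, l] = (int(r.allele1), int(r.allele2))
        pops[i] = str(r.pop)
        sexes[i] = str(r.sex) if str(r.sex) in SEXES else "U"
    return GenotypeMatrix(alleles, pops, loci, sexes, ids=inds)
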