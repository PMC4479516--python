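"""Isolation-by-resistance scenario scan and the R² ratio profile.

A family of two-class resistance scenarios — each a (natural,
agricultural) resistance pair, characterized by its agricultural:natural
ratio — is evaluated by computing effective-resistance matrices between
the sampled populations and regressing genetic differentiation on each
(single-predictor MMRR), alongside two null baselines: Euclidean
distance (isolation by distance) and a flat landscape of uniform
resistance.  Because effective resistance scales linearly with cell
resistance and MMRR standardizes its inputs, only the ratio shapes the
fit; the scan caches one Laplacian solve per distinct ratio and rescales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import resistance_matrix
from .distance import DistanceMatrix, euclidean_matrix
from .mmrr import MMRRResult, mmrr_fit
from .raster import HabitatRaster, build_resistance_surface, uniform_surface
from .sites import project_coordinates


@dataclass(frozen=True)
class IBRScenario:
    """A (natural, agricultural) resistance pair."""

    name: str
    natural: float
    agricultural: float

    def __post_init__(self) -> None:
        if self.natural <= 0 or self.agricultural <= 0:
            raise ValueError("scenario resistances must be > 0")

    @property
    def ratio(self) -> float:
        return self.agricultural / self.natural


_DEFAULT_PAIRS = [
    ("IBR-A", 1, 1),
    ("IBR-B", 100, 1),
    ("IBR-C", 50, 1),
    ("IBR-D", 25, 1),
    ("IBR-E", 100, 25),
    ("IBR-F", 100, 50),
    ("IBR-G", 50, 25),
    ("IBR-H", 50, 100),
    ("IBR-I", 25, 50),
    ("IBR-J", 25, 100),
    ("IBR-K", 1, 25),
    ("IBR-L", 1, 50),
    ("IBR-M", 1, 100),
    ("IBR-N", 1, 500),
    ("IBR-O", 1, 1000),
    ("IBR-P", 1, 2000),
    ("IBR-Q", 1, 5000),
    ("IBR-R", 1, 10_000),
    ("IBR-S", 1, 20_000),
    ("IBR-T", 1, 50_000),
    ("IBR-U", 1, 100_000),
]


def default_scenarios() -> list[IBRScenario]:
    """The 21 standard resistance scenarios, ratios 0.01 through 100 000."""
    return [IBRScenario(n, float(a), float(b)) for n, a, b in _DEFAULT_PAIRS]


@dataclass
class ScanResult:
    """Per-scenario MMRR fits plus the IBD and flat-landscape baselines."""

    table: pd.DataFrame
    fits: dict[tuple[str, str], MMRRResult] = field(default_factory=dict)
    resistance_matrices: dict[str, DistanceMatrix] = field(default_factory=dict)


_MATRIX_CACHE: dict[tuple, DistanceMatrix] = {}
_MATRIX_CACHE_MAX = 64


def _cache_key(raster: HabitatRaster, sites_xy: pd.DataFrame, ratio: float, connectivity: int):
    import hashlib

    h = hashlib.sha1()
    h.update(raster.classes.tobytes())
    h.update(np.asarray([raster.cellsize, raster.xll, raster.yll]).tobytes())
    h.update(sites_xy[["x", "y"]].to_numpy().tobytes())
    return (h.hexdigest(), float(ratio), connectivity)


def _scenario_matrices(
    raster: HabitatRaster,
    sites_xy: pd.DataFrame,
    scenarios: list[IBRScenario],
    connectivity: int,
) -> dict[str, DistanceMatrix]:
    """One resistance matrix per scenario, solving each distinct ratio once.

    A scenario (c·n, c·a) has matrix c times the matrix of (n, a), so
    matrices are computed for (1, ratio) surfaces and rescaled; solved
    ratios are cached keyed on (raster, sites, ratio) so repeated scans
    of one landscape do not refactorize the Laplacian.
    """
    out: dict[str, DistanceMatrix] = {}
    for sc in scenarios:
        ratio = sc.ratio
        key = _cache_key(raster, sites_xy, ratio, connectivity)
        if key not in _MATRIX_CACHE:
            if len(_MATRIX_CACHE) >= _MATRIX_CACHE_MAX:
                _MATRIX_CACHE.pop(next(iter(_MATRIX_CACHE)))
            surface = build_resistance_surface(
                raster, IBRScenario("unit", 1.0, ratio)
            )
            _MATRIX_CACHE[key] = resistance_matrix(
                surface, sites_xy, connectivity=connectivity
            )
        base = _MATRIX_CACHE[key]
        out[sc.name] = DistanceMatrix(
            base.labels, base.values * sc.natural, kind="resistance"
        )
    return out


def run_scan(
    raster: HabitatRaster,
    sites,
    fst_matrix: DistanceMatrix,
    fst_ena_matrix: DistanceMatrix | None = None,
    scenarios: list[IBRScenario] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    connectivity: int = 8,
) -> ScanResult:
    """Evaluate every scenario plus the IBD and flat baselines by MMRR.

    ``sites`` is either a projected xy DataFrame or a PopulationSite
    list.  Each genetic matrix (uncorrected and, if given, null-allele
    corrected θ) is regressed alone on each predictor matrix.
    """
    if scenarios is None:
        scenarios = default_scenarios()
    if isinstance(sites, pd.DataFrame):
        sites_xy = sites
    else:
        sites_xy = project_coordinates(sites)
    responses = {"fst": fst_matrix}
    if fst_ena_matrix is not None:
        responses["fst_ena"] = fst_ena_matrix
    matrices = _scenario_matrices(raster, sites_xy, scenarios, connectivity)
    # baselines: Euclidean and a uniform surface on the same grid
    euclid = euclidean_matrix(sites_xy)
    flat_surface = uniform_surface(
        raster.nrows, raster.ncols, raster.cellsize, raster.xll, raster.yll
    )
    flat = resistance_matrix(
        flat_surface, sites_xy, connectivity=connectivity, kind="flat_resistance"
    )
    rows = []
    fits: dict[tuple[str, str], MMRRResult] = {}
    ratios = {sc.name: sc.ratio for sc in scenarios}
    naturals = {sc.name: sc.natural for sc in scenarios}
    agris = {sc.name: sc.agricultural for sc in scenarios}
    models = [("IBD", euclid), ("FLAT", flat)] + [
        (sc.name, matrices[sc.name]) for sc in scenarios
    ]
    rng = np.random.default_rng(seed)
    for model_name, predictor in models:
        row = {
            "model": model_name,
            "natural": naturals.get(model_name, np.nan),
            "agricultural": agris.get(model_name, np.nan),
            "ratio": ratios.get(model_name, np.nan),
        }
        for resp_name, resp in responses.items():
            fit = mmrr_fit(
                resp,
                [predictor],
                n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
                names=[model_name],
            )
            fits[(model_name, resp_name)] = fit
            row[f"{resp_name}_r2"] = fit.r_squared
            row[f"{resp_name}_beta"] = fit.coefficients[model_name]
            row[f"{resp_name}_t"] = fit.tstats[model_name]
            row[f"{resp_name}_p"] = fit.pvalues[model_name]
        rows.append(row)
    table = pd.DataFrame(rows)
    matrices["FLAT"] = flat
    matrices["IBD"] = euclid
    return ScanResult(table, fits, matrices)


def r2_profile(
    scan: ScanResult,
    response: str = "fst",
    tol: float = 0.005,
) -> tuple[pd.DataFrame, float]:
    """R² against ratio on the natural = 1 arm, with the stabilization ratio.

    The stabilization ratio is the smallest ratio whose R² is within
    ``tol`` of the maximum over that ratio and all larger ones.
    """
    col = f"{response}_r2"
    arm = scan.table[(scan.table["natural"] == 1)].sort_values("ratio")
    if len(arm) < 3:
        raise ValueError("need at least 3 scenarios with natural = 1")
    profile = arm[["model", "ratio", col]].rename(columns={col: "r2"}).reset_index(
        drop=True
    )
    r2 = profile["r2"].to_numpy()
    suffix_max = np.maximum.accumulate(r2[::-1])[::-1]
    stable_idx = int(np.nonzero(r2 >= suffix_max - tol)[0][0])
    return profile, float(profile["ratio"].iloc[stable_idx])
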