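"""Two-class habitat rasters and resistance surfaces.

The landscape model is deliberately minimal: a georeferenced grid whose
cells are either natural (semi-natural vegetation suitable for the focal
species), agricultural (cultivated or otherwise unsuitable matrix), or
nodata.  Resistance surfaces are produced by substituting one positive
resistance value per habitat class, so the agricultural:natural resistance
*ratio* is the only shape parameter of an isolation-by-resistance scenario.

Grids are read and written in the ESRI ASCII grid dialect
(``ncols``/``nrows``/``xllcorner``/``yllcorner``/``cellsize``/
``NODATA_value`` header followed by row-major values, top row first).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .scan import IBRScenario

# internal class codes
NATURAL = 1
AGRICULTURAL = 2
NODATA = -1

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


class GridFormatError(ValueError):
    """Raised for malformed ASCII grid files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class HabitatRaster:
    """Gridded habitat classes with georeferencing.

    ``classes[r, c]`` holds :data:`NATURAL`, :data:`AGRICULTURAL` or
    :data:`NODATA`; row 0 is the *top* row of the map, matching the file
    layout.  ``xll``/``yll`` locate the lower-left corner in projected
    metres and ``cellsize`` is the cell edge length in metres.
    """

    classes: np.ndarray
    cellsize: float
    xll: float = 0.0
    yll: float = 0.0
    nodata_value: int = -9999

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise ValueError("classes must be a 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        bad = ~np.isin(self.classes, (NATURAL, AGRICULTURAL, NODATA))
        if bad.any():
            raise ValueError(f"unknown class codes: {np.unique(self.classes[bad])}")

    @property
    def nrows(self) -> int:
        return self.classes.shape[0]

    @property
    def ncols(self) -> int:
        return self.classes.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) of every cell centre, each shaped (nrows, ncols)."""
        c = np.arange(self.ncols)
        r = np.arange(self.nrows)
        x = self.xll + (c + 0.5) * self.cellsize
        y = self.yll + (self.nrows - 1 - r + 0.5) * self.cellsize
        return np.broadcast_to(x, (self.nrows, self.ncols)).copy(), np.broadcast_to(
            y[:, None], (self.nrows, self.ncols)
        ).copy()

    def nearest_cell(self, x: float, y: float) -> tuple[int, int]:
        """Nearest cell (row, col) to a planar point; ties break by (row, col)."""
        c = int(np.clip(np.floor((x - self.xll) / self.cellsize), 0, self.ncols - 1))
        r_from_bottom = int(
            np.clip(np.floor((y - self.yll) / self.cellsize), 0, self.nrows - 1)
        )
        return self.nrows - 1 - r_from_bottom, c


@dataclass
class ResistanceSurface:
    """Per-cell resistance on the same grid as a :class:`HabitatRaster`.

    All non-nodata cells carry a strictly positive, dimensionless
    resistance; nodata cells are NaN.
    """

    resistance: np.ndarray
    cellsize: float
    xll: float = 0.0
    yll: float = 0.0
    scenario: "IBRScenario | None" = field(default=None)

    def __post_init__(self) -> None:
        self.resistance = np.asarray(self.resistance, dtype=float)
        if self.resistance.ndim != 2:
            raise ValueError("resistance must be a 2-D array")
        finite = np.isfinite(self.resistance)
        if (self.resistance[finite] <= 0).any():
            raise ValueError("all non-nodata resistances must be > 0")

    @property
    def nrows(self) -> int:
        return self.resistance.shape[0]

    @property
    def ncols(self) -> int:
        return self.resistance.shape[1]

    def nearest_cell(self, x: float, y: float) -> tuple[int, int]:
        proxy = HabitatRaster(
            np.full_like(self.resistance, NATURAL, dtype=int),
            self.cellsize,
            self.xll,
            self.yll,
        )
        return proxy.nearest_cell(x, y)


def read_ascii_grid(
    path,
    class_codes: dict[int, int] | None = None,
) -> HabitatRaster:
    """Read a two-class habitat grid from an ESRI ASCII file.

    Parameters
    ----------
    path : str or path-like
    class_codes : mapping of file integer code -> habitat class, default
        ``{1: NATURAL, 2: AGRICULTURAL}``.  The file's declared
        ``NODATA_value`` always maps to :data:`NODATA`.
    """
    if class_codes is None:
        class_codes = {1: NATURAL, 2: AGRICULTURAL}
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: dict[str, float] = {}
    nodata_value = -9999
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            key = parts[0].lower()
            try:
                val = float(parts[1])
            except ValueError:
                raise GridFormatError(f"bad header value for {key!r}", line=i + 1)
            if key == "nodata_value":
                nodata_value = int(val)
            else:
                header[key] = val
            i += 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"missing header keys: {missing}", line=i + 1)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    rows = []
    for r in range(nrows):
        if i + r >= len(lines):
            raise GridFormatError("unexpected end of file", line=len(lines))
        parts = lines[i + r].split()
        if len(parts) != ncols:
            raise GridFormatError(
                f"expected {ncols} values, got {len(parts)}", line=i + r + 1
            )
        try:
            rows.append([int(float(v)) for v in parts])
        except ValueError:
            raise GridFormatError("non-numeric cell value", line=i + r + 1)
    raw = np.array(rows, dtype=int)
    classes = np.full_like(raw, NODATA)
    known = raw == nodata_value
    for code, cls in class_codes.items():
        mask = raw == code
        classes[mask] = cls
        known |= mask
    if not known.all():
        r, c = np.argwhere(~known)[0]
        raise GridFormatError(
            f"unknown class code {raw[r, c]}", line=i + int(r) + 1
        )
    return HabitatRaster(
        classes,
        cellsize=header["cellsize"],
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        nodata_value=nodata_value,
    )


def write_ascii_grid(
    raster: HabitatRaster, path, class_codes: dict[int, int] | None = None
) -> None:
    """Write a habitat grid in the ESRI ASCII dialect (inverse of the reader)."""
    if class_codes is None:
        class_codes = {1: NATURAL, 2: AGRICULTURAL}
    inverse = {cls: code for code, cls in class_codes.items()}
    inverse[NODATA] = raster.nodata_value
    out = np.vectorize(inverse.__getitem__)(raster.classes)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:.6f}\n")
        fh.write(f"yllcorner {raster.yll:.6f}\n")
        fh.write(f"cellsize {raster.cellsize:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata_value}\n")
        for row in out:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def build_resistance_surface(
    raster: HabitatRaster, scenario: "IBRScenario"
) -> ResistanceSurface:
    """Substitute per-class resistances into the grid.

    Natural cells get ``scenario.natural``, agricultural cells
    ``scenario.agricultural``; nodata cells become NaN.
    """
    if scenario.natural <= 0 or scenario.agricultural <= 0:
        raise ValueError("scenario resistances must be > 0")
    res = np.full(raster.classes.shape, np.nan)
    res[raster.classes == NATURAL] = scenario.natural
    res[raster.classes == AGRICULTURAL] = scenario.agricultural
    return ResistanceSurface(
        res, raster.cellsize, raster.xll, raster.yll, scenario=scenario
    )


def uniform_surface(
    nrows: int,
    ncols: int,
    cellsize: float,
    xll: float = 0.0,
    yll: float = 0.0,
    resistance: float = 1.0,
) -> ResistanceSurface:
    """A flat landscape in which every cell has the same resistance."""
    return ResistanceSurface(
        np.full((nrows, ncols), float(resistance)), cellsize, xll, yll
    )


def habitat_proportion(
    raster: HabitatRaster, site_xy: tuple[float, float], radius: float
) -> float:
    """Fraction of habitat cells within ``radius`` of a site that are natural.

    Membership is by cell centre: a cell counts if its centre lies within
    the disc.  Nodata cells are excluded from the denominator.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    x0, y0 = site_xy
    xs, ys = raster.cell_centers()
    inside = (xs - x0) ** 2 + (ys - y0) ** 2 <= radius**2
    inside &= raster.classes != NODATA
    n = int(inside.sum())
    if n == 0:
        raise ValueError("disc contains no usable cells (outside raster or all nodata)")
    return float((raster.classes[inside] == NATURAL).sum() / n)
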