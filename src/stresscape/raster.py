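"""Grid rasters and co-registered covariate stacks.

All surfaces in the pipeline live on axis-aligned, cell-centre-registered
grids in a projected metric coordinate system. ``GridRaster`` is the shared
container; ``CovariateStack`` holds a set of co-registered, named rasters
with a kind tag (continuous / categorical / ordinal) per layer.

Rasters are stored row-major with row 0 at the northern edge, matching the
ESRI ASCII grid (.asc) layout used for on-disk interchange.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

NODATA_DEFAULT = -9999.0

VALID_KINDS = frozenset({"continuous", "categorical", "ordinal"})


class ConfigurationError(ValueError):
    """Invalid configuration (extent, cell size, densities, model refs)."""


class GeometryError(ValueError):
    """Geometry problem: CRS/extent mismatch or invalid feature."""


class CoRegistrationError(ValueError):
    """Rasters do not share shape, origin, or cell size."""


@dataclass
class GridRaster:
    """A single-band raster on a 1-km-style metric grid.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values, row 0 northmost. Float or integer codes.
    x_origin, y_origin : float
        West edge and north edge of the grid, metres.
    cell_size : float
        Cell edge length, metres.
    nodata : float
        Sentinel for missing cells.
    name : str
        Variable label.
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    nodata: float = NODATA_DEFAULT
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ConfigurationError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid extent."""
        return (
            self.x_origin,
            self.y_origin - self.nrows * self.cell_size,
            self.x_origin + self.ncols * self.cell_size,
            self.y_origin,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (nrows, ncols) of x and y cell-centre coordinates."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def center_points(self) -> np.ndarray:
        """Flat (n_cells, 2) array of cell-centre coordinates."""
        gx, gy = self.cell_centers()
        return np.column_stack([gx.ravel(), gy.ravel()])

    def rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (x, y)."""
        col = np.floor((np.asarray(x) - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Raster values at point locations (containing-cell lookup)."""
        row, col = self.rowcol(x, y)
        inside = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        if not np.all(inside):
            raise GeometryError("sample point outside raster extent")
        return self.values[row, col]

    # -- bookkeeping ------------------------------------------------------
    def valid_mask(self) -> np.ndarray:
        vals = self.values.astype(float)
        return ~np.isclose(vals, self.nodata) & np.isfinite(vals)

    def like(self, values: np.ndarray, name: str = "") -> "GridRaster":
        """New raster on this grid with the given values."""
        return GridRaster(
            values=np.asarray(values),
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            cell_size=self.cell_size,
            nodata=self.nodata,
            name=name or self.name,
        )

    def co_registered(self, other: "GridRaster", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x_origin - other.x_origin) < tol
            and abs(self.y_origin - other.y_origin) < tol
            and abs(self.cell_size - other.cell_size) < tol
        )

    # -- I/O: ESRI ASCII grid --------------------------------------------
    def to_ascii(self, path: str | Path) -> None:
        xmin, ymin, _, _ = self.bounds
        buf = io.StringIO()
        buf.write(f"ncols {self.ncols}\n")
        buf.write(f"nrows {self.nrows}\n")
        buf.write(f"xllcorner {xmin:.6f}\n")
        buf.write(f"yllcorner {ymin:.6f}\n")
        buf.write(f"cellsize {self.cell_size:.6f}\n")
        buf.write(f"NODATA_value {self.nodata:g}\n")
        np.savetxt(buf, np.asarray(self.values, dtype=float), fmt="%.8g")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_ascii(cls, path: str | Path, name: str = "") -> "GridRaster":
        lines = Path(path).read_text().splitlines()
        header: dict[str, float] = {}
        i = 0
        while i < len(lines):
            parts = lines[i].split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
                i += 1
            else:
                break
        values = np.loadtxt(io.StringIO("\n".join(lines[i:])))
        values = np.atleast_2d(values)
        nrows, ncols = int(header["nrows"]), int(header["ncols"])
        if values.shape != (nrows, ncols):
            raise ConfigurationError(
                f"ASCII grid body {values.shape} does not match header "
                f"({nrows}, {ncols})"
            )
        cell = header["cellsize"]
        return cls(
            values=values,
            x_origin=header["xllcorner"],
            y_origin=header["yllcorner"] + nrows * cell,
            cell_size=cell,
            nodata=header.get("nodata_value", NODATA_DEFAULT),
            name=name or Path(path).stem,
        )


@dataclass
class CovariateStack:
    """Named, co-registered rasters with per-layer kind tags."""

    rasters: dict[str, GridRaster] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.rasters:
            self.kinds.setdefault(name, "continuous")
        self.validate()

    def validate(self) -> None:
        offenders = []
        template = self.template
        for name, rast in self.rasters.items():
            if template is not None and not template.co_registered(rast):
                offenders.append(name)
            kind = self.kinds.get(name, "continuous")
            if kind not in VALID_KINDS:
                raise ConfigurationError(f"unknown kind {kind!r} for layer {name!r}")
            if kind in ("categorical", "ordinal"):
                vals = rast.values[rast.valid_mask()]
                if vals.size and not np.allclose(vals, np.round(vals)):
                    raise ConfigurationError(
                        f"{kind} layer {name!r} holds non-integer codes"
                    )
        if offenders:
            raise CoRegistrationError(
                "layers not co-registered with the stack grid: "
                + ", ".join(sorted(offenders))
            )

    @property
    def template(self) -> GridRaster | None:
        return next(iter(self.rasters.values()), None)

    @property
    def names(self) -> list[str]:
        return list(self.rasters)

    def __len__(self) -> int:
        return len(self.rasters)

    def __iter__(self) -> Iterator[str]:
        return iter(self.rasters)

    def __getitem__(self, name: str) -> GridRaster:
        return self.rasters[name]

    def __contains__(self, name: str) -> bool:
        return name in self.rasters

    def add(self, raster: GridRaster, kind: str = "continuous") -> None:
        if raster.name in self.rasters:
            raise ConfigurationError(f"duplicate layer name {raster.name!r}")
        self.rasters[raster.name] = raster
        self.kinds[raster.name] = kind
        self.validate()

    def subset(self, names: list[str]) -> "CovariateStack":
        missing = [n for n in names if n not in self.rasters]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return CovariateStack(
            rasters={n: self.rasters[n] for n in names},
            kinds={n: self.kinds[n] for n in names},
        )

    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        template = self.template
        if template is None:
            raise ConfigurationError("empty stack")
        mask = np.ones(template.shape, dtype=bool)
        for rast in self.rasters.values():
            mask &= rast.valid_mask()
        return mask

    def table(self, mask: np.ndarray | None = None) -> "pd.DataFrame":
        """DataFrame of per-cell layer values (row-major cell order)."""
        import pandas as pd

        template = self.template
        if mask is None:
            mask = np.ones(template.shape, dtype=bool)
        flat = mask.ravel()
        data = {n: r.values.ravel()[flat] for n, r in self.rasters.items()}
        idx = np.flatnonzero(flat)
        return pd.DataFrame(data, index=idx)

    def write_dir(self, out_dir: str | Path) -> "pd.DataFrame":
        """Write one .asc per layer plus a manifest CSV; returns manifest."""
        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for name, rast in self.rasters.items():
            rast.to_ascii(out / f"{name}.asc")
            valid = rast.valid_mask()
            vals = rast.values[valid]
            rows.append(
                {
                    "name": name,
                    "kind": self.kinds[name],
                    "min": float(vals.min()) if vals.size else np.nan,
                    "max": float(vals.max()) if vals.size else np.nan,
                    "nodata_count": int((~valid).sum()),
                }
            )
        manifest = pd.DataFrame(rows)
        manifest.to_csv(out / "layers.csv", index=False)
        return manifest

    @classmethod
    def read_dir(cls, in_dir: str | Path) -> "CovariateStack":
        import pandas as pd

        in_path = Path(in_dir)
        manifest = pd.read_csv(in_path / "layers.csv")
        rasters = {}
        kinds = {}
        for _, row in manifest.iterrows():
            name = row["name"]
            rasters[name] = GridRaster.from_ascii(in_path / f"{name}.asc", name=name)
            kinds[name] = row["kind"]
        return cls(rasters=rasters, kinds=kinds)
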