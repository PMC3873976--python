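"""Derived landscape predictor rasters.

Builds the predictor layers used to model spatial stress patterns from raw
rasters and vector disturbance features, on a common 1-km cell-centre
registered grid:

* exponential distance decay ``e^(-a d)`` to roads / railways / well-sites,
  with the decay constant a fixed at 0.002 per metre (value 1 on a feature,
  ~0.018 at 2 km; not truncated),
* cumulative linear density of secondary linear features per cell (km/km^2),
* proportion of each cell harvested, split into <=15-yr and >15-yr age
  classes,
* proportion of parks and protected area within a 10-km radius of each cell
  centre,
* terrain ruggedness index (TRI, root of summed squared elevation
  differences to the 8 neighbours) and compound topographic index
  (CTI = ln(specific catchment area / tan(slope)) with D8 accumulation)
  from the DEM.

Distances are measured from cell centres to the nearest feature geometry
(not to rasterized feature cells), which avoids rasterization bias at
coarse cells.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree

from .raster import (
    ConfigurationError, CoRegistrationError, CovariateStack, GeometryError,
    GridRaster,
)

#: per-metre exponential decay constant of the disturbance influence
DECAY_CONSTANT = 0.002

#: neighbourhood radius of the protected-area proportion, metres
PROTECTED_RADIUS_M = 10000.0

#: harvest-block age split, years
HARVEST_AGE_SPLIT = 15

#: minimum tan(slope) used in the CTI to avoid division by zero on flats
CTI_SLOPE_FLOOR = 0.001


@dataclass
class DecayConfig:
    """Exponential distance-decay parameters: value = exp(-a * d_metres)."""

    a: float = DECAY_CONSTANT

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ConfigurationError("decay constant a must be positive")


def _require_geoms(features) -> list:
    """Coerce feature input (records or geometries) to a geometry list."""
    out = []
    for f in features:
        geom = f["geometry"] if isinstance(f, dict) else f
        out.append(geom)
    return out


def _check_within_reason(geom_list: list, grid: GridRaster) -> None:
    """Shared-CRS proxy check: features must overlap the grid neighbourhood."""
    if not geom_list:
        return
    gx0, gy0, gx1, gy1 = grid.bounds
    pad = 100 * max(gx1 - gx0, gy1 - gy0)
    fb = shapely.total_bounds(np.array(geom_list, dtype=object))
    if fb[0] > gx1 + pad or fb[2] < gx0 - pad or fb[1] > gy1 + pad or fb[3] < gy0 - pad:
        raise GeometryError(
            "feature coordinates are far outside the grid extent; "
            "inputs are probably in different coordinate systems"
        )


# ---------------------------------------------------------------------------
# vector -> raster covariates
# ---------------------------------------------------------------------------

def distance_decay_surface(
    features, grid: GridRaster, cfg: DecayConfig | None = None,
    name: str = "dd",
) -> GridRaster:
    """exp(-a * distance) from each cell centre to the nearest feature.

    A cell whose centre sits on a feature gets exactly 1; an empty feature
    collection yields the all-zero raster (no influence anywhere).
    """
    cfg = cfg or DecayConfig()
    geom_list = _require_geoms(features)
    if not geom_list:
        return grid.like(np.zeros(grid.shape), name=name)
    _check_within_reason(geom_list, grid)
    centers = grid.center_points()
    pts = shapely.points(centers[:, 0], centers[:, 1])
    tree = STRtree(geom_list)
    nearest = tree.nearest(pts)
    dist = shapely.distance(pts, np.array(geom_list, dtype=object)[nearest])
    values = np.exp(-cfg.a * dist).reshape(grid.shape)
    return grid.like(values, name=name)


def _cell_boxes(grid: GridRaster) -> np.ndarray:
    gx, gy = grid.cell_centers()
    half = grid.cell_size / 2.0
    return shapely.box(
        (gx - half).ravel(), (gy - half).ravel(),
        (gx + half).ravel(), (gy + half).ravel(),
    )


def linear_density_surface(lines, grid: GridRaster, name: str = "ln_den") -> GridRaster:
    """Total line length per cell in km per km^2 of cell area."""
    geom_list = _require_geoms(lines)
    total = np.zeros(grid.shape[0] * grid.shape[1])
    if geom_list:
        _check_within_reason(geom_list, grid)
        boxes = _cell_boxes(grid)
        tree = STRtree(geom_list)
        idx_cells, idx_lines = tree.query(boxes, predicate="intersects")
        if idx_cells.size:
            pieces = shapely.intersection(
                boxes[idx_cells], np.array(geom_list, dtype=object)[idx_lines]
            )
            np.add.at(total, idx_cells, shapely.length(pieces))
    km_per_km2 = (total / 1000.0) / ((grid.cell_size / 1000.0) ** 2)
    return grid.like(km_per_km2.reshape(grid.shape), name=name)


def area_proportion_surface(
    polygons, grid: GridRaster, name: str = "prop"
) -> GridRaster:
    """Proportion of each cell covered by the polygons, in [0, 1]."""
    geom_list = _require_geoms(polygons)
    for i, g in enumerate(geom_list):
        if not g.is_valid:
            raise GeometryError(f"invalid (self-intersecting) polygon at index {i}")
    covered = np.zeros(grid.shape[0] * grid.shape[1])
    if geom_list:
        _check_within_reason(geom_list, grid)
        union = shapely.unary_union(geom_list)  # avoid double counting overlaps
        boxes = _cell_boxes(grid)
        tree = STRtree([union])
        idx_cells, _ = tree.query(boxes, predicate="intersects")
        if idx_cells.size:
            pieces = shapely.intersection(boxes[idx_cells], union)
            covered[idx_cells] = shapely.area(pieces)
    prop = np.clip(covered / (grid.cell_size ** 2), 0.0, 1.0)
    return grid.like(prop.reshape(grid.shape), name=name)


def harvest_age_split(blocks, reference_year: int) -> tuple[list[dict], list[dict]]:
    """Partition harvest blocks into <=15-yr (young) and >15-yr (old).

    Age is reference_year - year; exactly 15 years counts as young. Every
    block must carry an integer ``year`` property no later than the
    reference year.
    """
    young, old = [], []
    for i, rec in enumerate(blocks):
        props = rec.get("properties", {}) if isinstance(rec, dict) else {}
        if "year" not in props:
            raise ValueError(f"harvest block {i} is missing its 'year' attribute")
        year = int(props["year"])
        if year > reference_year:
            raise ValueError(
                f"harvest block {i} has year {year} after reference {reference_year}"
            )
        (young if reference_year - year <= HARVEST_AGE_SPLIT else old).append(rec)
    return young, old


def protected_proportion_surface(
    parks, grid: GridRaster, radius: float = PROTECTED_RADIUS_M,
    name: str = "pa",
) -> GridRaster:
    """Proportion of a radius-r disc around each cell centre that is park.

    The disc is a centre-anchored circular buffer; the proportion is the
    exact polygon intersection area over the disc area. 1 deep inside
    parks, 0 where no park lies within the radius.
    """
    if radius <= 0:
        raise ConfigurationError("radius must be positive")
    geom_list = _require_geoms(parks)
    n_cells = grid.shape[0] * grid.shape[1]
    if not geom_list:
        return grid.like(np.zeros(grid.shape), name=name)
    _check_within_reason(geom_list, grid)
    union = shapely.unary_union(geom_list)
    shapely.prepare(union)
    centers = grid.center_points()
    values = np.zeros(n_cells)
    uxmin, uymin, uxmax, uymax = union.bounds
    for i, (cx, cy) in enumerate(centers):
        # bbox shortcut: disc cannot reach the parks at all
        if (cx + radius < uxmin or cx - radius > uxmax
                or cy + radius < uymin or cy - radius > uymax):
            continue
        disc = Point(cx, cy).buffer(radius, quad_segs=64)
        if shapely.contains_properly(union, disc):
            values[i] = 1.0
        elif union.intersects(disc):
            values[i] = disc.intersection(union).area / disc.area
    return grid.like(values.reshape(grid.shape), name=name)


# ---------------------------------------------------------------------------
# terrain indices
# ---------------------------------------------------------------------------

def terrain_ruggedness(dem: GridRaster, name: str = "tri") -> GridRaster:
    """Terrain ruggedness index: local relief magnitude.

    sqrt( sum over the 8 neighbours of (z_neighbour - z_centre)^2 ); edge
    cells use the neighbours they have. Nodata cells and all-nodata
    neighbourhoods propagate nodata.
    """
    if dem.nrows < 3 or dem.ncols < 3:
        raise ConfigurationError("TRI needs at least a 3x3 DEM")
    z = np.where(dem.valid_mask(), dem.values.astype(float), np.nan)
    padded = np.pad(z, 1, constant_values=np.nan)
    sq_sum = np.zeros_like(z)
    any_neighbor = np.zeros_like(z, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = padded[1 + dr: 1 + dr + z.shape[0], 1 + dc: 1 + dc + z.shape[1]]
            diff = nb - z
            ok = np.isfinite(diff)
            sq_sum[ok] += diff[ok] ** 2
            any_neighbor |= ok
    tri = np.sqrt(sq_sum)
    tri[~any_neighbor | ~np.isfinite(z)] = dem.nodata
    return dem.like(tri, name=name)


_D8_OFFSETS = [
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
]


def _priority_flood_fill(z: np.ndarray) -> np.ndarray:
    """Fill closed depressions: every cell drains to the boundary."""
    nr, nc = z.shape
    filled = z.copy()
    visited = np.zeros_like(z, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for r in range(nr):
        for c in (0, nc - 1):
            heapq.heappush(heap, (filled[r, c], r, c))
            visited[r, c] = True
    for c in range(1, nc - 1):
        for r in (0, nr - 1):
            heapq.heappush(heap, (filled[r, c], r, c))
            visited[r, c] = True
    while heap:
        elev, r, c = heapq.heappop(heap)
        for dr, dc in _D8_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not visited[rr, cc]:
                visited[rr, cc] = True
                filled[rr, cc] = max(filled[rr, cc], elev)
                heapq.heappush(heap, (filled[rr, cc], rr, cc))
    return filled


def compound_topographic_index(dem: GridRaster, name: str = "cti") -> GridRaster:
    """CTI / topographic wetness: ln(specific catchment area / tan(slope)).

    The DEM is pit-filled by priority flood; flow follows the single
    steepest D8 descent direction (ties broken by direction order); the
    specific catchment area is (number of upslope cells + 1) * cell_size;
    tan(slope) is each cell's steepest descent gradient, floored at
    ``CTI_SLOPE_FLOOR`` so flats stay finite. A constant DEM therefore
    yields the max-clamp value everywhere, with a warning.
    """
    if dem.nrows < 3 or dem.ncols < 3:
        raise ConfigurationError("CTI needs at least a 3x3 DEM")
    z = dem.values.astype(float)
    if not np.all(dem.valid_mask()):
        raise ConfigurationError("CTI requires a gap-free DEM")
    filled = _priority_flood_fill(z)
    nr, nc = filled.shape
    cell = dem.cell_size

    if np.ptp(filled) == 0:
        warnings.warn(
            "constant DEM: CTI is the slope-floor clamp value everywhere",
            RuntimeWarning, stacklevel=2,
        )

    # steepest D8 descent per cell
    flow_to = np.full((nr, nc), -1, dtype=int)
    tanb = np.zeros((nr, nc))
    for r in range(nr):
        for c in range(nc):
            best_drop = 0.0
            best_k = -1
            for k, (dr, dc) in enumerate(_D8_OFFSETS):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nr and 0 <= cc < nc):
                    continue
                dist = cell * (np.sqrt(2.0) if dr and dc else 1.0)
                drop = (filled[r, c] - filled[rr, cc]) / dist
                if drop > best_drop:
                    best_drop = drop
                    best_k = k
            tanb[r, c] = best_drop
            if best_k >= 0:
                dr, dc = _D8_OFFSETS[best_k]
                flow_to[r, c] = (r + dr) * nc + (c + dc)

    # accumulate: process cells from high to low so donors precede receivers
    acc = np.ones(nr * nc)
    order = np.argsort(-filled.ravel(), kind="stable")
    flat_flow = flow_to.ravel()
    for i in order:
        j = flat_flow[i]
        if j >= 0:
            acc[j] += acc[i]
    sca = acc.reshape(nr, nc) * cell  # specific catchment area, m
    cti = np.log(sca / np.maximum(tanb, CTI_SLOPE_FLOOR))
    return dem.like(cti, name=name)


# ---------------------------------------------------------------------------
# stack assembly
# ---------------------------------------------------------------------------

#: expected kind per standard layer name
STANDARD_KINDS = {
    "cc": "continuous", "pctcon": "continuous", "lcover": "categorical",
    "dhi_cum": "continuous", "dhi_cv": "continuous", "dhi_min": "continuous",
    "elev": "continuous", "tri": "continuous", "cti": "continuous",
    "rsf_s1": "ordinal", "rsf_s2": "ordinal", "rsf_s3": "ordinal",
    "rsf_max": "ordinal",
    "rd_dd": "continuous", "rail_dd": "continuous", "wl_dd": "continuous",
    "ln_den": "continuous", "cblk_l": "continuous", "cblk_g": "continuous",
    "pa": "continuous",
}


def assemble_stack(
    rasters: dict[str, GridRaster], kinds: dict[str, str] | None = None
) -> CovariateStack:
    """Validate and assemble named rasters into a covariate stack.

    Raises a co-registration error naming offending layers, and validates
    ordinal RSF layers against their 0-10 code range.
    """
    kinds = dict(kinds or {})
    for name in rasters:
        kinds.setdefault(name, STANDARD_KINDS.get(name, "continuous"))
    stack = CovariateStack(
        rasters={n: r for n, r in rasters.items()}, kinds=kinds
    )
    for name, rast in stack.rasters.items():
        if name.startswith("rsf"):
            vals = rast.values[rast.valid_mask()]
            if vals.size and (vals.min() < 0 or vals.max() > 10):
                raise ConfigurationError(
                    f"RSF layer {name!r} outside the 0-10 code range"
                )
    return stack


def build_standard_stack(
    fields: CovariateStack,
    vectors: dict[str, list[dict]],
    reference_year: int,
) -> CovariateStack:
    """Derive the full standard predictor stack from raw fields + vectors.

    Produces the raw field layers plus tri, cti, rd_dd, rail_dd, wl_dd,
    ln_den, cblk_l, cblk_g, and pa on the shared grid.
    """
    template = fields.template
    if template is None:
        raise ConfigurationError("empty field stack")
    rasters = dict(fields.rasters)
    kinds = dict(fields.kinds)

    dem = fields["elev"]
    rasters["tri"] = terrain_ruggedness(dem)
    rasters["cti"] = compound_topographic_index(dem)

    rasters["rd_dd"] = distance_decay_surface(
        vectors.get("roads", []), template, name="rd_dd"
    )
    rasters["rail_dd"] = distance_decay_surface(
        vectors.get("railways", []), template, name="rail_dd"
    )
    rasters["wl_dd"] = distance_decay_surface(
        vectors.get("wells", []), template, name="wl_dd"
    )
    rasters["ln_den"] = linear_density_surface(
        vectors.get("secondary_lines", []), template
    )
    young, old = harvest_age_split(vectors.get("harvest_blocks", []), reference_year)
    rasters["cblk_l"] = area_proportion_surface(young, template, name="cblk_l")
    rasters["cblk_g"] = area_proportion_surface(old, template, name="cblk_g")
    rasters["pa"] = protected_proportion_surface(
        vectors.get("parks", []), template
    )
    for name in rasters:
        kinds.setdefault(name, STANDARD_KINDS.get(name, "continuous"))
    return assemble_stack(rasters, kinds)
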