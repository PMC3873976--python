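"""Predicted stress maps and management summaries.

Applies a fitted forest to every 1-km cell outside the smoothing windows,
classifies predictions into low / moderate / high stress using the pooled
quartiles of the *input* point marks (never of the predictions), and
produces the management products: mean covariate profiles per class,
percent-area per management unit, and per-zone frequency distributions of
predicted values.

Class boundary convention: value <= q1 -> low, q1 < value <= q3 ->
moderate, value > q3 -> high, which reproduces half-open printed ranges of
the form (a-b | >b). Quartiles use linear-interpolation sample quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .forest import ForestModel
from .raster import ConfigurationError, CovariateStack, GeometryError, GridRaster

CLASS_LABELS = {1: "low", 2: "moderate", 3: "high"}

#: landcover codes treated as non-habitat (water, barren, snow/ice)
NON_HABITAT_CLASSES = (6, 7, 8)


@dataclass
class ClassBreaks:
    """Pooled lower/upper quartile breaks of the input marks, pg/mg."""

    q1: float
    q3: float
    source: str = "pooled_marks"

    def __post_init__(self) -> None:
        if not self.q1 < self.q3:
            raise ConfigurationError("require q1 < q3")

    @classmethod
    def from_marks(cls, marks: np.ndarray, source: str = "pooled_marks") -> "ClassBreaks":
        marks = np.asarray(marks, dtype=float)
        q1, q3 = np.quantile(marks, [0.25, 0.75])  # linear interpolation
        return cls(q1=float(q1), q3=float(q3), source=source)

    def classify(self, values: np.ndarray) -> np.ndarray:
        """Integer classes 1/2/3 for low/moderate/high."""
        v = np.asarray(values, dtype=float)
        return np.where(v <= self.q1, 1, np.where(v <= self.q3, 2, 3))


def _union(records) -> Polygon:
    geom_list = [f["geometry"] if isinstance(f, dict) else f for f in records]
    return shapely.unary_union(geom_list) if geom_list else Polygon()


def _centre_mask(geom, template: GridRaster) -> np.ndarray:
    if geom.is_empty:
        return np.zeros(template.shape, dtype=bool)
    shapely.prepare(geom)
    centers = template.center_points()
    pts = shapely.points(centers[:, 0], centers[:, 1])
    return shapely.covers(geom, pts).reshape(template.shape)


def habitat_mask(
    stack: CovariateStack,
    non_habitat_classes=NON_HABITAT_CLASSES,
    landcover: str = "lcover",
) -> np.ndarray:
    """Cells that are habitat: landcover not in the non-habitat code list."""
    if landcover not in stack:
        return np.ones(stack.template.shape, dtype=bool)
    lc = stack[landcover]
    mask = lc.valid_mask()
    for code in non_habitat_classes:
        mask &= lc.values != code
    return mask


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_surface(
    model: ForestModel,
    stack: CovariateStack,
    exclusion=None,
    habitat: np.ndarray | None = None,
) -> GridRaster:
    """Forest prediction at every eligible cell.

    Eligible cells are valid in every predictor layer, outside the
    exclusion polygons (the smoothing windows already represented by the
    observed surface), and inside the habitat mask. Everything else is
    nodata.
    """
    template = stack.template
    if template is None:
        raise ConfigurationError("empty covariate stack")
    needed = sorted({model.parent_of[c] for c in model.feature_names})
    missing = [v for v in needed if v not in stack]
    if missing:
        raise KeyError(f"stack is missing predictor layers: {missing}")
    mask = stack.subset(needed).valid_mask()
    if exclusion is not None:
        mask &= ~_centre_mask(_union(exclusion), template)
    if habitat is not None:
        mask &= habitat
    values = np.full(template.shape, template.nodata)
    if mask.any():
        frame = stack.subset(needed).table(mask)
        X = model.design_matrix(frame)
        values[mask] = model.predict(X)
    return template.like(values, name="hcc_pred")


def classify_surface(surface: GridRaster, breaks: ClassBreaks) -> GridRaster:
    """Categorical low/moderate/high raster (codes 1/2/3), nodata kept."""
    valid = surface.valid_mask()
    out = np.full(surface.shape, surface.nodata)
    out[valid] = breaks.classify(surface.values[valid])
    return surface.like(out, name="hcc_class")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def covariate_profile(
    predictions: GridRaster,
    stack: CovariateStack,
    breaks: ClassBreaks,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Mean covariate value per stress class (profile table).

    Classes with zero cells report missing means (NaN), never zero; cell
    counts per class are included.
    """
    template = stack.template
    if template is None or not template.co_registered(predictions):
        raise ConfigurationError("predictions and stack are not co-registered")
    variables = variables or stack.names
    classified = classify_surface(predictions, breaks)
    valid = classified.valid_mask() & stack.valid_mask()
    cls = classified.values
    rows = []
    counts = {
        label: int(((cls == code) & valid).sum())
        for code, label in CLASS_LABELS.items()
    }
    for var in variables:
        vals = stack[var].values
        row: dict = {"variable": var}
        for code, label in CLASS_LABELS.items():
            sel = (cls == code) & valid
            row[f"mean_{label}"] = float(vals[sel].mean()) if sel.any() else np.nan
        rows.append(row)
    profile = pd.DataFrame(rows)
    for label, cnt in counts.items():
        profile[f"n_{label}"] = cnt
    return profile


def unit_area_table(
    classified: GridRaster,
    units: dict[str, object] | list[dict],
    include_total: bool = True,
) -> pd.DataFrame:
    """Percent area per management unit in each stress class.

    ``units`` maps unit label -> polygon (or is a list of records with a
    'unit'/'zone' property). Percentages are over each unit's valid cells
    and sum to 100; units with no valid cells are flagged. A 'Total' row
    pools every unit's valid cells.
    """
    if isinstance(units, list):
        mapping: dict[str, list] = {}
        for rec in units:
            label = (
                rec.get("properties", {}).get("unit")
                or rec.get("properties", {}).get("zone")
                or "unit"
            )
            mapping.setdefault(label, []).append(rec["geometry"])
        units = {k: shapely.unary_union(v) for k, v in mapping.items()}
    valid = classified.valid_mask()
    cls = classified.values
    rows = []
    pooled = {code: 0 for code in CLASS_LABELS}
    pooled_n = 0
    for label, geom in units.items():
        mask = _centre_mask(geom, classified) & valid
        n = int(mask.sum())
        row: dict = {"unit": label, "n_cells": n, "flagged_empty": n == 0}
        for code, cname in CLASS_LABELS.items():
            cnt = int(((cls == code) & mask).sum())
            pooled[code] += cnt
            row[f"pct_{cname}"] = 100.0 * cnt / n if n else np.nan
        pooled_n += n
        rows.append(row)
    if include_total:
        row = {"unit": "Total", "n_cells": pooled_n, "flagged_empty": pooled_n == 0}
        for code, cname in CLASS_LABELS.items():
            row[f"pct_{cname}"] = (
                100.0 * pooled[code] / pooled_n if pooled_n else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def zone_frequency(
    predictions: GridRaster,
    zones: list[dict],
    bins: np.ndarray | int = 20,
    zone_key: str | None = None,
) -> pd.DataFrame:
    """Per-zone relative frequency distribution of predicted values.

    Cells are assigned to every zone whose polygon covers their centre
    (overlapping zones each receive the cell; the overlap fraction is
    logged via a warning). Frequencies sum to 1 within each zone; empty
    zones are flagged with all-zero rows.
    """
    valid = predictions.valid_mask()
    vals = predictions.values
    all_vals = vals[valid]
    if isinstance(bins, int):
        if all_vals.size == 0:
            bins = np.linspace(0, 1, bins + 1)
        else:
            bins = np.linspace(all_vals.min(), all_vals.max(), bins + 1)
    bins = np.asarray(bins, dtype=float)

    # group records by label
    grouped: dict[str, list] = {}
    for rec in zones:
        props = rec.get("properties", {})
        label = (
            props.get(zone_key) if zone_key
            else props.get("zone") or props.get("state") or props.get("unit")
        ) or "zone"
        grouped.setdefault(label, []).append(rec["geometry"])

    masks = {
        label: _centre_mask(shapely.unary_union(geoms), predictions) & valid
        for label, geoms in grouped.items()
    }
    # overlap logging
    if len(masks) > 1:
        coverage = np.zeros(predictions.shape, dtype=int)
        for m in masks.values():
            coverage += m
        overlap = int((coverage > 1).sum())
        if overlap:
            warnings.warn(
                f"{overlap} cells fall in multiple zones; counted in each",
                RuntimeWarning, stacklevel=2,
            )

    rows = []
    for label, mask in masks.items():
        zone_vals = vals[mask]
        hist, _ = np.histogram(zone_vals, bins=bins)
        n = int(mask.sum())
        freq = hist / n if n else np.zeros_like(hist, dtype=float)
        for b in range(len(bins) - 1):
            rows.append(
                {
                    "zone": label,
                    "bin_left": bins[b],
                    "bin_right": bins[b + 1],
                    "count": int(hist[b]),
                    "frequency": float(freq[b]),
                    "n_cells": n,
                    "flagged_empty": n == 0,
                }
            )
    return pd.DataFrame(rows)
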