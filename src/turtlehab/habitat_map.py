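"""Gridded suitability prediction, thresholding, area and zone accounting.

A fitted habitat model is scored on every sea pixel of a scene at a chosen
date (dynamic predictors matched to the nearest date not after it), giving a
probability surface on the scene's grid (500 m pixels by default). A pixel
is "suitable" when its predicted probability of presence is strictly above
0.5 — more likely than not. Areas are pixel counts times pixel area; zone
shares assign each suitable pixel to the first zone polygon containing its
centre; two-date comparisons report the area change and a
gained/lost/stable classification raster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .brt_engine import BrtModel, predict
from .synthetic_data import Scene

__all__ = ["SuitabilitySurface", "ZoneTable", "predict_surface",
           "suitable_area", "zone_overlap", "temporal_change"]

SUITABILITY_THRESHOLD = 0.5


@dataclass
class SuitabilitySurface:
    """Per-pixel probability of presence on the scene grid; NaN on masked
    (land or missing-predictor) pixels."""

    probabilities: np.ndarray
    scene: Scene
    date: np.datetime64
    model_features: list = field(default_factory=list)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.probabilities)

    def suitable_mask(self, threshold: float = SUITABILITY_THRESHOLD) -> np.ndarray:
        return self.valid & (self.probabilities > threshold)


def predict_surface(model: BrtModel, scene: Scene, date,
                    annual_layers: dict[str, dict[int, np.ndarray]] | None = None
                    ) -> SuitabilitySurface:
    """Score the model on every sea pixel of the scene at one date.

    Each pixel's predictor vector is assembled from the static layers, the
    dynamic stacks at the nearest date not after ``date`` and, when supplied,
    annual layers matched by calendar year; land pixels are masked. A
    predictor the scene cannot provide raises with the layer name.
    """
    date = np.datetime64(date)
    grid = scene.grid
    n = grid.n_rows * grid.n_cols
    cols = {}
    for name in model.feature_names:
        if name in scene.static:
            cols[name] = scene.static[name].ravel()
        elif name in scene.dynamic:
            da = scene.dynamic[name]
            dates = da["date"].values
            idx = int(np.searchsorted(dates, date, side="right") - 1)
            if idx < 0:
                raise ValueError(f"date precedes dynamic coverage of layer {name!r}")
            cols[name] = da.values[idx].ravel()
        elif annual_layers and name in annual_layers:
            year = pd.Timestamp(date).year
            per_year = annual_layers[name]
            if year not in per_year:
                raise ValueError(f"no {name!r} layer for year {year}")
            cols[name] = per_year[year].ravel()
        else:
            raise ValueError(f"scene provides no predictor layer {name!r}")

    X = pd.DataFrame(cols)
    probs = np.full(n, np.nan)
    sea = ~scene.land_mask.ravel()
    finite = np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    ok = sea & finite
    probs[ok] = predict(model, X[ok])
    return SuitabilitySurface(probabilities=probs.reshape(grid.shape),
                              scene=scene, date=date,
                              model_features=list(model.feature_names))


def suitable_area(surface: SuitabilitySurface,
                  threshold: float = SUITABILITY_THRESHOLD) -> tuple[float, float]:
    """(area_km2, percent_of_modelled_area) of pixels strictly above the
    threshold; the percentage denominator is the unmasked (modelled) pixels."""
    mask = surface.suitable_mask(threshold)
    n_valid = int(surface.valid.sum())
    area = float(mask.sum()) * surface.scene.grid.pixel_area_km2
    pct = 100.0 * mask.sum() / n_valid if n_valid else np.nan
    return area, float(pct)


@dataclass
class ZoneTable:
    """Per-zone suitable area and its share of total suitable area."""

    table: pd.DataFrame  # zone, area_km2, percent
    threshold: float
    zone_order: list


def zone_overlap(surface: SuitabilitySurface, zones,
                 threshold: float = SUITABILITY_THRESHOLD) -> ZoneTable:
    """Share of the suitable area inside each zone polygon.

    ``zones`` is a sequence of (name, shapely geometry) pairs or a GeoJSON
    FeatureCollection dict with a ``name`` property per feature. Each
    suitable pixel is assigned to the first listed zone containing its
    centre; pixels in no zone count as "outside". Percentages (zones plus
    outside) sum to 100.
    """
    pairs = _as_zone_pairs(zones)
    mask = surface.suitable_mask(threshold)
    rows, cols_idx = np.where(mask)
    xs, ys = surface.scene.grid.pixel_centers()
    px = xs[cols_idx]
    py = ys[rows]
    assigned = np.full(len(px), -1)
    for zi, (name, geom) in enumerate(pairs):
        if not geom.is_valid:
            raise ValueError(f"invalid zone geometry at index {zi} ({name!r})")
        free = assigned == -1
        if not free.any():
            break
        hit = contains_xy(geom, px[free], py[free])
        idx = np.where(free)[0][hit]
        assigned[idx] = zi
    pixel_area = surface.scene.grid.pixel_area_km2
    total = len(px) * pixel_area
    recs = []
    for zi, (name, _) in enumerate(pairs):
        a = float((assigned == zi).sum()) * pixel_area
        recs.append((name, a, 100.0 * a / total if total else np.nan))
    a_out = float((assigned == -1).sum()) * pixel_area
    recs.append(("outside", a_out, 100.0 * a_out / total if total else np.nan))
    return ZoneTable(table=pd.DataFrame(recs, columns=["zone", "area_km2", "percent"]),
                     threshold=threshold, zone_order=[n for n, _ in pairs])


def _as_zone_pairs(zones):
    if isinstance(zones, dict) and zones.get("type") == "FeatureCollection":
        return [(f["properties"].get("name", f"zone_{i}"),
                 shapely_shape(f["geometry"]))
                for i, f in enumerate(zones["features"])]
    out = []
    for name, geom in zones:
        if not isinstance(geom, BaseGeometry):
            geom = shapely_shape(geom)
        out.append((name, geom))
    return out


def temporal_change(surface_a: SuitabilitySurface, surface_b: SuitabilitySurface,
                    threshold: float = SUITABILITY_THRESHOLD) -> dict:
    """Compare suitable habitat between two dates on the same grid.

    Returns areas for both surfaces, the percent change 100*(b-a)/a (None
    when a has no suitable area), and a classification raster with codes
    0 = never suitable, 1 = stable suitable, 2 = gained (b only),
    3 = lost (a only).
    """
    if surface_a.probabilities.shape != surface_b.probabilities.shape:
        raise ValueError("surfaces are not on the same grid")
    ma = surface_a.suitable_mask(threshold)
    mb = surface_b.suitable_mask(threshold)
    pixel_area = surface_a.scene.grid.pixel_area_km2
    area_a = float(ma.sum()) * pixel_area
    area_b = float(mb.sum()) * pixel_area
    change = 100.0 * (area_b - area_a) / area_a if area_a > 0 else None
    classes = np.zeros(ma.shape, dtype=np.int8)
    classes[ma & mb] = 1
    classes[~ma & mb] = 2
    classes[ma & ~mb] = 3
    return {
        "area_a_km2": area_a,
        "area_b_km2": area_b,
        "percent_change": change,
        "classification": classes,
        "n_stable": int((classes == 1).sum()),
        "n_gained": int((classes == 2).sum()),
        "n_lost": int((classes == 3).sum()),
    }
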