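"""Environmental annotation of labelled points, collinearity screening, and
environmental-separation scoring.

Distance-to-feature grids are Euclidean distance transforms in metres;
time-varying source layers (e.g. annual mangrove canopy maps, where a pixel
counts as mangrove at >= 20% canopy cover) yield one distance grid per year.
Each presence/pseudo-absence point is annotated with every predictor at its
location and timestamp: static rasters by pixel containment, dynamic stacks
at the nearest date not after the point's timestamp (model outputs are
step-valid forward in time, so no values are invented by interpolation),
annual layers by calendar year. Points whose timestamps fall outside the
dynamic coverage window are removed altogether, presences and their matched
pseudo-absences alike. Before modelling, pairs of continuous predictors
correlated more than 70% are reduced to one member, and the Bhattacharyya
coefficient scores how separable presence and absence environments are
(0 = entirely dissimilar, 1 = identical).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import Scene, distance_from_mask

__all__ = ["AnnotatedTable", "ScreenReport", "distance_grid", "annotate",
           "temporal_clip", "correlation_screen", "bhattacharyya"]

CORRELATION_THRESHOLD = 0.70


@dataclass
class AnnotatedTable:
    """Model design matrix: one row per labelled point with its predictor
    vector; missingness is explicit in ``missing`` (same shape as the
    predictor block), never silently imputed."""

    data: pd.DataFrame  # label, animal_id, timestamp, x, y, <predictors...>
    predictors: list[str]
    categorical: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def continuous(self) -> list[str]:
        return [p for p in self.predictors if p not in self.categorical]

    @property
    def missing(self) -> pd.DataFrame:
        return self.data[self.predictors].isna()

    def dropna_rows(self) -> tuple["AnnotatedTable", int]:
        """Drop rows with any missing retained predictor (counted)."""
        keep = ~self.missing.any(axis=1)
        dropped = int((~keep).sum())
        return AnnotatedTable(self.data[keep].reset_index(drop=True),
                              list(self.predictors), self.categorical), dropped

    def with_predictors(self, names) -> "AnnotatedTable":
        names = list(names)
        cols = [c for c in self.data.columns if c not in self.predictors] + names
        return AnnotatedTable(self.data[cols], names,
                              frozenset(n for n in self.categorical if n in names))

    def to_csv(self, path, schema_path=None) -> None:
        """Write the table; optionally a JSON schema sidecar mapping each
        predictor column to its type."""
        self.data.to_csv(path, index=False)
        if schema_path is not None:
            import json
            schema = {p: ("categorical" if p in self.categorical else "continuous")
                      for p in self.predictors}
            with open(schema_path, "w") as fh:
                json.dump(schema, fh, indent=2)


@dataclass
class ScreenReport:
    """Audit trail of the collinearity screen."""

    correlation: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (dropped, partner)
    threshold: float = CORRELATION_THRESHOLD

    def to_json(self) -> str:
        import json
        return json.dumps({
            "threshold": self.threshold,
            "dropped": [{"predictor": d, "partner": p} for d, p in self.dropped],
            "correlation": {c: self.correlation[c].round(6).to_dict()
                            for c in self.correlation.columns},
        })


# ---------------------------------------------------------------------------
# distance grids
# ---------------------------------------------------------------------------


def distance_grid(scene: Scene, feature_layer, qualifier=None):
    """Euclidean distance (m) to qualifying source pixels of a feature layer.

    feature_layer is a 2-D array on the scene grid, or a dict/mapping of
    year -> array for annual layers (an annual distance grid is returned per
    year). ``qualifier`` turns the layer into a source mask: a callable
    predicate on the array, a threshold (source where layer >= threshold),
    or None for boolean/nonzero layers. A layer with no qualifying pixel
    yields an all-infinite grid and a warning.
    """
    if isinstance(feature_layer, dict):
        return {year: distance_grid(scene, arr, qualifier)
                for year, arr in feature_layer.items()}
    arr = np.asarray(feature_layer)
    if arr.shape != scene.grid.shape:
        raise ValueError("feature layer is not on the scene grid")
    if qualifier is None:
        mask = arr.astype(bool)
    elif callable(qualifier):
        mask = qualifier(arr)
    else:
        mask = arr >= qualifier
    if not mask.any():
        warnings.warn("no source pixel qualifies; distance grid is all-infinite")
        return np.full(scene.grid.shape, np.inf)
    return distance_from_mask(mask, scene.grid.pixel_size)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _nearest_not_after(dates: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Index of the latest date <= each timestamp; -1 when none exists."""
    return np.searchsorted(dates, ts, side="right") - 1


def annotate(points: pd.DataFrame, scene: Scene,
             annual_layers: dict[str, dict[int, np.ndarray]] | None = None
             ) -> AnnotatedTable:
    """Sample every scene predictor at each labelled point.

    ``points`` needs columns (label, timestamp, x, y); ``animal_id`` and
    ``sim_id`` are carried through when present. Static layers are sampled by
    pixel containment, dynamic layers at the nearest date not after the
    point's timestamp (earlier-than-coverage points get a missing value),
    annual layers by calendar year. Points outside the grid keep their row
    with all predictors missing.
    """
    pts = points.reset_index(drop=True)
    ts = pd.to_datetime(pts["timestamp"]).to_numpy()
    row, col = scene.grid.world_to_rowcol(pts["x"].to_numpy(float),
                                          pts["y"].to_numpy(float))
    inb = scene.grid.in_bounds(row, col)
    r = np.where(inb, row, 0)
    c = np.where(inb, col, 0)

    out = {}
    for name, arr in scene.static.items():
        v = arr[r, c].astype(float)
        v[~inb] = np.nan
        out[name] = v
    for name, da in scene.dynamic.items():
        dates = da["date"].values
        idx = _nearest_not_after(dates, ts)
        ok = inb & (idx >= 0)
        i = np.where(idx >= 0, idx, 0)
        v = da.values[i, r, c]
        v = np.where(ok, v, np.nan)
        out[name] = v
    if annual_layers:
        years = pd.DatetimeIndex(ts).year.to_numpy()
        for name, per_year in annual_layers.items():
            v = np.full(len(pts), np.nan)
            for yr, arr in per_year.items():
                sel = inb & (years == yr)
                v[sel] = arr[r[sel], c[sel]]
            out[name] = v

    meta_cols = [c_ for c_ in ("label", "animal_id", "sim_id", "timestamp", "x", "y")
                 if c_ in pts.columns]
    data = pd.concat([pts[meta_cols], pd.DataFrame(out)], axis=1)
    predictors = list(out)
    categorical = frozenset(n for n in predictors if n in scene.categorical)
    return AnnotatedTable(data=data, predictors=predictors, categorical=categorical)


def temporal_clip(table: AnnotatedTable, coverage) -> tuple[AnnotatedTable, dict]:
    """Drop all rows (presences and pseudo-absences alike) with timestamps
    outside [start, end] of the environmental coverage window; source tracks
    falling entirely outside are logged as fully dropped."""
    start, end = (pd.Timestamp(coverage[0]), pd.Timestamp(coverage[1]))
    if end < start:
        raise ValueError("coverage window is not well ordered")
    ts = pd.to_datetime(table.data["timestamp"])
    keep = (ts >= start) & (ts <= end)
    log = {"rows_removed": int((~keep).sum())}
    if "animal_id" in table.data.columns:
        by = table.data.groupby("animal_id", sort=False).apply(
            lambda d: bool((~keep[d.index]).all()), include_groups=False)
        log["tracks_fully_dropped"] = [a for a, gone in by.items() if gone]
    clipped = AnnotatedTable(table.data[keep].reset_index(drop=True),
                             list(table.predictors), table.categorical)
    return clipped, log


# ---------------------------------------------------------------------------
# collinearity screen
# ---------------------------------------------------------------------------


def correlation_screen(table: AnnotatedTable,
                       threshold: float = CORRELATION_THRESHOLD
                       ) -> tuple[AnnotatedTable, ScreenReport]:
    """Reduce each strictly-more-than-``threshold`` correlated pair of
    continuous predictors to one member.

    Pearson correlations are computed on complete pairs; pairs are resolved
    greedily, worst first, dropping the member with the larger mean absolute
    correlation to all other predictors (ties broken by column order).
    Zero-variance predictors are dropped with a warning. Categorical
    predictors are exempt.
    """
    cont = [p for p in table.continuous]
    if len(cont) < 2:
        raise ValueError("need at least 2 continuous predictors to screen")
    X = table.data[cont]
    dropped: list[tuple[str, str]] = []

    for p in list(cont):
        if X[p].std(skipna=True) == 0 or X[p].isna().all():
            warnings.warn(f"zero-variance predictor {p!r} dropped")
            dropped.append((p, ""))
            cont.remove(p)

    corr = X[cont].corr(method="pearson")
    report_corr = corr.copy()
    work = corr.abs().to_numpy()
    np.fill_diagonal(work, 0.0)
    names = list(cont)
    alive = dict.fromkeys(names, True)
    while True:
        live = [n for n in names if alive[n]]
        sub = report_corr.loc[live, live].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        if sub.size == 0 or np.nanmax(sub) <= threshold:
            break
        i, j = np.unravel_index(np.nanargmax(sub), sub.shape)
        a, b = live[i], live[j]
        mean_a = np.nanmean([abs(report_corr.loc[a, o]) for o in live if o != a])
        mean_b = np.nanmean([abs(report_corr.loc[b, o]) for o in live if o != b])
        # drop the member more entangled with everything else; first column
        # wins ties (so its later-ordered partner goes)
        victim, partner = (a, b) if mean_a > mean_b else (b, a)
        if mean_a == mean_b:
            victim, partner = (b, a) if names.index(a) < names.index(b) else (a, b)
        alive[victim] = False
        dropped.append((victim, partner))

    keep = [p for p in table.predictors
            if p in table.categorical or alive.get(p, False)]
    reduced = table.with_predictors(keep)
    return reduced, ScreenReport(correlation=report_corr, dropped=dropped,
                                 threshold=threshold)


# ---------------------------------------------------------------------------
# environmental separation
# ---------------------------------------------------------------------------


def bhattacharyya(presence_values, absence_values, n_bins: int = 100) -> float:
    """Bhattacharyya coefficient between two samples.

    Both samples are binned on ``n_bins`` equal-width bins spanning their
    pooled range; BC = sum_i sqrt(p_i * q_i) of the bin proportions, in
    [0, 1] with 1 for identical distributions and 0 for disjoint supports.
    """
    p = np.asarray(presence_values, dtype=float)
    q = np.asarray(absence_values, dtype=float)
    p = p[np.isfinite(p)]
    q = q[np.isfinite(q)]
    if len(p) == 0 or len(q) == 0:
        raise ValueError("both samples must be non-empty and finite")
    lo = min(p.min(), q.min())
    hi = max(p.max(), q.max())
    if lo == hi:
        warnings.warn("single distinct pooled value; coefficient is 1 by convention")
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    hp, _ = np.histogram(p, bins=edges)
    hq, _ = np.histogram(q, bins=edges)
    return float(np.sqrt((hp / hp.sum()) * (hq / hq.sum())).sum())
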