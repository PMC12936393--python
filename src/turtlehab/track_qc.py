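"""Quality control for raw satellite telemetry.

The cleaning pipeline turns a raw fix table into independent, cleaned track
segments: remove empty rows and exact duplicates, keep only high-quality
ARGOS classes (1/2/3; GPS always kept), discard each animal's first 24 h
(post-release behaviour), strip speed/turning-angle spikes, drop on-land
fixes, split at gaps of more than 72 h, keep only segments with more than 20
locations, and truncate long (> 150 km) directed departures such as breeding
migrations. Every removal is counted in a provenance log.

The speed/angle filter is this package's concrete definition of a
spike filter driven by a maximum plausible speed and a threshold inner
angle: a fix is a spike if the legs into and out of it both exceed the
maximum speed, or if it forms an inner angle sharper than the threshold with
both adjacent legs faster than half the maximum speed; removal is iterated
to a fixed point. It is an approximation to published data-driven filters,
with the same thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import Scene, TELEMETRY_COLUMNS

__all__ = ["QcConfig", "Track", "basic_clean", "speed_angle_filter",
           "remove_terrestrial", "split_and_trim", "remove_migrations", "run_qc"]

RETAINED_ARGOS_CLASSES = frozenset({"1", "2", "3"})

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for the QC pipeline (all strictly positive).

    max_speed_kmh: maximum plausible sustained travel speed.
    inner_angle_deg: spikes form inner angles sharper than this.
    gap_hours: a gap longer than this splits a track into independent segments.
    min_locations: segments must contain strictly more fixes than this.
    burn_in_hours: discard this long after each animal's first fix.
    migration_km: displacement beyond this flags a directed departure.
    planar: coordinates are planar metres (synthetic scenes) rather than
        geographic degrees; controls the distance formula.
    migration_mode: "truncate" removes the departure (and any loop) and
        re-splits the remainder; "drop_track" discards the whole track.
    """

    max_speed_kmh: float = 9.9
    inner_angle_deg: float = 90.0
    gap_hours: float = 72.0
    min_locations: int = 20
    burn_in_hours: float = 24.0
    migration_km: float = 150.0
    retained_argos_classes: frozenset = RETAINED_ARGOS_CLASSES
    planar: bool = True
    migration_mode: str = "truncate"
    migration_home_km: float = 10.0

    def __post_init__(self):
        for name in ("max_speed_kmh", "inner_angle_deg", "gap_hours",
                     "min_locations", "migration_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.burn_in_hours < 0:  # 0 disables the burn-in entirely
            raise ValueError("burn_in_hours must be non-negative")


@dataclass
class Track:
    """One independent, cleaned track segment for one animal."""

    animal_id: object
    segment_id: int
    fixes: pd.DataFrame  # columns: timestamp, x, y, lc, tag_type
    planar: bool = True
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def positions(self) -> np.ndarray:
        return self.fixes[["x", "y"]].to_numpy(dtype=float)

    @property
    def times_h(self) -> np.ndarray:
        """Fix times in hours since the first fix."""
        t = pd.to_datetime(self.fixes["timestamp"]).to_numpy()
        return (t - t[0]) / np.timedelta64(1, "h")


def _dist_km(x0, y0, x1, y1, planar: bool):
    if planar:
        return np.hypot(np.asarray(x1) - x0, np.asarray(y1) - y0) / 1000.0
    lat0, lat1 = np.radians(y0), np.radians(y1)
    dlat = lat1 - lat0
    dlon = np.radians(np.asarray(x1) - x0)
    a = np.sin(dlat / 2) ** 2 + np.cos(lat0) * np.cos(lat1) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


# ---------------------------------------------------------------------------
# basic cleaning
# ---------------------------------------------------------------------------


def basic_clean(raw: pd.DataFrame, cfg: QcConfig) -> tuple[pd.DataFrame, dict]:
    """Remove empty/unparseable rows, exact duplicates, low-quality ARGOS
    classes, and each animal's burn-in window; sort by animal then time.

    Returns the cleaned table and a removal log (rule -> rows removed).
    """
    log: dict[str, int] = {}
    df = raw.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce")

    bad = df["timestamp"].isna() | df["lon"].isna() | df["lat"].isna()
    log["empty_or_invalid"] = int(bad.sum())
    df = df[~bad]

    n = len(df)
    df = df.drop_duplicates(subset=TELEMETRY_COLUMNS, keep="first")
    log["duplicates"] = n - len(df)

    keep = (df["tag_type"] != "ARGOS") | df["lc"].isin(cfg.retained_argos_classes)
    log["argos_class"] = int((~keep).sum())
    df = df[keep]

    df = df.sort_values(["animal_id", "timestamp"], kind="mergesort")
    first = df.groupby("animal_id")["timestamp"].transform("min")
    in_burn = (df["timestamp"] - first) < pd.Timedelta(hours=cfg.burn_in_hours)
    log["burn_in"] = int(in_burn.sum())
    df = df[~in_burn].reset_index(drop=True)
    return df, log


# ---------------------------------------------------------------------------
# speed / angle spike filter
# ---------------------------------------------------------------------------


def _leg_speeds_kmh(x, y, t_h, planar):
    """Speed of the leg into each fix (speed[i] = leg i-1 -> i); length n-1."""
    d = _dist_km(x[:-1], y[:-1], x[1:], y[1:], planar)
    dt = np.diff(t_h)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dt > 0, d / dt, np.inf)


def _inner_angles_deg(x, y):
    """Inner angle at each interior fix (index 1..n-2), degrees in [0, 180]."""
    ux, uy = x[:-2] - x[1:-1], y[:-2] - y[1:-1]
    vx, vy = x[2:] - x[1:-1], y[2:] - y[1:-1]
    dot = ux * vx + uy * vy
    nu = np.hypot(ux, uy)
    nv = np.hypot(vx, vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where((nu > 0) & (nv > 0), dot / (nu * nv), -1.0)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def speed_angle_filter(fixes: pd.DataFrame, cfg: QcConfig) -> tuple[pd.DataFrame, int]:
    """Iteratively remove speed/angle spikes from one time-sorted fix table.

    Per sweep: (a) drop every fix whose legs both run faster than
    ``max_speed_kmh`` (endpoints judged on their single leg); (b) drop every
    interior fix whose inner angle is sharper than ``inner_angle_deg`` while
    both adjacent legs exceed half the maximum speed. Sweeps repeat until a
    fixed point. Tables with fewer than 3 fixes are returned unchanged.
    """
    df = fixes.reset_index(drop=True)
    if len(df) < 3:
        return df, 0
    t = pd.to_datetime(df["timestamp"]).to_numpy()
    t_h = (t - t[0]) / np.timedelta64(1, "h")
    alive = np.ones(len(df), dtype=bool)
    x_all = df["x"].to_numpy(dtype=float)
    y_all = df["y"].to_numpy(dtype=float)

    changed = True
    while changed and alive.sum() >= 3:
        changed = False
        idx = np.where(alive)[0]
        x, y, th = x_all[idx], y_all[idx], t_h[idx]
        sp = _leg_speeds_kmh(x, y, th, cfg.planar)  # sp[i]: leg i -> i+1
        n = len(idx)
        viol = np.zeros(n, dtype=bool)
        # interior: both legs above max speed
        viol[1:-1] = (sp[:-1] > cfg.max_speed_kmh) & (sp[1:] > cfg.max_speed_kmh)
        if not viol.any():
            # endpoints (single adjacent leg), only once no interior spike
            # remains to explain the fast leg
            viol[0] = sp[0] > cfg.max_speed_kmh
            viol[-1] = sp[-1] > cfg.max_speed_kmh
        if not viol.any():
            ang = _inner_angles_deg(x, y)
            half = cfg.max_speed_kmh / 2.0
            viol[1:-1] = (ang < cfg.inner_angle_deg) & (sp[:-1] > half) & (sp[1:] > half)
        if viol.any():
            alive[idx[viol]] = False
            changed = True
    removed = int((~alive).sum())
    return df[alive].reset_index(drop=True), removed


# ---------------------------------------------------------------------------
# land filter
# ---------------------------------------------------------------------------


def remove_terrestrial(fixes: pd.DataFrame, scene: Scene) -> tuple[pd.DataFrame, dict]:
    """Drop fixes whose containing pixel is land; fixes outside the mask
    extent are also dropped, counted separately. Pixel-centre containment:
    a coordinate belongs to the pixel whose cell contains it (boundary
    coordinates fall in the cell to their upper-right)."""
    x = fixes["x"].to_numpy(dtype=float)
    y = fixes["y"].to_numpy(dtype=float)
    row, col = scene.grid.world_to_rowcol(x, y)
    inb = scene.grid.in_bounds(row, col)
    on_land = np.zeros(len(fixes), dtype=bool)
    on_land[inb] = scene.land_mask[row[inb], col[inb]]
    log = {"on_land": int(on_land.sum()), "outside_mask": int((~inb).sum())}
    return fixes[inb & ~on_land].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# independence splitting
# ---------------------------------------------------------------------------


def split_and_trim(fixes: pd.DataFrame, cfg: QcConfig,
                   animal_id=None) -> tuple[list[Track], int]:
    """Split one animal's time-sorted fixes at every gap strictly longer than
    ``gap_hours``; keep only segments with strictly more than ``min_locations``
    fixes. Returns retained Tracks (sequential segment ids) and the count of
    fixes discarded with short segments."""
    df = fixes.reset_index(drop=True)
    if animal_id is None and len(df):
        animal_id = df["animal_id"].iloc[0] if "animal_id" in df else None
    if df.empty:
        return [], 0
    t = pd.to_datetime(df["timestamp"]).to_numpy()
    gaps = np.diff(t) / np.timedelta64(1, "h")
    breaks = np.where(gaps > cfg.gap_hours)[0]
    bounds = np.concatenate([[0], breaks + 1, [len(df)]])
    tracks: list[Track] = []
    dropped = 0
    seg = 0
    for a, b in zip(bounds[:-1], bounds[1:]):
        piece = df.iloc[a:b]
        if len(piece) > cfg.min_locations:
            tracks.append(Track(animal_id=animal_id, segment_id=seg,
                                fixes=piece.reset_index(drop=True), planar=cfg.planar))
            seg += 1
        else:
            dropped += len(piece)
    return tracks, dropped


# ---------------------------------------------------------------------------
# migration removal
# ---------------------------------------------------------------------------


def remove_migrations(tracks: list[Track], cfg: QcConfig) -> tuple[list[Track], dict]:
    """Truncate long directed departures (> ``migration_km`` from the track
    start).

    Onset is the last fix still within ``migration_home_km`` of the
    pre-departure centroid; everything from the onset to the point of return
    (back within home range), or to the end of the track when the animal never
    returns, is removed. The remainder is re-split so that any retained
    post-return piece must independently satisfy the gap and minimum-length
    rules. With ``migration_mode="drop_track"`` the whole track is discarded
    instead.
    """
    out: list[Track] = []
    log = {"migration_fixes_removed": 0, "migration_tracks_dropped": 0}
    for tr in tracks:
        pieces = _strip_departures(tr, cfg, log)
        out.extend(pieces)
    # renumber segments sequentially per animal
    counter: dict[object, int] = {}
    for tr in out:
        seg = counter.get(tr.animal_id, 0)
        tr.segment_id = seg
        counter[tr.animal_id] = seg + 1
    return out, log


def _strip_departures(tr: Track, cfg: QcConfig, log: dict) -> list[Track]:
    df = tr.fixes
    for _ in range(10):  # a track may hold several departures
        x = df["x"].to_numpy(dtype=float)
        y = df["y"].to_numpy(dtype=float)
        d0 = _dist_km(x[0], y[0], x, y, cfg.planar)
        far = np.where(d0 > cfg.migration_km)[0]
        if far.size == 0:
            break
        if cfg.migration_mode == "drop_track":
            log["migration_tracks_dropped"] += 1
            log["migration_fixes_removed"] += len(df)
            return []
        j = int(far[0])
        cx, cy = x[:j].mean(), y[:j].mean()
        dc = _dist_km(cx, cy, x, y, cfg.planar)
        near = np.where(dc[:j] <= cfg.migration_home_km)[0]
        onset = int(near[-1]) if near.size else 0
        back = np.where(dc <= cfg.migration_home_km)[0]
        back = back[back > j]
        if back.size:
            ret = int(back[0])
            keep = np.concatenate([np.arange(onset + 1), np.arange(ret, len(df))])
        else:
            keep = np.arange(onset + 1)
        log["migration_fixes_removed"] += len(df) - len(keep)
        df = df.iloc[keep].reset_index(drop=True)
        if df.empty:
            return []
    pieces, dropped = split_and_trim(df, cfg, animal_id=tr.animal_id)
    log["migration_fixes_removed"] += dropped
    for p in pieces:
        p.provenance = dict(tr.provenance)
    return pieces


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def run_qc(raw: pd.DataFrame, cfg: QcConfig,
           scene: Scene | None = None) -> tuple[list[Track], dict]:
    """Full QC pipeline: basic_clean -> speed/angle filter -> land filter ->
    split_and_trim -> remove_migrations.

    Returns cleaned Tracks and a provenance log satisfying
    ``input rows == surviving fixes + sum(removals)``.
    """
    n_in = len(raw)
    df, log = basic_clean(raw, cfg)
    df = df.rename(columns={"lon": "x", "lat": "y"})

    kept_frames = []
    log["speed_angle"] = 0
    for _, sub in df.groupby("animal_id", sort=True):
        filt, nrem = speed_angle_filter(sub, cfg)
        log["speed_angle"] += nrem
        kept_frames.append(filt)
    df = pd.concat(kept_frames, ignore_index=True) if kept_frames else df.iloc[:0]

    if scene is not None:
        df, land_log = remove_terrestrial(df, scene)
        log.update(land_log)

    tracks: list[Track] = []
    log["short_segment"] = 0
    for animal, sub in df.groupby("animal_id", sort=True):
        trs, dropped = split_and_trim(sub, cfg, animal_id=animal)
        log["short_segment"] += dropped
        tracks.extend(trs)

    tracks, mig_log = remove_migrations(tracks, cfg)
    log.update(mig_log)

    n_out = sum(len(t) for t in tracks)
    log["input_rows"] = n_in
    log["output_rows"] = n_out
    for t in tracks:
        t.provenance = dict(log)
    assert n_in == n_out + sum(
        v for k, v in log.items() if k not in ("input_rows", "output_rows")), log
    return tracks, log
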