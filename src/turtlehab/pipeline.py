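"""End-to-end study driver on synthetic scenes.

Chains every stage — scene generation, habitat-biased track simulation,
telemetry degradation, QC, regularization, CRW pseudo-absences, annotation,
collinearity screening, cross-validated boosted-tree fitting and suitability
mapping — with all randomness derived from one seed. Used by the acceptance
machinery and convenient for experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import brt_engine, env_annotate, habitat_map, pseudo_absence
from . import synthetic_data as sd
from . import regularize as rg
from . import track_qc as qc

__all__ = ["StudyConfig", "StudyResult", "run_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Study conditions for one synthetic end-to-end run.

    The defaults are the package's reference conditions: a 128x128 scene of
    500-m pixels with 24 dynamic dates, 15 animals tracked for 600 true fixes
    at 2-h intervals (~50 days), 9 CRW pseudo-absence simulations per track,
    and the habitat-model hyper-parameters (tree complexity 5, learning rate
    0.005, bag fraction 0.75, five folds) with the tree budget capped at
    2,000 for tractable runtimes.
    """

    n_rows: int = 128
    n_cols: int = 128
    n_dates: int = 24
    n_animals: int = 15
    steps_per_animal: int = 600
    n_sims: int = 9
    tree_complexity: int = 5
    learning_rate: float = 0.005
    max_trees: int = 2000
    bag_fraction: float = 0.75
    n_folds: int = 5
    run_mapping: bool = True


@dataclass
class StudyResult:
    scene: object
    truth: object
    qc_log: dict
    reg_log: dict
    table: object
    screen_report: object
    cv: object
    model: object
    influence: pd.Series
    metrics: dict
    truth_rank: list
    bhattacharyya: dict = field(default_factory=dict)
    mapping: dict = field(default_factory=dict)


def _sub_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31 - 1)) for s in state]


def run_study(seed: int, cfg: StudyConfig = StudyConfig()) -> StudyResult:
    """Run the whole pipeline once; deterministic given ``seed``."""
    s_scene, s_tracks, s_degrade, s_abs, s_fit = _sub_seeds(seed, 5)

    scene = sd.build_scene(s_scene, cfg.n_rows, cfg.n_cols, cfg.n_dates)
    truth = sd.default_truth()
    paths = sd.simulate_tracks(scene, truth, cfg.n_animals,
                               cfg.steps_per_animal, seed=s_tracks)
    raw = sd.degrade_telemetry(paths, sd.ErrorModel(), seed=s_degrade)

    tracks, qc_log = qc.run_qc(raw, qc.QcConfig(), scene)
    rts, reg_log = rg.regularize_tracks(tracks)
    if not rts:
        raise RuntimeError("no track survived regularization")

    sets = pseudo_absence.generate_absence_sets(rts, scene, n_sims=cfg.n_sims,
                                                seed=s_abs)
    pts = pd.concat([pseudo_absence.presence_table(rts),
                     pseudo_absence.absence_table(sets)], ignore_index=True)
    table = env_annotate.annotate(pts, scene)
    table, _ = env_annotate.temporal_clip(table, scene.coverage)
    table, _ = table.dropna_rows()
    table, screen_report = env_annotate.correlation_screen(table)

    brt_cfg = brt_engine.BrtConfig(
        tree_complexity=cfg.tree_complexity, learning_rate=cfg.learning_rate,
        max_trees=cfg.max_trees, bag_fraction=cfg.bag_fraction,
        n_folds=cfg.n_folds, seed=s_fit)
    cv = brt_engine.cross_validate(table, brt_cfg)
    model = brt_engine.fit(table, brt_cfg)
    influence = brt_engine.relative_influence(model)
    metrics = cv.mean_metrics

    truth_rank = [influence.index.get_loc(p) + 1
                  for p in truth.active_predictors if p in influence.index]

    bc = {}
    pres = table.data["label"] == 1
    for p in truth.active_predictors:
        if p in table.predictors:
            bc[p] = env_annotate.bhattacharyya(table.data.loc[pres, p],
                                               table.data.loc[~pres, p])

    mapping = {}
    if cfg.run_mapping:
        d_a, d_b = scene.dates[0], scene.dates[-1]
        surf_a = habitat_map.predict_surface(model, scene, d_a)
        surf_b = habitat_map.predict_surface(model, scene, d_b)
        area_b, pct_b = habitat_map.suitable_area(surf_b)
        change = habitat_map.temporal_change(surf_a, surf_b)
        g = scene.grid
        zones = [
            ("protection_zone", _box(g, 0.45, 0.0, 1.0, 1.0)),
            ("port_area", _box(g, 0.0, 0.0, 0.45, 0.35)),
        ]
        zt = habitat_map.zone_overlap(surf_b, zones)
        mapping = {"surface_a": surf_a, "surface_b": surf_b,
                   "area_km2": area_b, "area_percent": pct_b,
                   "change": change, "zones": zt}

    return StudyResult(scene=scene, truth=truth, qc_log=qc_log, reg_log=reg_log,
                       table=table, screen_report=screen_report, cv=cv,
                       model=model, influence=influence, metrics=metrics,
                       truth_rank=truth_rank, bhattacharyya=bc, mapping=mapping)


def _box(grid, fx0, fy0, fx1, fy1):
    from shapely.geometry import box
    w = grid.n_cols * grid.pixel_size
    h = grid.n_rows * grid.pixel_size
    return box(grid.x0 + fx0 * w, grid.y0 + fy0 * h,
               grid.x0 + fx1 * w, grid.y0 + fy1 * h)
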