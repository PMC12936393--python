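"""Correlated-random-walk pseudo-absences.

True absences are unobservable for a tracked animal, so the contrast class
is simulated: for every regularized presence track, correlated random walks
(CRWs) resample that track's own empirical step lengths and turning angles,
start at the track's first estimated position with a uniform initial
heading, and copy its timestamp grid. Candidate points falling on land are
redrawn, so simulated tracks share the movement signature of the presences
while being free to wander into habitat the animal did not use.

Step lengths and turning angles are resampled independently (the joint
option is exposed for sensitivity checks). The number of simulations per
presence track defaults to 9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regularize import RegularizedTrack
from .synthetic_data import Scene

__all__ = ["MoveStats", "AbsenceSet", "extract_move_stats", "simulate_crw",
           "generate_absence_sets", "presence_table", "absence_table"]

DEFAULT_N_SIMS = 9


@dataclass
class MoveStats:
    """Empirical movement signature of one regularized track: step lengths
    (metres per timestep) and signed turning angles (radians in (-pi, pi])."""

    step_lengths: np.ndarray
    turning_angles: np.ndarray
    n_degenerate_angles: int = 0


@dataclass
class AbsenceSet:
    """CRW pseudo-absences paired to one source track; ``points`` has one
    block of source-grid timestamps per simulation."""

    animal_id: object
    segment_id: int
    n_sims: int
    points: pd.DataFrame  # sim_id, timestamp, x, y


def _wrap_angle(a):
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def extract_move_stats(rt: RegularizedTrack) -> MoveStats:
    """Step lengths and turning angles of a regularized track.

    Steps are successive displacement norms (n-1 of them); angles are the
    signed heading change between successive steps (n-2). Zero-length steps
    have no heading: the angles touching them are skipped and counted.
    """
    xy = rt.positions
    if len(xy) < 4:
        raise ValueError("need at least 4 estimates to extract movement statistics")
    d = np.diff(xy, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    ok = steps > 0
    headings = np.arctan2(d[:, 1], d[:, 0])
    valid_pair = ok[:-1] & ok[1:]
    angles = _wrap_angle(np.diff(headings))[valid_pair]
    return MoveStats(step_lengths=steps, turning_angles=angles,
                     n_degenerate_angles=int((~valid_pair).sum()))


def simulate_crw(ms: MoveStats, start, timestamps, land_mask_scene: Scene,
                 seed, max_tries: int = 100) -> pd.DataFrame:
    """One CRW simulation on the source track's timestamp grid.

    The initial heading is uniform; each subsequent point resamples (with
    replacement) one empirical step length and one empirical turning angle.
    A candidate on land (or off the grid) is redrawn, up to ``max_tries``
    times; when the draws are exhausted the heading is reflected by pi and
    the walk continues. Deterministic given the seed.
    """
    if max_tries < 1:
        raise ValueError("max_tries must be >= 1")
    scene = land_mask_scene
    x0, y0 = float(start[0]), float(start[1])
    if scene.on_land([x0], [y0])[0]:
        raise ValueError("CRW start position is on land")
    rng = np.random.default_rng(seed)
    n = len(timestamps)
    xs = np.empty(n)
    ys = np.empty(n)
    xs[0], ys[0] = x0, y0
    heading = rng.uniform(-np.pi, np.pi)
    steps = ms.step_lengths
    angles = ms.turning_angles
    for i in range(1, n):
        placed = False
        for _ in range(max_tries):
            length = steps[rng.integers(len(steps))]
            turn = angles[rng.integers(len(angles))] if len(angles) else 0.0
            h = heading + turn
            cx = xs[i - 1] + length * math.cos(h)
            cy = ys[i - 1] + length * math.sin(h)
            if not scene.on_land([cx], [cy])[0]:
                xs[i], ys[i] = cx, cy
                heading = h
                placed = True
                break
        if not placed:
            heading = heading + np.pi
            xs[i], ys[i] = xs[i - 1], ys[i - 1]
    return pd.DataFrame({"timestamp": np.asarray(timestamps), "x": xs, "y": ys})


def generate_absence_sets(rts: list[RegularizedTrack], scene: Scene,
                          n_sims: int = DEFAULT_N_SIMS, seed: int = 0,
                          max_tries: int = 100) -> list[AbsenceSet]:
    """n_sims independent CRWs per source track.

    Per-simulation seeds derive deterministically from (seed, track index,
    sim index) via a seed sequence, so the whole collection is reproducible
    and individual simulations are independent.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    out: list[AbsenceSet] = []
    for k, rt in enumerate(rts):
        ms = extract_move_stats(rt)
        start = rt.positions[0]
        ts = rt.estimates["timestamp"].to_numpy()
        frames = []
        for s in range(n_sims):
            child_seed = np.random.SeedSequence(entropy=seed, spawn_key=(k, s))
            sim = simulate_crw(ms, start, ts, scene, child_seed, max_tries=max_tries)
            sim.insert(0, "sim_id", s)
            frames.append(sim)
        pts = pd.concat(frames, ignore_index=True)
        out.append(AbsenceSet(animal_id=rt.animal_id, segment_id=rt.segment_id,
                              n_sims=n_sims, points=pts))
    return out


def presence_table(rts: list[RegularizedTrack]) -> pd.DataFrame:
    """Stack regularized estimates as labelled presences (label=1)."""
    frames = []
    for rt in rts:
        df = rt.estimates[["timestamp", "x", "y"]].copy()
        df.insert(0, "segment_id", rt.segment_id)
        df.insert(0, "animal_id", rt.animal_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["label"] = 1
    return out


def absence_table(sets: list[AbsenceSet]) -> pd.DataFrame:
    """Stack AbsenceSets as labelled pseudo-absences (label=0)."""
    frames = []
    for ab in sets:
        df = ab.points[["timestamp", "x", "y", "sim_id"]].copy()
        df.insert(0, "segment_id", ab.segment_id)
        df.insert(0, "animal_id", ab.animal_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["label"] = 0
    return out
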