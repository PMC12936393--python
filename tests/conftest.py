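"""Shared fixtures: one small synthetic scene and the pipeline stages built
from it, session-scoped so the chain is computed once."""

import numpy as np
import pandas as pd
import pytest

import turtlehab as th


@pytest.fixture(scope="session")
def scene():
    return th.build_scene(seed=1, n_rows=64, n_cols=64, n_dates=12)


@pytest.fixture(scope="session")
def truth():
    return th.default_truth()


@pytest.fixture(scope="session")
def paths(scene, truth):
    return th.simulate_tracks(scene, truth, n_animals=5, steps_per_animal=200, seed=2)


@pytest.fixture(scope="session")
def raw(paths):
    return th.degrade_telemetry(paths, th.ErrorModel(), seed=3)


@pytest.fixture(scope="session")
def qc_result(raw, scene):
    return th.run_qc(raw, th.QcConfig(), scene)


@pytest.fixture(scope="session")
def tracks(qc_result):
    return qc_result[0]


@pytest.fixture(scope="session")
def regularized(tracks):
    rts, _ = th.regularize_tracks(tracks)
    assert rts, "no track survived regularization"
    return rts


@pytest.fixture(scope="session")
def absence_sets(regularized, scene):
    return th.generate_absence_sets(regularized, scene, n_sims=9, seed=5)


@pytest.fixture(scope="session")
def annotated(regularized, absence_sets, scene):
    pts = pd.concat([th.presence_table(regularized), th.absence_table(absence_sets)],
                    ignore_index=True)
    table = th.annotate(pts, scene)
    table, _ = th.env_annotate.temporal_clip(table, scene.coverage)
    table, _ = table.dropna_rows()
    return table


@pytest.fixture(scope="session")
def screened(annotated):
    table, _ = th.correlation_screen(annotated)
    return table


@pytest.fixture(scope="session")
def small_model(screened):
    cfg = th.BrtConfig(learning_rate=0.05, max_trees=150, seed=1)
    return th.fit(screened, cfg)


def make_separable_table(n=2000, p=5, seed=0, informative="x0"):
    """Synthetic design matrix where y = 1{informative > 0}; the other
    predictors are independent noise."""
    rng = np.random.default_rng(seed)
    cols = {f"x{i}": rng.standard_normal(n) for i in range(p)}
    df = pd.DataFrame(cols)
    df["label"] = (df[informative] > 0).astype(float)
    return th.AnnotatedTable(df, predictors=list(cols))


def make_logistic_table(n=5000, seed=0, beta=(1.5, -1.0), intercept=-0.5):
    """Smooth logistic ground truth in two predictors plus one noise column;
    returns (table, true probability vector)."""
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal(n)
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    eta = intercept + beta[0] * x0 + beta[1] * x1
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.uniform(size=n) < p).astype(float)
    df = pd.DataFrame({"x0": x0, "x1": x1, "x2": x2, "label": y})
    return th.AnnotatedTable(df, predictors=["x0", "x1", "x2"]), p
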