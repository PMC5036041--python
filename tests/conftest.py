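"""Shared fixtures.

The expensive end-to-end objects (texture model, two-population study,
rotation study) are session-scoped and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import colonymorph as cm
from colonymorph.pipeline import (
    run_rotation_study,
    run_two_population_study,
    train_default_texture_model,
)

STUDY_SEED = 1
ROTATION_SEED = 99
MODEL_SEED = 7


@pytest.fixture(scope="session")
def texture_model():
    return train_default_texture_model(seed=MODEL_SEED)


@pytest.fixture(scope="session")
def study(texture_model):
    """Two-population benchmark study: DB from one draw, held-out from another."""
    return run_two_population_study(
        n_per_class=20, effect=1.0, seed=STUDY_SEED, holdout=True,
        model=texture_model,
    )


@pytest.fixture(scope="session")
def rotation_result(study):
    return run_rotation_study(
        study.db, study.model, n_colonies=15, effect=1.0, seed=ROTATION_SEED
    )


@pytest.fixture(scope="session")
def small_db():
    """Small constructed reference DB for classifier tests."""
    from colonymorph.db import ColonyDB, standardize

    rng = np.random.default_rng(10)
    n, p = 30, 8
    raw = rng.normal(loc=10, scale=3, size=(n, p))
    _, stats = standardize(raw)
    names = [f"par{j}" for j in range(p)]
    ids = [f"db{i:02d}" for i in range(n)]
    labels = {cid: ("A" if i < 15 else "B") for i, cid in enumerate(ids)}
    return ColonyDB(
        colony_ids=ids,
        parameter_names=names,
        matrix=raw,
        standardization=stats,
        cluster_label_of=labels,
        major_labels=["A", "B"],
    )


@pytest.fixture(scope="session")
def single_disk_scene():
    """Noise-free single circular colony with ground truth."""
    spec = cm.SceneSpec(
        image_size_px=(700, 700),
        colonies=(
            cm.ColonySpec(center_px=(350.0, 350.0), base_radius_px=260.0),
        ),
        debris_count=0,
        background_gradient_amplitude=0.0,
        noise_sd=0.0,
        seed=12,
    )
    image, gt = cm.render_scene(spec)
    return spec, image, gt


def disk_mask(shape=(401, 401), center=(200.0, 200.0), radius=150.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= radius


def star_mask(shape=(401, 401), center=(200.0, 200.0), r0=130.0, spikes=8, amp=0.35):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    rho = np.hypot(yy - center[0], xx - center[1])
    theta = np.arctan2(yy - center[0], xx - center[1])
    return rho <= r0 * (1 + amp * np.cos(spikes * theta))
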