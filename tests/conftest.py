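"""Shared fixtures: the packaged synthetic movies, generated at test time."""

import numpy as np
import pytest

import radmig as rm

CANONICAL_SEED = 0


@pytest.fixture(scope="session")
def lum_fixture():
    """Packaged luminescence fixture: default SimParams, canonical seed.

    Returns (params, label stack, luminescence stack, truth, annotation).
    """
    params = rm.SimParams(seed=CANONICAL_SEED)
    label, truth = rm.generate_migration_movie(params)
    lum = rm.generate_luminescence_movie(params, truth)
    return params, label, lum, truth, rm.default_annotation(params)


def migration_params(seed: int, v_mean: float = 10.0, n_cells: int = 20,
                     v_sd: float = 1.0) -> rm.SimParams:
    """The tracking fixture: 24 h movie, 2 um/px, cells well separated."""
    return rm.SimParams(image_shape=(224, 256), pixel_size_um=2.0,
                        n_frames=49, frame_interval_h=0.5, n_cells=n_cells,
                        velocity_um_per_h=(v_mean, v_sd), jitter_px_sd=1.0,
                        start_row_range=(140, 215), transition_row=104,
                        burst_band_rows=(40, 168), seed=seed)


@pytest.fixture(scope="session")
def migration_fixture():
    """20 cells at true 10 um/h with 1 px jitter (tracking fixture)."""
    params = migration_params(seed=3)
    stack, truth = rm.generate_migration_movie(params)
    return params, stack, truth, rm.default_annotation(params)


@pytest.fixture()
def flat_annotation():
    """Simple pia-up annotation for a 64-row image."""
    return rm.LayerAnnotation(pial_row=0, ventricular_row=63,
                              sp_center_row=30, radial_up=True)
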