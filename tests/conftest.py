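"""Shared fixtures: canonical synthetic scenes reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from dropletbench import GridSpec, SceneSpec, arrange_lattice, render_scene


@pytest.fixture(scope="session")
def grid16() -> GridSpec:
    """Electrode grid comfortably holding a 4 x 4 lattice at 4-electrode spacing."""
    return GridSpec(n_cols=22, n_rows=22, pitch_px=16)


@pytest.fixture(scope="session")
def lattice16(grid16):
    return tuple(arrange_lattice(grid16, 4, 4, 4))


@pytest.fixture(scope="session")
def scene16(grid16, lattice16):
    """Default 16-droplet scene with identical nominal radii (radius_cv = 0)."""
    spec = SceneSpec(grid=grid16, droplet_centers=lattice16, droplet_radius_cv=0.0, seed=7)
    return render_scene(spec)


@pytest.fixture(scope="session")
def poisson_scene():
    """10^4 droplets loaded at lambda = 1.3 for occupancy statistics."""
    grid = GridSpec(n_cols=100, n_rows=100, pitch_px=8)
    centers = tuple(arrange_lattice(grid, 100, 100, 0, origin_electrode=(0, 0)))
    spec = SceneSpec(
        grid=grid,
        droplet_centers=centers,
        droplet_radius_mean_px=3.0,
        droplet_radius_cv=0.0,
        cell_rate_lambda=1.3,
        cell_radius_px=0.8,
        blur_sigma_px=0.0,
        noise_sigma=0.0,
        seed=5,
    )
    return render_scene(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
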