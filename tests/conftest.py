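"""Shared fixtures: tiny synthetic cohorts and simple geometric masks."""

from __future__ import annotations

import numpy as np
import pytest

from gbp_radiomics.synthdata import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12-lesion cohort, fixed seed; enough for structural checks."""
    spec = CohortSpec(n_lesions=12, n_neoplastic=4, seed=41)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_lesions=12, n_neoplastic=4, seed=41)


@pytest.fixture()
def square_contour():
    """Axis-aligned square with corners (10,10)-(20,20): rasterizes to 100 px."""
    return np.array([[10.0, 10.0], [10.0, 20.0], [20.0, 20.0], [20.0, 10.0]])


@pytest.fixture()
def disc_mask():
    """Filled disc of radius 10 px centered in a 64x64 grid."""
    yy, xx = np.mgrid[0:64, 0:64]
    return (xx - 32) ** 2 + (yy - 32) ** 2 <= 10**2


def rng_polygon(rng: np.random.Generator, n_vertices: int = 12,
                center=(32.0, 32.0), r_range=(6.0, 20.0)) -> np.ndarray:
    """Random simple (star-shaped) polygon inside a 64x64 grid."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(*r_range, n_vertices)
    return np.column_stack(
        [center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles)]
    )
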