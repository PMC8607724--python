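import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # oracle helpers

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

from tomoqa.dose import DoseGrid, DosePointSet, DetectorGeometry
from tomoqa.synthetic import GaussianBlobSpec, PerturbationSpec, make_dose_pair


@pytest.fixture
def uniform_grid():
    """Flat 2 Gy field, 40x40 mm at 2 mm spacing."""
    return DoseGrid(np.full((21, 21), 2.0), (2.0, 2.0), (0.0, 0.0))


@pytest.fixture
def small_geometry():
    """Detector small enough to sit inside test-sized fields."""
    return DetectorGeometry(
        cylinder_radius_mm=5.0,
        axial_spacing_mm=10.0,
        circumferential_spacing_mm=10.0,
        axial_extent_mm=40.0,
    )


@pytest.fixture
def blob_pair_factory():
    """Synthetic (plan grid, measured points) pairs with known perturbation."""

    def make(seed=0, **perturbation_kwargs):
        base = GaussianBlobSpec(extent_u_mm=90.0, extent_v_mm=90.0, seed=seed)
        pert = PerturbationSpec(seed=seed + 1000, **perturbation_kwargs)
        return make_dose_pair(base, pert)

    return make


@pytest.fixture
def interior_points_factory():
    """Random reference points well inside a grid, doses near the planned ones."""

    def make(grid, n=5, dose_jitter=0.05, seed=0, margin=9.0):
        rng = np.random.default_rng(seed)
        (ylo, yhi), (xlo, xhi) = grid.extent_mm(0), grid.extent_mm(1)
        u = rng.uniform(xlo + margin, xhi - margin, n)
        v = rng.uniform(ylo + margin, yhi - margin, n)
        d = grid.interpolator()(np.column_stack([v, u]))
        d = np.abs(d * (1.0 + dose_jitter * rng.standard_normal(n)))
        return DosePointSet(u, v, d)

    return make
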