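"""Shared fixtures: one small seeded landscape reused across the suite."""

import numpy as np
import pytest

import stresscape as sc


@pytest.fixture(scope="session")
def small_spec() -> sc.LandscapeSpec:
    return sc.LandscapeSpec(
        extent=(0.0, 0.0, 30000.0, 30000.0),
        seed=7,
        n_wells=5,
        park_count=2,
        park_size_range=(4000.0, 9000.0),
        harvest_fraction=0.08,
    )


@pytest.fixture(scope="session")
def fields(small_spec) -> sc.CovariateStack:
    return sc.generate_fields(small_spec)


@pytest.fixture(scope="session")
def vectors(small_spec) -> dict:
    return sc.generate_vectors(small_spec)


@pytest.fixture(scope="session")
def stack(fields, vectors, small_spec) -> sc.CovariateStack:
    return sc.build_standard_stack(fields, vectors, small_spec.reference_year)


@pytest.fixture(scope="session")
def pattern_truth(stack) -> tuple:
    model = sc.GenerativeModel(
        coefficients={"elev": 0.4, "cc": 0.25, "pa": 0.3},
        noise_sd=0.35,
    )
    return sc.generate_hcc_points(stack, model, 150, seed=11)


@pytest.fixture(scope="session")
def pattern(pattern_truth) -> sc.MarkedPointPattern:
    return pattern_truth[0]


def make_template(nrows=10, ncols=10, cell=1000.0, x0=0.0, y1=None):
    """Small helper grid with cell centres at (x0+(j+.5)c, y1-(i+.5)c)."""
    y1 = y1 if y1 is not None else nrows * cell
    return sc.GridRaster(
        values=np.zeros((nrows, ncols)), x_origin=x0, y_origin=y1,
        cell_size=cell,
    )


@pytest.fixture
def template():
    return make_template()
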