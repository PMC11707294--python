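"""Shared fixtures: small phantoms reused across test modules."""

import numpy as np
import pytest

import memflat as mf


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Open cylindrical membrane patch (no particles, no noise)."""
    spec = mf.PhantomSpec(shape="circular_cylinder", dims=(120, 160, 110), radius=50.0,
                          center=(60.0, 79.5, 20.0), angle_limit_deg=60, seed=2,
                          make_mesh=True)
    tomo, mask, surf, truth, mesh = mf.make_phantom(spec)
    return {"spec": spec, "tomo": tomo, "mask": mask, "surf": surf, "mesh": mesh}


@pytest.fixture(scope="session")
def cylinder_flat(cylinder_phantom):
    """Cylinder phantom flattened through the polynomial-cylinder pathway."""
    fm, flat, fits = mf.flatten_volume(
        cylinder_phantom["tomo"], cylinder_phantom["surf"], mode="poly",
        surface_kind="poly", poly_degree=8, cyl_degree=6, w_t=10)
    return {"fm": fm, "flat": flat, **fits, **cylinder_phantom}


@pytest.fixture(scope="session")
def plane_phantom():
    spec = mf.PhantomSpec(shape="plane", dims=(48, 48, 32), z0=16.0, seed=1)
    tomo, mask, surf, truth, _ = mf.make_phantom(spec)
    return {"spec": spec, "tomo": tomo, "mask": mask, "surf": surf}


@pytest.fixture(scope="session")
def plane_flat(plane_phantom):
    fm, flat, fits = mf.flatten_volume(
        plane_phantom["tomo"], plane_phantom["surf"], mode="plane",
        surface_kind="poly", poly_degree=1, w_t=5)
    return {"fm": fm, "flat": flat, **fits, **plane_phantom}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
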