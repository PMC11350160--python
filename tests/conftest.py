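"""Shared fixtures: small Monte Carlo runs and IRFs reused across test modules.

Session scope amortises the transport cost; tests must not mutate fixtures.
"""

import pytest

from lungtdos import (
    DetectionGeometry,
    LayeredSlabMedium,
    OpticalProperties,
    TimeAxis,
    generate_irf,
    run_mc,
)


@pytest.fixture(scope="session")
def irf_10ps():
    """150 ps FWHM IRF on a 10 ps grid spanning [-1, 2] ns, peak at t = 0."""
    axis = TimeAxis(t0=-1.0, dt=0.010, n_channels=300)
    return generate_irf(axis, fwhm_ps=150.0, total_counts=1.0e6, seed=42)


@pytest.fixture(scope="session")
def mc_homog_rho3():
    """Homogeneous mus'=10 run, ring at rho=3 cm, 1e4 detected photons."""
    medium = LayeredSlabMedium.homogeneous(OpticalProperties(0.0, 10.0))
    geometry = DetectionGeometry(rho=3.0, t_max_record=6.0)
    res = run_mc(medium, geometry, 10_000, seed=5)
    assert res.complete
    return res


@pytest.fixture(scope="session")
def two_layer_medium():
    """Chest (mus'=7, 3 cm) over lung (mus'=12); mua 0.15 in both layers."""
    top = OpticalProperties(0.15, 7.0)
    lung = OpticalProperties(0.15, 12.0)
    return LayeredSlabMedium.two_layer(top, 3.0, lung)


@pytest.fixture(scope="session")
def mc_protocol_run(two_layer_medium):
    """Two-layer run at rho=6 cm feeding the synthetic protocol tests."""
    axis = TimeAxis.default(dt=0.050, t_span=7.0)
    geometry = DetectionGeometry(rho=6.0, t_max_record=axis.t_end + axis.dt)
    res = run_mc(two_layer_medium, geometry, 20_000, seed=21)
    assert res.complete
    return res


@pytest.fixture(scope="session")
def protocol_axis():
    return TimeAxis.default(dt=0.050, t_span=7.0)
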