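import numpy as np
import pytest

import pcdosim as pc


@pytest.fixture(scope="session")
def sphere_solver():
    """Rotationally invariant fixture: concentric spheres in a spherical body."""
    return pc.VirtualSolver(pc.sphere_fixture(), pc.SolverConfig())


@pytest.fixture(scope="session")
def coarse_9mo_solver():
    """9-month fixture with coarsened point clouds for fast whole-body sweeps."""
    ga = pc.ga_fixture("9mo", resolution_scale=2.5)
    return pc.VirtualSolver(ga, pc.SolverConfig())


@pytest.fixture(scope="session")
def whole_body_model(coarse_9mo_solver):
    """A converged whole-body surrogate at modest (N, p) for exposure statistics."""
    model, report = pc.adaptive_fit(coarse_9mo_solver, "whole_body",
                                    n_grid=[120], p_grid=[8],
                                    tau_percent=0.5, seeds={"validation": 11})
    assert report.converged
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(20150527)
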