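"""Shared fixtures. Everything stochastic is seeded; expensive simulated
artifacts are session-scoped so independent tests can share them."""

from __future__ import annotations

import numpy as np
import pytest

import trapswim as ts


@pytest.fixture(scope="session")
def size2_trap():
    """Geometry/wall/swimmer for the 12.8 µm study trap."""
    return dict(
        params=ts.SwimmerParams(v=40.0),
        geom=ts.TrapGeometry(Rtrap=12.8, H=10.0),
        wall=ts.WallModel(Aw=3.0, Tw=11.0),
        env=ts.Environment(),
    )


@pytest.fixture(scope="session")
def size2_trajectory(size2_trap):
    """One 40 s zero-field trajectory in the size-2 trap (seed 11)."""
    c = size2_trap
    return ts.simulate(
        c["params"], c["env"], c["geom"], c["wall"], duration=40.0, seed=11
    )


@pytest.fixture(scope="session")
def size2_track(size2_trajectory):
    """The same trajectory degraded into an experiment-like track."""
    return ts.degrade(size2_trajectory, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
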