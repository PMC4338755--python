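"""Shared fixtures.

The heavy session fixtures (998-node synthetic connectome, calibrated
coupling, healthy noise-scan totals) are built lazily and shared between the
property tests and the acceptance tests so each expensive simulation runs
once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import connectosim as cs


def make_random_connectome(n=12, density=0.4, seed=0, atlas=None):
    """Small random symmetric connectome for unit tests."""
    rng = np.random.Generator(np.random.Philox(seed))
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < density
    w[iu[mask], ju[mask]] = rng.uniform(0.05, 1.0, mask.sum())
    w += w.T
    coords = rng.uniform(-70, 70, (n, 3))
    labels = (
        atlas.node_labels()
        if atlas is not None
        else [f"rS{i % 3 + 1:02d}" for i in range(n)]
    )
    return cs.Connectome(w, coords, labels, atlas=atlas)


@pytest.fixture(scope="session")
def atlas():
    return cs.load_builtin_atlas()


@pytest.fixture()
def small_conn():
    return make_random_connectome(n=12, seed=42)


@pytest.fixture(scope="session")
def synthetic_conn():
    """Default 998-node synthetic connectome (the study network)."""
    return cs.generate(cs.SynthSpec(seed=1))


@pytest.fixture(scope="session")
def calibrated(synthetic_conn):
    """(connectome, params) with the coupling at the bifurcation edge."""
    params = cs.MeanFieldParams()
    g = cs.calibrate_g(synthetic_conn, params)
    from dataclasses import replace

    return synthetic_conn, replace(params, g=g)


#: Noise amplitudes scanned in the resting-state study.
STUDY_SIGMAS = (0.01, 0.05, 0.07, 0.1)
STUDY_SEEDS = tuple(range(5))


@pytest.fixture(scope="session")
def healthy_scan(calibrated):
    """Healthy resting-state totals: 10 s runs over sigmas x 5 seeds."""
    conn, params = calibrated
    cfg = cs.SimulationConfig(duration=10.0)
    return cs.noise_scan(conn, params, list(STUDY_SIGMAS), cfg, seeds=list(STUDY_SEEDS))
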