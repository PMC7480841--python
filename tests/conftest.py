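"""Shared fixtures: parameter sets and small tissue rigs."""

from __future__ import annotations

import numpy as np
import pytest

import wingdisc as wd
from wingdisc.builder import mini_config


@pytest.fixture()
def ep():
    return wd.default_energy_params()


@pytest.fixture()
def dp():
    return wd.default_damping_params()


@pytest.fixture(scope="session")
def mini_tissue_factory():
    """Builds a small three-ish-cell-wide tissue; returns fresh copies."""
    ep = wd.default_energy_params()
    cfg = mini_config(n_columnar=3, n_squamous=1, n_boundary_per_side=1,
                      nucleus_nodes_per_cell=4)
    base = wd.build_tissue(cfg, ep)

    def factory():
        return base.copy(), ep

    return factory


@pytest.fixture()
def jiggled_rig(mini_tissue_factory):
    """Small rig with randomized (but safely non-degenerate) positions.

    The perturbation is small enough that no Morse pair sits within a
    finite-difference step of its hard cutoff and no breakable spring of its
    break distance, so the energy is smooth around the configuration.
    """
    state, ep = mini_tissue_factory()
    rng = np.random.default_rng(42)
    state.pos = state.pos + rng.uniform(-0.03, 0.03, state.pos.shape)
    wd.refresh_pairs(state, ep)
    return state, ep
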