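"""Shared fixtures: small random states and reference oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

import polyphase as pp
from polyphase.engine import build_forcefield


@pytest.fixture(scope="session")
def params():
    return pp.EngineParams()


@pytest.fixture(scope="session")
def default_table():
    return pp.build_interaction_table(1.2, 0.5)


def random_state(
    n_chains=2, chain_len=10, box=60.0, seed=0, spread=8.0, roles=None
) -> pp.SystemState:
    """Loose random multi-chain state (NOT overlap-free; for oracle tests)."""
    rng = np.random.default_rng(seed)
    n = n_chains * chain_len
    centers = rng.uniform(0, box, size=(n_chains, 3))
    positions = np.concatenate(
        [c + rng.normal(scale=spread, size=(chain_len, 3)) for c in centers]
    )
    if roles is None:
        roles = np.tile(
            [int(r) for r in pp.default_chain_roles(chain_len, min(3, chain_len))],
            n_chains,
        )
    return pp.SystemState(
        positions=np.mod(positions, box),
        velocities=np.zeros((n, 3)),
        roles=np.asarray(roles),
        chain_id=np.repeat(np.arange(n_chains), chain_len),
        box_edge=box,
        time=0.0,
    )


def min_image(d, box):
    return d - box * np.round(d / box)


@pytest.fixture(scope="session")
def dimer_state(params):
    chain = pp.ChainSpec(roles=pp.default_chain_roles())
    return pp.build_contact_dimer(chain, params, box_edge=150.0, seed=7)


@pytest.fixture(scope="session")
def dimer_ff(dimer_state, default_table, params):
    return build_forcefield(dimer_state.roles, dimer_state.chain_id, default_table, params)
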