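"""Shared fixtures: hand-built trees and session-scoped simulation ensembles."""
from __future__ import annotations

import math

import numpy as np
import pytest

from tebbo import (
    Branch,
    GrowthParameters,
    OrganoidTree,
    SimulationConfig,
    run_ensemble,
)


def make_branch(
    id: int,
    nodes,
    width: float,
    parent_id: int | None = None,
    terminal: bool = True,
    broken: bool = False,
    birth_time: float = 0.0,
) -> Branch:
    """Build a branch whose volume follows the cylindrical closure."""
    nodes = np.asarray(nodes, dtype=float)
    if nodes.shape[0] > 1:
        length = float(np.linalg.norm(np.diff(nodes, axis=0), axis=1).sum())
    else:
        length = 1.0  # degenerate single-node branch used in edge-case tests
    return Branch(
        id=id,
        parent_id=parent_id,
        nodes=nodes,
        length=length,
        width=width,
        volume=math.pi / 4.0 * width**2 * length,
        birth_time=birth_time,
        terminal=terminal,
        broken=broken,
    )


def make_tree(branches, time: float = 0.0) -> OrganoidTree:
    return OrganoidTree(branches={b.id: b for b in branches}, time=time, rng_seed=0)


@pytest.fixture
def straight_tree():
    """Single straight 400 µm branch along +x, width 20 µm."""
    nodes = np.column_stack([np.linspace(0, 400, 41), np.zeros(41)])
    return make_tree([make_branch(0, nodes, width=20.0)])


@pytest.fixture
def y_tree():
    """100 µm trunk with two 100 µm daughters at ±60° (2D)."""
    trunk = np.column_stack([np.zeros(11), np.linspace(0, 100, 11)])
    s, c = math.sin(math.radians(60)), math.cos(math.radians(60))
    t = np.linspace(0, 100, 11)
    left = np.column_stack([-s * t, 100 + c * t])
    right = np.column_stack([s * t, 100 + c * t])
    return make_tree(
        [
            make_branch(0, trunk, width=30.0, terminal=False),
            make_branch(1, left, width=20.0, parent_id=0),
            make_branch(2, right, width=20.0, parent_id=0),
        ]
    )


@pytest.fixture(scope="session")
def calibrated_ensemble():
    """500 spatial runs at the calibrated extension-phase parameters,
    days 0–9, daily snapshots. Shared by the branching-rate, coupling,
    width-ordering and mean-field-consistency checks."""
    config = SimulationConfig(
        params=GrowthParameters(), duration=9.0, record_nodes=False, seed=0
    )
    return run_ensemble(config, 500, base_seed=20_000)
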