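"""Shared fixtures: tiny hand-built lattices and standard parameter sets."""

from __future__ import annotations

import numpy as np
import pytest

from cpmclusters.engine import (CellTypeSpec, ContactTable, Simulation,
                                TypeTable)

# the baseline contact energies of the active-motility regime
BASE_J = {("E", "E"): 2.0, ("E", "medium"): 20.0,
          ("H", "H"): 6.0, ("H", "medium"): 6.0, ("E", "H"): 6.0}


def make_types(T_E=1.0, T_H=1.0, lambda_area=1.0, target_area=25.0,
               lambda_perim=0.0, target_perim=0.0):
    return TypeTable([
        CellTypeSpec("E", T=T_E, lambda_area=lambda_area,
                     target_area=target_area),
        CellTypeSpec("H", T=T_H, lambda_area=lambda_area,
                     target_area=target_area, lambda_perim=lambda_perim,
                     target_perim=target_perim),
    ])


def make_sim(grid, type_of_cell, J=None, mu=None, seed=0, shell="dist2",
             perimeter="edge", tau=50, motility_mode="com", **type_kw):
    """Simulation from a hand-built grid.

    ``type_of_cell`` maps cell id -> "E" or "H" (id 0 is always medium).
    """
    types = make_types(**type_kw)
    contact = ContactTable(types, J or BASE_J)
    ncells = int(np.max(grid)) + 1
    cell_types = np.zeros(ncells, dtype=int)
    for cid, name in type_of_cell.items():
        cell_types[cid] = types.index(name)
    return Simulation(grid=np.asarray(grid, dtype=np.int64),
                      cell_types=cell_types, types=types, contact=contact,
                      mu=mu, tau=tau, shell=shell, perimeter=perimeter,
                      motility_mode=motility_mode, seed=seed)


def random_blob_grid(rng, n=24, ncells=6, growth_steps=160):
    """Small lattice of ragged but connected cells, for oracle tests.

    Seeds ``ncells`` single pixels and grows them by random boundary
    accretion, leaving irregular interfaces and plenty of medium.
    """
    grid = np.zeros((n, n), dtype=np.int64)
    seeds = rng.choice(n * n, size=ncells, replace=False)
    for cid, s in enumerate(seeds, start=1):
        grid[divmod(int(s), n)] = cid
    offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for _ in range(growth_steps):
        i, j = int(rng.integers(n)), int(rng.integers(n))
        if grid[i, j] == 0:
            di, dj = offs[int(rng.integers(4))]
            c = grid[(i + di) % n, (j + dj) % n]
            if c != 0:
                grid[i, j] = c
    return grid


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def two_cell_sim():
    """6x6 lattice holding one E and one H cell, hand-built."""
    grid = np.zeros((6, 6), dtype=np.int64)
    grid[1:3, 1:4] = 1          # E cell, 2x3
    grid[3:5, 2:4] = 2          # H cell, 2x2
    return make_sim(grid, {1: "E", 2: "H"}, target_area=6.0)
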