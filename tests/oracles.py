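"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — O(n^2 * shell) double loops and
pixel-level flood fills — and shares no code with the package's incremental
implementations.
"""

from __future__ import annotations

import numpy as np


def contact_energy(grid, ctype, J, offs):
    """Sum J over unordered neighbor pixel pairs with different cell index."""
    n = grid.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            c = grid[i, j]
            for di, dj in offs:
                i2, j2 = (i + di) % n, (j + dj) % n
                c2 = grid[i2, j2]
                if c != c2:
                    total += J[ctype[c], ctype[c2]]
    return total / 2.0  # every unordered pair visited twice


def area_energy(grid, ctype, lam_a, a0, ncells=None):
    # dead cells stay in the sum at area 0 (constant term), matching the
    # incremental convention
    if ncells is None:
        ncells = int(grid.max()) + 1
    areas = np.bincount(grid.ravel(), minlength=ncells)
    total = 0.0
    for c in range(1, ncells):
        d = areas[c] - a0[ctype[c]]
        total += lam_a[ctype[c]] * d * d
    return total


def perimeters(grid, poffs):
    """Per-cell count of shell neighbors holding a different cell index."""
    n = grid.shape[0]
    ncells = int(grid.max()) + 1
    p = np.zeros(ncells, dtype=int)
    for i in range(n):
        for j in range(n):
            c = grid[i, j]
            if c == 0:
                continue
            for di, dj in poffs:
                if grid[(i + di) % n, (j + dj) % n] != c:
                    p[c] += 1
    return p


def perimeter_energy(grid, ctype, lam_p, p0, poffs, ncells=None):
    p = perimeters(grid, poffs)
    if ncells is None:
        ncells = len(p)
    total = 0.0
    for c in range(1, ncells):
        pc = p[c] if c < len(p) else 0
        d = pc - p0[ctype[c]]
        total += lam_p[ctype[c]] * d * d
    return total


def total_hamiltonian(sim):
    """Full-recompute H from the simulation's raw arrays."""
    t = sim.types
    ncells = len(sim.area)
    return (contact_energy(sim.grid, sim.cell_types, sim.contact.J, sim.offs)
            + area_energy(sim.grid, sim.cell_types, t.lambda_area,
                          t.target_area, ncells)
            + perimeter_energy(sim.grid, sim.cell_types, t.lambda_perim,
                               t.target_perim, sim.poffs, ncells))


def com_displacement(grid_before, grid_after, cell, n):
    """Exact COM displacement of one compact cell across a single-pixel flip."""
    coords_b = np.argwhere(grid_before == cell).astype(float)
    coords_a = np.argwhere(grid_after == cell).astype(float)
    if len(coords_a) == 0 or len(coords_b) == 0:
        return np.zeros(2)
    ref = coords_b[0]
    unb = coords_b + n * np.floor((ref - coords_b) / n + 0.5)
    una = coords_a + n * np.floor((ref - coords_a) / n + 0.5)
    return una.mean(axis=0) - unb.mean(axis=0)


def flood_fill_components(grid, cell_ids, connectivity=4):
    """Pixel-level flood fill over the pixels of the given cells.

    Returns a list of frozensets of cell ids, one per pixel-connected
    component (periodic boundaries).
    """
    n = grid.shape[0]
    if connectivity == 4:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                if (di, dj) != (0, 0)]
    wanted = set(int(c) for c in cell_ids)
    pixels = {(i, j) for (i, j), c in np.ndenumerate(grid) if int(c) in wanted}
    seen = set()
    comps = []
    for start in sorted(pixels):
        if start in seen:
            continue
        stack = [start]
        seen.add(start)
        members = set()
        while stack:
            i, j = stack.pop()
            members.add(int(grid[i, j]))
            for di, dj in offs:
                q = ((i + di) % n, (j + dj) % n)
                if q in pixels and q not in seen:
                    seen.add(q)
                    stack.append(q)
        comps.append(frozenset(members))
    # merge components sharing a cell (a fragmented cell joins its islands)
    merged = True
    comps = [set(c) for c in comps]
    while merged:
        merged = False
        for a in range(len(comps)):
            for b in range(a + 1, len(comps)):
                if comps[a] & comps[b]:
                    comps[a] |= comps[b]
                    del comps[b]
                    merged = True
                    break
            if merged:
                break
    return sorted(frozenset(c) for c in comps)
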