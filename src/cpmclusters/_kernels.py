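"""Compiled primitives for the lattice Monte Carlo dynamics.

All mutable simulation state lives in flat numpy arrays owned by
:class:`cpmclusters.engine.Simulation`; the functions here are the single
implementation of the energy deltas and the cache updates.  They are driven
either one attempt at a time from Python (for tests and small systems) or by
the batched :func:`run_kernel` loop, which uses numba's internal seeded RNG.

Conventions baked in here:

* pixel (i, j) has center coordinate (i, j); the lattice is periodic,
* cell index 0 is the medium (unconstrained area/perimeter, never motile),
* per-cell center-of-mass sums are kept in unwrapped coordinates; a pixel
  entering or leaving a cell is assigned the periodic image closest to the
  cell's current center of mass (exact for any cell of diameter < n/2),
* perimeter is a count of pixel edges (over `poffs`) facing a different cell.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _wrap(i, n):
    if i >= n:
        return i - n
    if i < 0:
        return i + n
    return i


@njit(cache=True, inline="always")
def _nearest_image(x, ref, n):
    """Periodic image of coordinate ``x`` closest to ``ref``."""
    return x + n * np.floor((ref - x) / n + 0.5)


@njit(cache=True)
def delta_contact(grid, offs, ctype, J, tx, ty, old, new):
    """Contact-energy change from writing cell ``new`` into pixel (tx, ty).

    Only pairs involving the flipped pixel change, so a scan of its
    interaction shell is exact.
    """
    n = grid.shape[0]
    t_old = ctype[old]
    t_new = ctype[new]
    d = 0.0
    for k in range(offs.shape[0]):
        i = _wrap(tx + offs[k, 0], n)
        j = _wrap(ty + offs[k, 1], n)
        c = grid[i, j]
        tc = ctype[c]
        if c != new:
            d += J[t_new, tc]
        if c != old:
            d -= J[t_old, tc]
    return d


@njit(cache=True)
def delta_area(area, ctype, lam_a, a0, old, new):
    """Area-constraint change; the medium (index 0) is unconstrained."""
    d = 0.0
    if new != 0:
        t = ctype[new]
        if lam_a[t] != 0.0:
            a = float(area[new])
            up = a + 1.0 - a0[t]
            dn = a - a0[t]
            d += lam_a[t] * (up * up - dn * dn)
    if old != 0:
        t = ctype[old]
        if lam_a[t] != 0.0:
            a = float(area[old])
            up = a - 1.0 - a0[t]
            dn = a - a0[t]
            d += lam_a[t] * (up * up - dn * dn)
    return d


@njit(cache=True)
def perimeter_counts(grid, poffs, tx, ty, old, new):
    """Counts of perimeter-shell neighbors of (tx, ty) in cells old / new."""
    n = grid.shape[0]
    c_old = 0
    c_new = 0
    for k in range(poffs.shape[0]):
        i = _wrap(tx + poffs[k, 0], n)
        j = _wrap(ty + poffs[k, 1], n)
        c = grid[i, j]
        if c == old:
            c_old += 1
        if c == new:
            c_new += 1
    return c_old, c_new


@njit(cache=True)
def delta_perimeter(ctype, perim, lam_p, p0, old, new, c_old, c_new, npo):
    """Perimeter-constraint change given the neighbor counts of the pixel.

    Under an edge-count perimeter only the losing and gaining cells change:
    dp(old) = 2*c_old - npo, dp(new) = npo - 2*c_new.
    """
    d = 0.0
    if old != 0:
        t = ctype[old]
        if lam_p[t] != 0.0:
            dp = 2 * c_old - npo
            up = float(perim[old] + dp) - p0[t]
            dn = float(perim[old]) - p0[t]
            d += lam_p[t] * (up * up - dn * dn)
    if new != 0:
        t = ctype[new]
        if lam_p[t] != 0.0:
            dp = npo - 2 * c_new
            up = float(perim[new] + dp) - p0[t]
            dn = float(perim[new]) - p0[t]
            d += lam_p[t] * (up * up - dn * dn)
    return d


@njit(cache=True)
def delta_motility(area, sumx, sumy, mu, polx, poly, tx, ty, sx, sy,
                   old, new, n, mode):
    """Active-motility energy change for the (at most two) affected cells.

    mode 0 ("copyvector"): ΔH = −(μ_new n̂_new + μ_old n̂_old)·v̂ with v̂ the
    unit vector from the source pixel (sx, sy) to the target (tx, ty) — the
    copy translates both cells along v̂.  mode 2 ("copyvector_gain"): same
    v̂ form but only the gaining (source) cell contributes, so retraction
    of the cell's own rear earns no motility reward.  mode 1 ("com"):
    ΔH = −Σ μ_c n̂_c·Δr⃗_c with Δr⃗_c the exact center-of-mass displacement
    the copy causes (a losing cell at area 1 vanishes and contributes
    nothing).
    """
    d = 0.0
    if mode == 0 or mode == 2:
        vx = float(tx - sx)
        vy = float(ty - sy)
        # source is a shell neighbor; undo the periodic wrap
        if vx > 2.0:
            vx -= n
        elif vx < -2.0:
            vx += n
        if vy > 2.0:
            vy -= n
        elif vy < -2.0:
            vy += n
        r = np.sqrt(vx * vx + vy * vy)
        vx /= r
        vy /= r
        if new != 0 and mu[new] != 0.0:
            d -= mu[new] * (polx[new] * vx + poly[new] * vy)
        if mode == 0 and old != 0 and mu[old] != 0.0:
            d -= mu[old] * (polx[old] * vx + poly[old] * vy)
        return d
    if new != 0 and mu[new] != 0.0:
        a = float(area[new])
        cx = sumx[new] / a
        cy = sumy[new] / a
        ux = _nearest_image(tx, cx, n)
        uy = _nearest_image(ty, cy, n)
        drx = (ux - cx) / (a + 1.0)
        dry = (uy - cy) / (a + 1.0)
        d -= mu[new] * (polx[new] * drx + poly[new] * dry)
    if old != 0 and mu[old] != 0.0 and area[old] > 1:
        a = float(area[old])
        cx = sumx[old] / a
        cy = sumy[old] / a
        ux = _nearest_image(tx, cx, n)
        uy = _nearest_image(ty, cy, n)
        drx = (cx - ux) / (a - 1.0)
        dry = (cy - uy) / (a - 1.0)
        d -= mu[old] * (polx[old] * drx + poly[old] * dry)
    return d


@njit(cache=True)
def effective_temperature(ctype, T, old, new):
    """min(T_a, T_b) between distinct cell types; a cell↔medium attempt
    uses the non-medium cell's temperature."""
    t_old = ctype[old]
    t_new = ctype[new]
    if t_old == 0:
        return T[t_new]
    if t_new == 0:
        return T[t_old]
    if T[t_old] < T[t_new]:
        return T[t_old]
    return T[t_new]


@njit(cache=True)
def total_delta(grid, offs, poffs, ctype, area, perim, sumx, sumy, mu,
                polx, poly, lam_a, a0, lam_p, p0, J, tx, ty, sx, sy,
                old, new, motility_mode):
    """Full ΔH = Δcontact + Δarea + Δperimeter + Δmotility for one copy."""
    n = grid.shape[0]
    d = delta_contact(grid, offs, ctype, J, tx, ty, old, new)
    d += delta_area(area, ctype, lam_a, a0, old, new)
    c_old, c_new = perimeter_counts(grid, poffs, tx, ty, old, new)
    d += delta_perimeter(ctype, perim, lam_p, p0, old, new, c_old, c_new,
                         poffs.shape[0])
    d += delta_motility(area, sumx, sumy, mu, polx, poly, tx, ty, sx, sy,
                        old, new, n, motility_mode)
    return d


@njit(cache=True)
def commit_copy(grid, poffs, area, perim, sumx, sumy, tx, ty, old, new):
    """Write ``new`` into the pixel and update all incremental caches."""
    n = grid.shape[0]
    npo = poffs.shape[0]
    c_old, c_new = perimeter_counts(grid, poffs, tx, ty, old, new)
    grid[tx, ty] = new
    if new != 0:
        a = float(area[new])
        cx = sumx[new] / a
        cy = sumy[new] / a
        sumx[new] += _nearest_image(tx, cx, n)
        sumy[new] += _nearest_image(ty, cy, n)
        perim[new] += npo - 2 * c_new
    if old != 0:
        a = float(area[old])
        if area[old] > 1:
            cx = sumx[old] / a
            cy = sumy[old] / a
            sumx[old] -= _nearest_image(tx, cx, n)
            sumy[old] -= _nearest_image(ty, cy, n)
        else:
            sumx[old] = 0.0
            sumy[old] = 0.0
        perim[old] += 2 * c_old - npo
    area[new] += 1
    area[old] -= 1


@njit(cache=True)
def run_kernel(grid, offs, coffs, poffs, ctype, area, perim, sumx, sumy, mu,
               polx, poly, comx_prev, comy_prev, velx, vely,
               comx_mark, comy_mark, T, lam_a, a0, lam_p, p0, J,
               n_mcs, tau, mcs_start, seed, motility_mode):
    """Run ``n_mcs`` Monte Carlo steps (n*n copy attempts each).

    After every mcs the per-cell velocity (COM displacement over that mcs)
    is recorded, and every ``tau`` mcs each motile cell's polarity is reset
    to its normalized net displacement since the previous update (kept
    unchanged if the cell did not move).  Returns the number of accepted
    copies.
    """
    np.random.seed(seed)
    n = grid.shape[0]
    npix = n * n
    ncoffs = coffs.shape[0]
    npo = poffs.shape[0]
    ncells = area.shape[0]
    accepted = 0
    for step in range(n_mcs):
        for _ in range(npix):
            p = np.random.randint(npix)
            tx = p // n
            ty = p - tx * n
            k = np.random.randint(ncoffs)
            sx = _wrap(tx + coffs[k, 0], n)
            sy = _wrap(ty + coffs[k, 1], n)
            old = grid[tx, ty]
            new = grid[sx, sy]
            if old == new:
                continue
            d = delta_contact(grid, offs, ctype, J, tx, ty, old, new)
            d += delta_area(area, ctype, lam_a, a0, old, new)
            c_old, c_new = perimeter_counts(grid, poffs, tx, ty, old, new)
            d += delta_perimeter(ctype, perim, lam_p, p0, old, new,
                                 c_old, c_new, npo)
            d += delta_motility(area, sumx, sumy, mu, polx, poly,
                                tx, ty, sx, sy, old, new, n, motility_mode)
            if d > 0.0:
                teff = effective_temperature(ctype, T, old, new)
                if np.random.random() >= np.exp(-d / teff):
                    continue
            # inline commit, reusing the neighbor counts
            grid[tx, ty] = new
            if new != 0:
                a = float(area[new])
                cx = sumx[new] / a
                cy = sumy[new] / a
                sumx[new] += _nearest_image(tx, cx, n)
                sumy[new] += _nearest_image(ty, cy, n)
                perim[new] += npo - 2 * c_new
            if old != 0:
                a = float(area[old])
                if area[old] > 1:
                    cx = sumx[old] / a
                    cy = sumy[old] / a
                    sumx[old] -= _nearest_image(tx, cx, n)
                    sumy[old] -= _nearest_image(ty, cy, n)
                else:
                    sumx[old] = 0.0
                    sumy[old] = 0.0
                perim[old] += 2 * c_old - npo
            area[new] += 1
            area[old] -= 1
            accepted += 1
        # end-of-mcs bookkeeping: velocities then the tau-scheduled polarity
        for c in range(1, ncells):
            if area[c] > 0:
                cx = sumx[c] / area[c]
                cy = sumy[c] / area[c]
                velx[c] = cx - comx_prev[c]
                vely[c] = cy - comy_prev[c]
                comx_prev[c] = cx
                comy_prev[c] = cy
        mcs = mcs_start + step + 1
        if tau > 0 and mcs % tau == 0:
            for c in range(1, ncells):
                if area[c] > 0 and mu[c] != 0.0:
                    cx = sumx[c] / area[c]
                    cy = sumy[c] / area[c]
                    dx = cx - comx_mark[c]
                    dy = cy - comy_mark[c]
                    r = np.sqrt(dx * dx + dy * dy)
                    if r > 0.0:
                        polx[c] = dx / r
                        poly[c] = dy / r
                    comx_mark[c] = cx
                    comy_mark[c] = cy
    return accepted
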