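"""Active motility: polarity vectors with persistence, and their energetics.

Motile (hybrid) cells carry a unit polarity vector n̂ and an energy term
``H_motility = -Σ_c μ_c n̂_c · r⃗_c`` that rewards center-of-mass motion along
the polarity.  The polarity has persistence: every τ mcs it is reset to the
cell's mean center-of-mass velocity over the last τ mcs, normalized,

    n̂_c ← <v⃗_c>_[t-τ, t] / |<v⃗_c>_[t-τ, t]|

which equals the net COM displacement over the window divided by its length.
If a cell did not move at all over the window (0/0 in the rule above), its
polarity is kept unchanged.  Between updates n̂ is frozen, and the energy
change of a proposed pixel copy uses the pre-copy polarity.

The simulation engine evaluates these updates inline in its compiled loop;
the functions here are the reference implementations used at setup time and
by tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def initialize_polarity(mu: np.ndarray, rng: np.random.Generator):
    """Independent uniformly random unit vectors for every motile cell.

    Non-motile cells (μ = 0) get a zero vector; their motility term is
    identically zero so the direction is never consulted.
    """
    ncells = len(mu)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=ncells)
    polx = np.where(mu != 0, np.cos(theta), 0.0)
    poly = np.where(mu != 0, np.sin(theta), 0.0)
    return polx, poly


def update_polarity(displacements: np.ndarray, previous: np.ndarray) -> np.ndarray:
    """New polarity from a window of per-mcs COM displacements.

    Parameters
    ----------
    displacements : (τ, 2) array
        Per-mcs center-of-mass displacement vectors over the window.
    previous : (2,) array
        Polarity before the update, returned unchanged if the mean
        displacement is the zero vector.
    """
    mean = np.asarray(displacements, dtype=float).mean(axis=0)
    norm = float(np.hypot(mean[0], mean[1]))
    if norm == 0.0:
        return np.asarray(previous, dtype=float)
    return mean / norm


@dataclass
class PolarityState:
    """Polarity bookkeeping for all cells of a simulation.

    ``nx, ny`` are the unit polarity components (zero for non-motile cells);
    ``mark`` holds each cell's COM at the last scheduled update, so the
    window-mean velocity is (COM − mark)/τ without storing the τ individual
    displacements; ``last_update_mcs`` is the time of that update.
    """

    nx: np.ndarray
    ny: np.ndarray
    mark_x: np.ndarray
    mark_y: np.ndarray
    tau: int
    last_update_mcs: int = 0

    def scheduled_update(self, com: np.ndarray, motile: np.ndarray, mcs: int):
        """Apply the τ-schedule update for every motile cell."""
        dx = com[:, 0] - self.mark_x
        dy = com[:, 1] - self.mark_y
        norm = np.hypot(dx, dy)
        move = motile & (norm > 0)
        self.nx[move] = dx[move] / norm[move]
        self.ny[move] = dy[move] / norm[move]
        self.mark_x[motile] = com[motile, 0]
        self.mark_y[motile] = com[motile, 1]
        self.last_update_mcs = mcs


def delta_motility(sim, pixel, new_cell: int) -> float:
    """Motility energy change of copying ``new_cell`` into ``pixel``.

    Both the gaining and the losing cell contribute when both are motile;
    the medium contributes nothing.  Delegates to the engine's compiled
    primitive so there is a single implementation.
    """
    return sim.delta_motility(pixel, new_cell)
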