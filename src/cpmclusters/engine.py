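"""Core Cellular Potts engine: lattice state, Hamiltonian, Metropolis dynamics.

The model is the standard Glazier–Graner–Hogeweg formulation on a periodic 2D
square lattice.  Each biological cell is the set of pixels sharing an integer
index; index 0 is the medium, a special "cell" with unconstrained area and
perimeter.  The energy is

    H = H_contact + H_area + H_perimeter

with ``H_contact = Σ_neighbors J[t_i, t_j] (1 - δ_{c_i, c_j})`` summed once per
unordered neighbor pair over the interaction shell, ``H_area = Σ_c λ_a (a_c -
a₀)²`` and ``H_perimeter = Σ_c λ_p (p_c - p₀)²`` over non-medium cells.  An
active-motility term ``-Σ_c μ_c n̂_c·r⃗_c`` enters the dynamics through its
exact energy change (see :mod:`cpmclusters.motility`).

Dynamics: a random target pixel and a random shell neighbor are drawn; if they
hold different cell indices the neighbor's index is proposed for the target
pixel and accepted with the modified-Metropolis probability
``P = exp(-ΔH/T)`` for ΔH > 0, else 1.  When the two sides belong to distinct
cell types, the lower of their two temperatures is used; cell↔medium attempts
use the cell's own temperature.  One Monte Carlo step (mcs) is n×n attempts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .motility import initialize_polarity

MEDIUM = 0

#: Interaction shells: the offsets whose pixel pairs enter H_contact.
#: "dist2" (default) is every neighbor within Euclidean distance 2 — nearest,
#: diagonal and axial second-nearest pixels, 12 offsets.  "moore8" is the
#: 8-connected shell common in CPM practice, kept for sensitivity checks;
#: it fragments motile cells noticeably more at high μ.
SHELLS = {
    "nn4": [(-1, 0), (1, 0), (0, -1), (0, 1)],
    "moore8": [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
               if (di, dj) != (0, 0)],
    "dist2": [(di, dj) for di in (-2, -1, 0, 1, 2) for dj in (-2, -1, 0, 1, 2)
              if (di, dj) != (0, 0) and di * di + dj * dj <= 4],
}

#: 4-connected offsets used by the default edge-count perimeter.
EDGE_OFFSETS = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def shell_offsets(name: str) -> np.ndarray:
    try:
        return np.array(SHELLS[name], dtype=np.int64)
    except KeyError:
        raise ValueError(f"unknown interaction shell {name!r}; "
                         f"choose from {sorted(SHELLS)}") from None


@dataclass(frozen=True)
class CellTypeSpec:
    """Physics of one cell type.

    Parameters
    ----------
    name : str
        Type label, e.g. ``"E"`` (epithelial, nonmotile) or ``"H"`` (hybrid,
        motile).
    T : float
        Fluctuation temperature (membrane activity); must be positive.
    lambda_area, target_area : float
        Strength and target of the area constraint (pixels).
    lambda_perim, target_perim : float
        Strength and target of the perimeter constraint; ``lambda_perim = 0``
        (the default) disables it.
    mu : float
        Default motile-force coefficient for cells of this type; individual
        cells may override it (phenotype spectra).
    """

    name: str
    T: float
    lambda_area: float = 1.0
    target_area: float = 25.0
    lambda_perim: float = 0.0
    target_perim: float = 0.0
    mu: float = 0.0


class TypeTable:
    """Indexed collection of cell types; index 0 is always the medium."""

    def __init__(self, types: list[CellTypeSpec]):
        names = ["medium"] + [t.name for t in types]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell type names")
        self.names = names
        ntyp = len(names)
        self.T = np.ones(ntyp)
        self.lambda_area = np.zeros(ntyp)
        self.target_area = np.zeros(ntyp)
        self.lambda_perim = np.zeros(ntyp)
        self.target_perim = np.zeros(ntyp)
        self.mu = np.zeros(ntyp)
        for i, t in enumerate(types, start=1):
            if t.T <= 0:
                raise ValueError(f"type {t.name!r}: T must be > 0")
            if t.lambda_area < 0 or t.lambda_perim < 0:
                raise ValueError(f"type {t.name!r}: constraint strengths "
                                 "must be >= 0")
            self.T[i] = t.T
            self.lambda_area[i] = t.lambda_area
            self.target_area[i] = t.target_area
            self.lambda_perim[i] = t.lambda_perim
            self.target_perim[i] = t.target_perim
            self.mu[i] = t.mu

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValueError(f"unknown cell type {name!r}") from None

    def __len__(self) -> int:
        return len(self.names)


class ContactTable:
    """Symmetric contact energies J[type_a][type_b], with J_mm = 0.

    Pair energies are given by type name, e.g. ``{("E", "E"): 2,
    ("E", "medium"): 20}``; order within a pair does not matter.  Unspecified
    pairs default to 0 (notably medium–medium, which is required to be 0).
    """

    def __init__(self, types: TypeTable, energies: dict):
        self.types = types
        ntyp = len(types)
        J = np.zeros((ntyp, ntyp))
        for (a, b), val in energies.items():
            ia, ib = types.index(a), types.index(b)
            if (ia, ib) != (0, 0):
                J[ia, ib] = val
                J[ib, ia] = val
        if energies.get(("medium", "medium"), 0) != 0:
            raise ValueError("medium-medium contact energy must be 0")
        if not np.allclose(J, J.T):
            raise ValueError("contact table must be symmetric")
        self.J = J

    def __getitem__(self, pair) -> float:
        a, b = pair
        return self.J[self.types.index(a), self.types.index(b)]


def surface_tension(contact: ContactTable, type_a: str, type_b: str) -> float:
    """Surface tension γ_ab = J_ab − (J_aa + J_bb)/2.

    With J_mm = 0 this reduces to the cell–medium form γ_cm = J_cm − J_cc/2;
    γ > 0 means the two phases prefer to minimize shared boundary.
    """
    ia = contact.types.index(type_a)
    ib = contact.types.index(type_b)
    J = contact.J
    return J[ia, ib] - (J[ia, ia] + J[ib, ib]) / 2.0


def effective_temperature(type_a: str, type_b: str, types: TypeTable) -> float:
    """Temperature used for a copy attempt between the two types.

    The lower temperature applies at a boundary between distinct cell types;
    with the medium on one side, the non-medium cell's temperature is used.
    """
    ia, ib = types.index(type_a), types.index(type_b)
    return float(_kernels.effective_temperature(
        np.array([ia, ib]), types.T, 0, 1))


def metropolis_accept(delta_H: float, T: float, rng: np.random.Generator) -> bool:
    """Modified Metropolis rule: always accept ΔH ≤ 0, else with exp(-ΔH/T).

    Exactly one uniform draw is consumed when ΔH > 0 and none otherwise.
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    if delta_H <= 0:
        return True
    return rng.random() < np.exp(-delta_H / T)


@dataclass
class Simulation:
    """A periodic 2D CPM lattice with incremental bookkeeping.

    Parameters
    ----------
    grid : (n, n) int array
        Pixel → cell-index map; 0 is medium.
    cell_types : int array
        Type index (into ``types``) per cell id; entry 0 must be medium.
    types : TypeTable
    contact : ContactTable
    mu : float array, optional
        Per-cell motile force; defaults to each cell's type default.
    tau : int
        Polarity persistence time in mcs (update cadence).
    shell : str
        Interaction shell for H_contact ("moore8" or "dist2").
    copy_shell : str
        Shell from which copy sources are drawn ("moore8" default, "dist2",
        or "nn4" for first neighbors only).  Narrower than the energy shell
        in standard practice: a copy from a distance-2 source would deposit
        a pixel detached from the source cell.
    perimeter : str
        "edge" (4-connected edge count, default) or "shell" (count over the
        interaction shell).
    motility_mode : str
        "com" (default): ΔH_motility = −Σ μ_c n̂_c·Δr⃗_c with Δr⃗_c the exact
        center-of-mass displacement a copy causes — the persistent-motility
        formulation in which the motile force μ acts on the cell's center of
        mass.  "copyvector" / "copyvector_gain": O(μ) kicks along the unit
        pixel-copy vector (both cells, or the gaining cell only), kept for
        sensitivity analysis; at μ comparable to tens of J they overpower
        the area constraint and shred or destroy cells over long runs.
    seed : int
        Seeds both the attempt stream and the initial polarity directions.
    """

    grid: np.ndarray
    cell_types: np.ndarray
    types: TypeTable
    contact: ContactTable
    mu: np.ndarray | None = None
    tau: int = 50
    shell: str = "dist2"
    copy_shell: str = "moore8"
    perimeter: str = "edge"
    motility_mode: str = "com"
    seed: int = 0
    mcs: int = field(default=0, init=False)
    attempts: int = field(default=0, init=False)
    accepted: int = field(default=0, init=False)

    def __post_init__(self):
        self.grid = np.array(self.grid, dtype=np.int64, order="C", copy=True)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("grid must be square (n x n)")
        self.n = self.grid.shape[0]
        ncells = int(self.grid.max()) + 1
        self.cell_types = np.asarray(self.cell_types, dtype=np.int64)
        if len(self.cell_types) < ncells:
            raise ValueError("cell_types shorter than the number of cell ids")
        if self.cell_types[0] != MEDIUM:
            raise ValueError("cell id 0 must be of medium type")
        self.offs = shell_offsets(self.shell)
        self.coffs = shell_offsets(self.copy_shell)
        if self.perimeter == "edge":
            self.poffs = np.array(EDGE_OFFSETS, dtype=np.int64)
        elif self.perimeter == "shell":
            self.poffs = self.offs
        else:
            raise ValueError("perimeter must be 'edge' or 'shell'")
        try:
            self._motility_mode = {"copyvector": 0, "com": 1,
                                   "copyvector_gain": 2}[self.motility_mode]
        except KeyError:
            raise ValueError("motility_mode must be 'copyvector', "
                             "'copyvector_gain' or 'com'") from None
        if self.mu is None:
            self.mu = self.types.mu[self.cell_types].astype(float)
        else:
            self.mu = np.asarray(self.mu, dtype=float).copy()
        if self.mu[0] != 0 or np.any(self.mu[self.cell_types == MEDIUM] != 0):
            raise ValueError("medium cannot be motile")
        self._seedseq = np.random.SeedSequence(self.seed)
        self.rng = np.random.default_rng(self._seedseq.spawn(1)[0])
        self._rebuild_caches()
        # polarity and velocity bookkeeping
        self.polx, self.poly = initialize_polarity(self.mu, self.rng)
        com = self.centers_of_mass_unwrapped
        self.comx_prev = com[:, 0].copy()
        self.comy_prev = com[:, 1].copy()
        self.comx_mark = com[:, 0].copy()
        self.comy_mark = com[:, 1].copy()
        self.velx = np.zeros(len(self.area))
        self.vely = np.zeros(len(self.area))

    # ------------------------------------------------------------------
    # cache construction and verification
    # ------------------------------------------------------------------
    def _rebuild_caches(self):
        ncells = int(self.grid.max()) + 1
        self.area = np.bincount(self.grid.ravel(), minlength=ncells).astype(np.int64)
        self.perim = self.recompute_perimeters()
        self.sumx, self.sumy = self.recompute_com_sums()

    def recompute_areas(self) -> np.ndarray:
        return np.bincount(self.grid.ravel(), minlength=len(self.area)).astype(np.int64)

    def recompute_perimeters(self) -> np.ndarray:
        ncells = len(self.area)  # fixed id space; the top id may have died
        perim = np.zeros(ncells, dtype=np.int64)
        for di, dj in self.poffs:
            neigh = np.roll(self.grid, (-di, -dj), axis=(0, 1))
            mask = neigh != self.grid
            perim += np.bincount(self.grid[mask], minlength=ncells)
        perim[MEDIUM] = 0
        return perim

    def recompute_com_sums(self, ref: np.ndarray | None = None):
        """Per-cell sums of unwrapped pixel coordinates.

        Without a reference, each cell's pixels are unwrapped around their
        circular mean (exact for cells of diameter < n/2, so the result is
        the true COM modulo the box).  With ``ref`` (e.g. cached COMs), pixels
        are unwrapped to the image nearest the given point, which reproduces
        the incremental sums exactly.
        """
        n = self.n
        ncells = len(self.area)
        ii, jj = np.indices(self.grid.shape)
        sumx = np.zeros(ncells)
        sumy = np.zeros(ncells)
        flat = self.grid.ravel()
        for c in range(1, ncells):
            sel = flat == c
            if not sel.any():
                continue
            x = ii.ravel()[sel].astype(float)
            y = jj.ravel()[sel].astype(float)
            if ref is None:
                rx = _circular_mean(x, n)
                ry = _circular_mean(y, n)
            else:
                rx, ry = ref[c]
            sumx[c] = np.sum(x + n * np.floor((rx - x) / n + 0.5))
            sumy[c] = np.sum(y + n * np.floor((ry - y) / n + 0.5))
        return sumx, sumy

    def check_consistency(self, atol: float = 1e-9):
        """Raise AssertionError if any incremental cache drifted."""
        assert np.array_equal(self.area, self.recompute_areas()), "area cache"
        assert np.array_equal(self.perim, self.recompute_perimeters()), \
            "perimeter cache"
        assert self.area.sum() == self.n * self.n, "pixel conservation"
        com = self.centers_of_mass_unwrapped
        sx, sy = self.recompute_com_sums(ref=com)
        live = self.area > 0
        live[MEDIUM] = False
        if live.any():
            scale = float(self.area[live].max())
            np.testing.assert_allclose(self.sumx[live], sx[live],
                                       atol=atol * scale)
            np.testing.assert_allclose(self.sumy[live], sy[live],
                                       atol=atol * scale)

    # ------------------------------------------------------------------
    # derived state
    # ------------------------------------------------------------------
    @property
    def medium_area(self) -> int:
        return int(self.area[MEDIUM])

    @property
    def live_cells(self) -> np.ndarray:
        ids = np.nonzero(self.area > 0)[0]
        return ids[ids != MEDIUM]

    @property
    def centers_of_mass_unwrapped(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(self.area > 0, self.area, 1)
            return np.stack([self.sumx / a, self.sumy / a], axis=1)

    @property
    def centers_of_mass(self) -> np.ndarray:
        return np.mod(self.centers_of_mass_unwrapped, self.n)

    @property
    def polarity(self):
        """Polarity bookkeeping as a :class:`~cpmclusters.motility.PolarityState`.

        A live view: the arrays are the ones the kernel updates in place.
        """
        from .motility import PolarityState
        return PolarityState(nx=self.polx, ny=self.poly,
                             mark_x=self.comx_mark, mark_y=self.comy_mark,
                             tau=self.tau,
                             last_update_mcs=self.mcs - self.mcs % self.tau
                             if self.tau > 0 else 0)

    def type_name(self, cell_id: int) -> str:
        return self.types.names[self.cell_types[cell_id]]

    # ------------------------------------------------------------------
    # energies
    # ------------------------------------------------------------------
    def contact_energy(self) -> float:
        """H_contact summed once per unordered neighbor pair in the shell."""
        tgrid = self.cell_types[self.grid]
        total = 0.0
        half = [(di, dj) for di, dj in self.offs
                if di > 0 or (di == 0 and dj > 0)]
        for di, dj in half:
            neigh = np.roll(self.grid, (-di, -dj), axis=(0, 1))
            tneigh = np.roll(tgrid, (-di, -dj), axis=(0, 1))
            mask = neigh != self.grid
            total += self.contact.J[tgrid[mask], tneigh[mask]].sum()
        return float(total)

    def area_energy(self) -> float:
        """Σ λ_a (a - a₀)² over non-medium cells.

        A cell whose last pixel was copied away stays in the sum at a = 0;
        its term is then a constant, which keeps every incremental ΔH equal
        to the difference of totals (and makes killing the last pixel cost
        λ_a(2a₀ - 1), strongly penalizing cell destruction).
        """
        t = self.cell_types
        sel = np.arange(len(self.area)) != MEDIUM
        d = self.area[sel] - self.types.target_area[t[sel]]
        return float(np.sum(self.types.lambda_area[t[sel]] * d * d))

    def perimeter_energy(self) -> float:
        t = self.cell_types
        sel = np.arange(len(self.area)) != MEDIUM
        d = self.perim[sel] - self.types.target_perim[t[sel]]
        return float(np.sum(self.types.lambda_perim[t[sel]] * d * d))

    def total_hamiltonian(self) -> float:
        """H = H_contact + H_area + H_perimeter (motility enters only as ΔH)."""
        return self.contact_energy() + self.area_energy() + self.perimeter_energy()

    # ------------------------------------------------------------------
    # incremental energy changes for a proposed copy
    # ------------------------------------------------------------------
    def delta_contact(self, pixel, new_cell: int) -> float:
        tx, ty = pixel
        return float(_kernels.delta_contact(
            self.grid, self.offs, self.cell_types, self.contact.J,
            tx, ty, self.grid[tx, ty], new_cell))

    def delta_area(self, gaining_cell: int, losing_cell: int) -> float:
        if losing_cell != MEDIUM and self.area[losing_cell] == 0:
            raise ValueError(f"cell {losing_cell} has area 0; invalid state")
        return float(_kernels.delta_area(
            self.area, self.cell_types, self.types.lambda_area,
            self.types.target_area, losing_cell, gaining_cell))

    def delta_perimeter(self, pixel, new_cell: int) -> float:
        tx, ty = pixel
        old = self.grid[tx, ty]
        c_old, c_new = _kernels.perimeter_counts(
            self.grid, self.poffs, tx, ty, old, new_cell)
        return float(_kernels.delta_perimeter(
            self.cell_types, self.perim, self.types.lambda_perim,
            self.types.target_perim, old, new_cell, c_old, c_new,
            len(self.poffs)))

    def _source_pixel(self, pixel, new_cell: int):
        """A copy-shell neighbor of ``pixel`` occupied by ``new_cell``."""
        tx, ty = pixel
        for di, dj in self.coffs:
            sx, sy = (tx + di) % self.n, (ty + dj) % self.n
            if self.grid[sx, sy] == new_cell:
                return sx, sy
        raise ValueError(f"cell {new_cell} occupies no shell neighbor of "
                         f"pixel {tuple(pixel)}")

    def delta_motility(self, pixel, new_cell: int, source=None) -> float:
        tx, ty = pixel
        if source is None:
            source = self._source_pixel(pixel, new_cell)
        sx, sy = source
        return float(_kernels.delta_motility(
            self.area, self.sumx, self.sumy, self.mu, self.polx, self.poly,
            tx, ty, sx, sy, self.grid[tx, ty], new_cell, self.n,
            self._motility_mode))

    def delta_H(self, pixel, new_cell: int, source=None) -> float:
        tx, ty = pixel
        if source is None:
            source = self._source_pixel(pixel, new_cell)
        sx, sy = source
        return float(_kernels.total_delta(
            self.grid, self.offs, self.poffs, self.cell_types, self.area,
            self.perim, self.sumx, self.sumy, self.mu, self.polx, self.poly,
            self.types.lambda_area, self.types.target_area,
            self.types.lambda_perim, self.types.target_perim,
            self.contact.J, tx, ty, sx, sy, self.grid[tx, ty], new_cell,
            self._motility_mode))

    # ------------------------------------------------------------------
    # dynamics
    # ------------------------------------------------------------------
    def attempt_copy(self, rng: np.random.Generator | None = None) -> bool:
        """One pixel-copy attempt driven from Python.

        Used for fine-grained testing; bulk runs go through :meth:`run_mcs`,
        which executes the same energy primitives in a compiled loop (with
        its own seeded stream).
        """
        rng = rng or self.rng
        p = int(rng.integers(self.n * self.n))
        tx, ty = divmod(p, self.n)
        k = int(rng.integers(len(self.coffs)))
        sx = (tx + self.coffs[k, 0]) % self.n
        sy = (ty + self.coffs[k, 1]) % self.n
        old = self.grid[tx, ty]
        new = self.grid[sx, sy]
        self.attempts += 1
        if old == new:
            return False
        d = self.delta_H((tx, ty), new, source=(sx, sy))
        teff = _kernels.effective_temperature(self.cell_types, self.types.T,
                                              old, new)
        if not metropolis_accept(d, teff, rng):
            return False
        _kernels.commit_copy(self.grid, self.poffs, self.area, self.perim,
                             self.sumx, self.sumy, tx, ty, old, new)
        self.accepted += 1
        return True

    def run_mcs(self, n_steps: int):
        """Advance the lattice by ``n_steps`` Monte Carlo steps.

        Each mcs performs n×n attempts in the compiled kernel; per-mcs cell
        velocities are recorded and polarities refresh on the τ schedule.
        """
        if n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if n_steps == 0:
            return self
        kseed = int(self._seedseq.spawn(1)[0].generate_state(1)[0] & 0x7FFFFFFF)
        acc = _kernels.run_kernel(
            self.grid, self.offs, self.coffs, self.poffs, self.cell_types,
            self.area,
            self.perim, self.sumx, self.sumy, self.mu, self.polx, self.poly,
            self.comx_prev, self.comy_prev, self.velx, self.vely,
            self.comx_mark, self.comy_mark, self.types.T,
            self.types.lambda_area, self.types.target_area,
            self.types.lambda_perim, self.types.target_perim, self.contact.J,
            n_steps, self.tau, self.mcs, kseed, self._motility_mode)
        self.mcs += n_steps
        self.attempts += n_steps * self.n * self.n
        self.accepted += int(acc)
        return self

    # ------------------------------------------------------------------
    # export
    # ------------------------------------------------------------------
    def cells_dataframe(self) -> pd.DataFrame:
        """Per-cell snapshot table (live cells only)."""
        ids = self.live_cells
        com = self.centers_of_mass
        return pd.DataFrame({
            "cell_id": ids,
            "type": [self.types.names[self.cell_types[c]] for c in ids],
            "mu": self.mu[ids],
            "area": self.area[ids],
            "perimeter": self.perim[ids],
            "com_x": com[ids, 0],
            "com_y": com[ids, 1],
            "polarity_x": self.polx[ids],
            "polarity_y": self.poly[ids],
            "vel_x": self.velx[ids],
            "vel_y": self.vely[ids],
        })


def _circular_mean(x: np.ndarray, n: int) -> float:
    """Mean of positions on a ring of circumference n (angle method)."""
    theta = 2.0 * np.pi * x / n
    return float(np.mod(np.arctan2(np.sin(theta).mean(), np.cos(theta).mean()),
                        2.0 * np.pi) * n / (2.0 * np.pi))
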