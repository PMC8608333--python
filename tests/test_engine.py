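"""Engine tests: energies, incremental deltas vs oracles, Metropolis law."""

import numpy as np
import pytest

import oracles
from conftest import BASE_J, make_sim, make_types, random_blob_grid
from cpmclusters import _kernels
from cpmclusters.engine import (CellTypeSpec, ContactTable, Simulation,
                                TypeTable, effective_temperature,
                                metropolis_accept, shell_offsets,
                                surface_tension)


class TestSurfaceTension:
    @pytest.mark.parametrize("energies, pair, expected", [
        ({("E", "E"): 2, ("E", "medium"): 20}, ("E", "medium"), 19.0),
        ({("H", "H"): 6, ("H", "medium"): 6}, ("H", "medium"), 3.0),
        ({("E", "E"): 2, ("H", "H"): 6, ("E", "H"): 4}, ("E", "H"), 0.0),
    ])
    def test_printed_values(self, energies, pair, expected):
        types = make_types()
        contact = ContactTable(types, energies)
        assert surface_tension(contact, *pair) == expected

    def test_unknown_type_is_named(self):
        contact = ContactTable(make_types(), BASE_J)
        with pytest.raises(ValueError, match="X"):
            surface_tension(contact, "X", "medium")

    def test_symmetry_enforced_and_medium_zero(self):
        types = make_types()
        with pytest.raises(ValueError, match="medium"):
            ContactTable(types, {("medium", "medium"): 1.0})
        contact = ContactTable(types, BASE_J)
        assert np.array_equal(contact.J, contact.J.T)
        assert contact[("medium", "medium")] == 0.0


class TestTotalHamiltonian:
    def test_all_medium_is_zero(self):
        sim = make_sim(np.zeros((8, 8), dtype=int), {})
        assert sim.total_hamiltonian() == 0.0

    def test_single_pixel_cell_counts_shell_links(self):
        grid = np.zeros((8, 8), dtype=int)
        grid[4, 4] = 1
        sim = make_sim(grid, {1: "H"}, shell="moore8", target_area=1.0)
        # 8 heterotypic H-medium links, area exactly on target
        assert sim.total_hamiltonian() == 8 * BASE_J[("H", "medium")]

    @pytest.mark.parametrize("shell", ["moore8", "dist2"])
    def test_matches_pair_enumeration_oracle(self, two_cell_sim, shell):
        sim = make_sim(two_cell_sim.grid.copy(), {1: "E", 2: "H"},
                       shell=shell, target_area=6.0)
        assert sim.total_hamiltonian() == pytest.approx(
            oracles.total_hamiltonian(sim), rel=1e-12)

    def test_oracle_on_random_states(self, rng):
        for _ in range(5):
            grid = random_blob_grid(rng)
            sim = make_sim(grid, {c: ("E" if c % 2 else "H")
                                  for c in range(1, int(grid.max()) + 1)},
                           lambda_perim=0.5, target_perim=10.0)
            assert sim.total_hamiltonian() == pytest.approx(
                oracles.total_hamiltonian(sim), rel=1e-12)


class TestDeltaAlgebra:
    def test_area_loss_at_target(self):
        # cell exactly at a0 loses a pixel: (a0-1-a0)^2 - 0 = 1
        grid = np.zeros((10, 10), dtype=int)
        grid[2:7, 2:7] = 1
        sim = make_sim(grid, {1: "H"}, target_area=25.0)
        assert sim.delta_area(gaining_cell=0, losing_cell=1) == 1.0

    def test_area_loss_above_target(self):
        grid = np.zeros((10, 10), dtype=int)
        grid[2:7, 2:7] = 1
        grid[7, 2] = 1  # area a0 + 1
        sim = make_sim(grid, {1: "H"}, target_area=25.0)
        assert sim.delta_area(gaining_cell=0, losing_cell=1) == -1.0

    def test_losing_dead_cell_is_invalid(self):
        grid = np.zeros((6, 6), dtype=int)
        grid[2, 2] = 2
        sim = make_sim(grid, {1: "E", 2: "H"})
        with pytest.raises(ValueError, match="area 0"):
            sim.delta_area(gaining_cell=2, losing_cell=1)

    def test_removing_lone_pixel_cell_contact(self):
        grid = np.zeros((8, 8), dtype=int)
        grid[4, 4] = 1
        sim = make_sim(grid, {1: "H"}, shell="moore8", target_area=1.0)
        assert sim.delta_contact((4, 4), 0) == -8 * BASE_J[("H", "medium")]

    def test_same_type_zero_J_copy_is_free(self):
        # two cells of one type with J_tt = 0: contact cannot change
        grid = np.zeros((8, 8), dtype=int)
        grid[2:4, 2:6] = 1
        grid[4:6, 2:6] = 2
        J = dict(BASE_J)
        J[("H", "H")] = 0.0
        sim = make_sim(grid, {1: "H", 2: "H"}, J=J, target_area=8.0)
        d = sim.delta_contact((3, 3), 2)
        # pixel interior to the 1/2 block: only H-H links change, all J=0,
        # H-medium links unchanged
        assert d == 0.0

    def test_perimeter_zero_when_unconstrained(self, two_cell_sim):
        assert two_cell_sim.delta_perimeter((3, 2), 0) == 0.0

    def test_lone_pixel_absorption_perimeter(self):
        grid = np.zeros((8, 8), dtype=int)
        grid[4, 4] = 1
        sim = make_sim(grid, {1: "H"}, target_area=1.0,
                       lambda_perim=1.0, target_perim=0.0)
        # 1-pixel cell has edge-count perimeter 4; absorbing it removes it
        assert sim.delta_perimeter((4, 4), 0) == -16.0


@pytest.mark.parametrize("shell", ["moore8", "dist2"])
def test_incremental_deltas_match_full_recompute(rng, shell):
    """>= 1e4 attempted copies: each ΔH term equals the full-recompute
    difference to 1e-9 relative tolerance, and pixels are conserved."""
    total_attempts = 0
    checked = 0
    while total_attempts < 10_000 or checked < 1500:
        grid = random_blob_grid(rng)
        ncells = int(grid.max())
        mu = np.zeros(ncells + 1)
        mu[1:] = rng.uniform(5, 40, ncells)
        type_of = {c: ("E" if c % 3 == 0 else "H")
                   for c in range(1, ncells + 1)}
        for c, name in type_of.items():
            if name == "E":
                mu[c] = 0.0
        sim = make_sim(grid, type_of, mu=mu, shell=shell, seed=7,
                       target_area=20.0, lambda_perim=0.3, target_perim=14.0,
                       tau=10, motility_mode="com")
        npix = sim.n * sim.n
        for _ in range(6000):
            total_attempts += 1
            p = int(rng.integers(npix))
            tx, ty = divmod(p, sim.n)
            k = int(rng.integers(len(sim.offs)))
            sx = (tx + sim.offs[k, 0]) % sim.n
            sy = (ty + sim.offs[k, 1]) % sim.n
            old, new = sim.grid[tx, ty], sim.grid[sx, sy]
            if old == new:
                continue
            checked += 1
            d_con = sim.delta_contact((tx, ty), new)
            d_area = sim.delta_area(new, old)
            d_per = sim.delta_perimeter((tx, ty), new)
            d_mot = sim.delta_motility((tx, ty), new, source=(sx, sy))
            before = (sim.contact_energy(), sim.area_energy(),
                      sim.perimeter_energy())
            grid_before = sim.grid.copy()
            _kernels.commit_copy(sim.grid, sim.poffs, sim.area, sim.perim,
                                 sim.sumx, sim.sumy, tx, ty, old, new)
            after = (sim.contact_energy(), sim.area_energy(),
                     sim.perimeter_energy())
            assert d_con == pytest.approx(after[0] - before[0], rel=1e-9,
                                          abs=1e-9)
            assert d_area == pytest.approx(after[1] - before[1], rel=1e-9,
                                           abs=1e-9)
            assert d_per == pytest.approx(after[2] - before[2], rel=1e-9,
                                          abs=1e-9)
            assert sim.area.sum() == npix  # pixel conservation, every copy
            if checked % 20 == 0:  # motility oracle is the slow pure-python path
                expected = 0.0
                for c in (old, new):
                    if c != 0 and sim.mu[c] > 0:
                        dr = oracles.com_displacement(grid_before, sim.grid,
                                                      c, sim.n)
                        expected -= sim.mu[c] * (sim.polx[c] * dr[0]
                                                 + sim.poly[c] * dr[1])
                assert d_mot == pytest.approx(expected, rel=1e-9, abs=1e-9)
    assert total_attempts >= 10_000 and checked >= 1500
    sim.check_consistency()


class TestEffectiveTemperature:
    def test_distinct_types_take_minimum(self):
        types = make_types(T_E=1.0, T_H=6.0)
        assert effective_temperature("E", "H", types) == 1.0

    def test_medium_side_uses_cell_temperature(self):
        types = make_types(T_E=1.0, T_H=6.0)
        assert effective_temperature("H", "medium", types) == 6.0
        assert effective_temperature("medium", "E", types) == 1.0

    def test_equal_temperatures(self):
        types = make_types(T_E=1.0, T_H=1.0)
        assert effective_temperature("E", "H", types) == 1.0


class _CountingRng:
    def __init__(self, rng):
        self.rng = rng
        self.draws = 0

    def random(self):
        self.draws += 1
        return self.rng.random()


class TestMetropolis:
    def test_nonpositive_delta_always_accepted_without_draw(self, rng):
        counter = _CountingRng(rng)
        assert metropolis_accept(-3.0, 1.0, counter)
        assert metropolis_accept(0.0, 5.0, counter)
        assert counter.draws == 0

    def test_positive_delta_uses_one_draw(self, rng):
        counter = _CountingRng(rng)
        metropolis_accept(2.0, 1.0, counter)
        assert counter.draws == 1

    def test_nonpositive_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, rng)

    def test_acceptance_frequency_matches_boltzmann_factor(self, rng):
        """P(accept | ΔH = T) -> e^-1 within 3 binomial SE at 1e5 trials."""
        trials = 100_000
        hits = sum(metropolis_accept(2.5, 2.5, rng) for _ in range(trials))
        p = np.exp(-1.0)
        se = np.sqrt(p * (1 - p) / trials)
        assert abs(hits / trials - p) < 3 * se

    @pytest.mark.parametrize("ratio", [0.5, 2.0])
    def test_acceptance_frequency_other_ratios(self, rng, ratio):
        trials = 100_000
        hits = sum(metropolis_accept(ratio * 1.7, 1.7, rng)
                   for _ in range(trials))
        p = np.exp(-ratio)
        se = np.sqrt(p * (1 - p) / trials)
        assert abs(hits / trials - p) < 3 * se


class TestAttemptCopy:
    def test_same_cell_pick_changes_nothing(self):
        grid = np.ones((6, 6), dtype=int)
        sim = make_sim(grid, {1: "E"}, target_area=36.0)
        before = sim.grid.copy()
        assert sim.attempt_copy() is False
        assert np.array_equal(sim.grid, before)
        assert sim.attempts == 1

    def test_python_and_kernel_paths_keep_caches_exact(self, rng):
        grid = random_blob_grid(rng)
        sim = make_sim(grid, {c: "H" for c in range(1, int(grid.max()) + 1)},
                       target_area=20.0, lambda_perim=0.2, target_perim=14.0,
                       seed=3)
        accepted = sum(sim.attempt_copy() for _ in range(3000))
        assert accepted > 0
        sim.check_consistency()
        sim.run_mcs(40)
        sim.check_consistency()


class TestRunMcs:
    def test_zero_steps_is_identity(self, two_cell_sim):
        before = two_cell_sim.grid.copy()
        two_cell_sim.run_mcs(0)
        assert np.array_equal(two_cell_sim.grid, before)
        assert two_cell_sim.mcs == 0

    def test_attempt_count_is_exact(self, two_cell_sim):
        two_cell_sim.run_mcs(7)
        assert two_cell_sim.attempts == 7 * 36
        assert two_cell_sim.mcs == 7

    def test_single_epithelial_cell_is_stable(self):
        """A lone E cell (mu=0, gamma_Em=19, T=1) neither fragments nor
        drifts from its target area over 1000 mcs."""
        grid = np.zeros((20, 20), dtype=int)
        grid[8:13, 8:13] = 1
        sim = make_sim(grid, {1: "E"}, seed=11, target_area=25.0)
        sim.run_mcs(1000)
        assert 20 <= sim.area[1] <= 30
        from cpmclusters.clusters import fragmentation_check
        assert fragmentation_check(sim) == []
        sim.check_consistency()


class TestStationarySanity:
    """The two-cell toy system visits energies as the exact chain predicts.

    The pixel-copy proposal is asymmetric, so the chain's stationary law is
    close to, but not exactly, Boltzmann; the reference here is the exact
    stationary distribution of the enumerated Markov chain, with a check
    that it ranks energy levels the same way Boltzmann weights do.
    """

    def _toy(self, seed=0):
        grid = np.array([[1, 1, 1], [1, 1, 2], [2, 2, 2]], dtype=int)
        types = TypeTable([
            CellTypeSpec("E", T=2.0, lambda_area=2.0, target_area=5.0),
            CellTypeSpec("H", T=2.0, lambda_area=2.0, target_area=4.0),
        ])
        contact = ContactTable(types, {("E", "H"): 1.0})
        return Simulation(grid=grid, cell_types=np.array([0, 1, 2]),
                          types=types, contact=contact, shell="moore8",
                          seed=seed)

    def _exact_stationary(self, sim):
        import itertools
        offs = [tuple(o) for o in sim.offs]
        states = [np.array(b).reshape(3, 3) + 1
                  for b in itertools.product([0, 1], repeat=9)]
        live = [g for g in states if (g == 1).any() and (g == 2).any()]
        idx = {g.tobytes(): k for k, g in enumerate(live)}

        def energy(g):
            return (oracles.contact_energy(g, sim.cell_types, sim.contact.J,
                                           offs)
                    + oracles.area_energy(g, sim.cell_types,
                                          sim.types.lambda_area,
                                          sim.types.target_area))

        energies = np.array([energy(g) for g in live])
        P = np.zeros((len(live), len(live)))
        for k, g in enumerate(live):
            for i in range(3):
                for j in range(3):
                    for di, dj in offs:
                        prob = 1.0 / (9 * len(offs))
                        src = g[(i + di) % 3, (j + dj) % 3]
                        if src == g[i, j]:
                            P[k, k] += prob
                            continue
                        g2 = g.copy()
                        g2[i, j] = src
                        key = g2.tobytes()
                        if key not in idx:   # would kill a cell
                            P[k, k] += prob  # (reached with prob ~ e^-30)
                            continue
                        dE = energy(g2) - energy(g)
                        acc = 1.0 if dE <= 0 else np.exp(-dE / 2.0)
                        P[k, idx[key]] += prob * acc
                        P[k, k] += prob * (1.0 - acc)
        evals, evecs = np.linalg.eig(P.T)
        pi = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
        pi = np.abs(pi) / np.abs(pi).sum()
        return energies, pi

    def test_energy_histogram_matches_exact_chain(self):
        from scipy.stats import chi2

        sim = self._toy(seed=5)
        energies, pi = self._exact_stationary(sim)
        levels = np.unique(energies)
        expected_p = np.array([pi[energies == e].sum() for e in levels])
        # Boltzmann consistency of the reference: weights decrease with E
        assert np.all(np.diff(expected_p[expected_p > 1e-12]) <= 0)
        nsamp = 2000
        counts = np.zeros(len(levels))
        for _ in range(nsamp):
            sim.run_mcs(10)  # ~90 attempts between samples: decorrelated
            E = sim.total_hamiltonian()
            counts[np.argmin(np.abs(levels - E))] += 1
        mask = expected_p * nsamp >= 5
        chi = np.sum((counts[mask] - expected_p[mask] * nsamp) ** 2
                     / (expected_p[mask] * nsamp))
        dof = mask.sum() - 1
        assert chi < chi2.ppf(0.99, dof)
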