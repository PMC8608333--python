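"""Cluster identification and the summary statistics of disseminated cells.

A *cluster* is a contact-connected set of cells: by default two cells are
adjacent iff they share a pixel edge (4-connected contact, with periodic
wrap-around), so a cluster is exactly what a pixel-level flood fill over
the member pixels would join.  Diagonal-touch ("moore8") and
interaction-shell ("shell") adjacency are available for sensitivity checks;
the shell variant is looser than physical contact, since under a distance-2
energy shell it links cells separated by a one-pixel medium gap.
Connected components that contain at least one epithelial (E)
cell form the tumor side (including the rare all-E escapees, which are
excluded from all statistics); components made of motile H cells only are
the *released* clusters whose size statistics this module computes:

* N̄               — mean released-cluster size,
* f̄_H             — fraction of all H cells that sit in released clusters,
* f̄_singlecell    — fraction of released clusters of size N = 1,
* P(N)            — cluster-size distribution, normalized to Σ P(N) = 1.

Standard deviations reported here use the population convention (divide by
the group size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


@dataclass
class Cluster:
    """One released (all-H) connected component."""

    members: np.ndarray          # cell ids
    type_names: list[str]        # phenotype label per member
    mu: np.ndarray               # motile force per member

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSummary:
    """Released clusters plus the totals needed for fractions."""

    clusters: list[Cluster]
    tumor_components: list[np.ndarray]   # components containing >= 1 E cell
    total_h: int

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.clusters], dtype=int)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def mean_size(self) -> float:
        """N̄; NaN when nothing has been released."""
        return float(self.sizes.mean()) if self.clusters else float("nan")

    @property
    def released_h(self) -> int:
        return int(self.sizes.sum())

    @property
    def released_fraction(self) -> float:
        """f̄_H = released H cells / total H cells."""
        if self.total_h == 0:
            raise ValueError("no H cells in the system")
        return self.released_h / self.total_h

    @property
    def f_singlecell(self) -> float:
        if not self.clusters:
            return float("nan")
        return float((self.sizes == 1).sum() / self.n_clusters)


#: Half-plane offset sets defining when two cells touch.
ADJACENCY = {
    "edge": [(1, 0), (0, 1)],
    "moore8": [(1, 0), (0, 1), (1, 1), (1, -1)],
}


def cell_adjacency(sim, adjacency: str = "edge") -> np.ndarray:
    """Unique adjacent (cell, cell) id pairs under the given contact rule."""
    grid = sim.grid
    pairs = []
    if adjacency == "shell":
        half = [(di, dj) for di, dj in sim.offs
                if di > 0 or (di == 0 and dj > 0)]
    else:
        try:
            half = ADJACENCY[adjacency]
        except KeyError:
            raise ValueError(f"unknown adjacency {adjacency!r}; choose from "
                             f"{sorted(ADJACENCY) + ['shell']}") from None
    for di, dj in half:
        neigh = np.roll(grid, (-di, -dj), axis=(0, 1))
        mask = (grid != neigh) & (grid != 0) & (neigh != 0)
        if mask.any():
            pairs.append(np.stack([grid[mask], neigh[mask]], axis=1))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    allp = np.concatenate(pairs)
    allp = np.sort(allp, axis=1)
    return np.unique(allp, axis=0)


def label_clusters(sim, epithelial: tuple[str, ...] = ("E",),
                   adjacency: str = "edge") -> ClusterSummary:
    """Connected components of the cell-contact graph, classified.

    Components containing an epithelial cell count as tumor side; all-H
    components are the released clusters.
    """
    live = sim.live_cells
    ncells = len(sim.area)
    pairs = cell_adjacency(sim, adjacency)
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
        shape=(ncells, ncells))
    _, comp = connected_components(adj, directed=False)
    e_idx = {sim.types.index(name) for name in epithelial
             if name in sim.types.names}
    is_e = np.isin(sim.cell_types, list(e_idx))
    is_h = ~is_e & (np.arange(ncells) != 0)
    total_h = int((is_h[live]).sum())
    clusters: list[Cluster] = []
    tumor: list[np.ndarray] = []
    for label in np.unique(comp[live]):
        members = live[comp[live] == label]
        if is_e[members].any():
            tumor.append(members)
        else:
            clusters.append(Cluster(
                members=members,
                type_names=[sim.type_name(c) for c in members],
                mu=sim.mu[members].copy()))
    return ClusterSummary(clusters=clusters, tumor_components=tumor,
                          total_h=total_h)


def released_fraction(summary: ClusterSummary, total_h: int | None = None) -> float:
    """f̄_H; ``total_h`` overrides the count recorded in the summary."""
    if total_h is not None:
        if total_h <= 0:
            raise ValueError("total_h must be positive")
        return summary.released_h / total_h
    return summary.released_fraction


def size_distribution(summaries) -> pd.Series:
    """Normalized cluster-size histogram P(N), Σ P(N) = 1.

    Accepts one summary or an iterable of summaries; replicates are pooled
    (all clusters concatenated) before normalizing.
    """
    if isinstance(summaries, ClusterSummary):
        summaries = [summaries]
    sizes = np.concatenate([s.sizes for s in summaries]) if summaries else np.array([])
    if sizes.size == 0:
        return pd.Series(dtype=float, name="P")
    vals, counts = np.unique(sizes, return_counts=True)
    p = pd.Series(counts / counts.sum(), index=vals, name="P")
    p.index.name = "N"
    return p


def composition_split(summaries, type_a: str = "H1",
                      type_b: str = "H2") -> pd.DataFrame:
    """Split P(N) into only-``type_a`` / only-``type_b`` / mixed sub-histograms.

    The three columns sum to P(N) at every N.  Only meaningful in the binary
    phenotype mode; raises if neither subtype occurs in any cluster.
    """
    if isinstance(summaries, ClusterSummary):
        summaries = [summaries]
    clusters = [c for s in summaries for c in s.clusters]
    seen = {t for c in clusters for t in c.type_names}
    if type_a not in seen and type_b not in seen:
        raise ValueError(
            f"no {type_a!r}/{type_b!r} cells found; composition_split "
            "requires the binary phenotype mode")
    total = len(clusters)
    rows: dict[int, np.ndarray] = {}
    for c in clusters:
        kinds = set(c.type_names)
        row = rows.setdefault(c.size, np.zeros(3))
        if kinds == {type_a}:
            row[0] += 1
        elif kinds == {type_b}:
            row[1] += 1
        else:
            row[2] += 1
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"P_only_{type_a}", f"P_only_{type_b}", "P_mixed"])
    df = df.sort_index() / total
    df.index.name = "N"
    return df


def per_cluster_mu_stats(summaries) -> pd.DataFrame:
    """Mean and std of member μ per cluster size N.

    Cells of all clusters of a given size are pooled; std is the population
    standard deviation.  Used to quantify how EMT-ness (μ) segregates by
    cluster size in the spectrum mode.
    """
    if isinstance(summaries, ClusterSummary):
        summaries = [summaries]
    pools: dict[int, list[np.ndarray]] = {}
    nclust: dict[int, int] = {}
    for s in summaries:
        for c in s.clusters:
            pools.setdefault(c.size, []).append(c.mu)
            nclust[c.size] = nclust.get(c.size, 0) + 1
    rows = []
    for size in sorted(pools):
        mu = np.concatenate(pools[size])
        rows.append({"N": size, "mu_mean": mu.mean(),
                     "mu_std": mu.std(ddof=0), "n_cells": len(mu),
                     "n_clusters": nclust[size]})
    return pd.DataFrame(rows).set_index("N") if rows else pd.DataFrame(
        columns=["mu_mean", "mu_std", "n_cells", "n_clusters"])


def shape_metrics(sim, types: tuple[str, ...] = ("H", "H1", "H2")) -> pd.DataFrame:
    """Per-cell shape index p/√a and circularity 4πa/p².

    Computed under the simulation's configured perimeter convention for the
    motile cell types (a square of side L has shape index 4 and circularity
    π/4 under the edge-count perimeter).
    """
    idx = [sim.types.index(t) for t in types if t in sim.types.names]
    ids = sim.live_cells
    ids = ids[np.isin(sim.cell_types[ids], idx)]
    a = sim.area[ids].astype(float)
    p = sim.perim[ids].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = pd.DataFrame({
            "cell_id": ids,
            "area": a,
            "perimeter": p,
            "shape_index": p / np.sqrt(a),
            "circularity": 4.0 * np.pi * a / (p * p),
        })
    return df


def fragmentation_check(sim, connectivity: int = 4) -> list[int]:
    """Ids of cells whose pixel sets are not connected (lattice artifact).

    Connectivity 4 (default) or 8, with periodic wrap.  An empty list means
    no cell has fragmented.
    """
    if connectivity == 4:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        offs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                if (di, dj) != (0, 0)]
    else:
        raise ValueError("connectivity must be 4 or 8")
    n = sim.n
    fragmented = []
    coords_by_cell: dict[int, list[tuple[int, int]]] = {}
    for (i, j), c in np.ndenumerate(sim.grid):
        if c != 0:
            coords_by_cell.setdefault(int(c), []).append((i, j))
    for c, coords in coords_by_cell.items():
        pixels = set(coords)
        stack = [coords[0]]
        seen = {coords[0]}
        while stack:
            i, j = stack.pop()
            for di, dj in offs:
                q = ((i + di) % n, (j + dj) % n)
                if q in pixels and q not in seen:
                    seen.add(q)
                    stack.append(q)
        if len(seen) != len(pixels):
            fragmented.append(c)
    return sorted(fragmented)


def summarize(sim, epithelial: tuple[str, ...] = ("E",)) -> dict:
    """One time-series row of scalar statistics for the current state."""
    s = label_clusters(sim, epithelial=epithelial)
    return {
        "mcs": sim.mcs,
        "n_mean": s.mean_size,
        "f_h": s.released_fraction if s.total_h else float("nan"),
        "n_clusters": s.n_clusters,
        "f_singlecell": s.f_singlecell,
    }


def time_series(rows: list[dict]) -> pd.DataFrame:
    """Assemble summarize() rows (fixed mcs cadence) into a table."""
    return pd.DataFrame(rows, columns=["mcs", "n_mean", "f_h", "n_clusters",
                                       "f_singlecell"])
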