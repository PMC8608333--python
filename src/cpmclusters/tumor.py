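"""Initial primary-tumor configurations.

The starting state of every experiment is a compact disk of cells in the
middle of the lattice: 60% nonmotile epithelial (E) cells and 40% motile
hybrid (H) cells by default, with the H positions chosen uniformly at random
inside the tumor.  Three phenotype modes cover the experiment classes:

* ``single``  — one H type, a common motile force μ,
* ``binary``  — two H subtypes H1/H2 (default number ratio E:H1:H2 = 6:2:2)
  differing in μ (and optionally in their medium contact energy),
* ``spectrum``— each H cell draws its own μ ~ Normal(mu_mean, mu_sigma),
  truncated at 0 (a negative motile force would just mean nonmotile).

Cells are initialized as square blocks of ~target_area pixels packed on a
grid and clipped to a disk; the first ~100 mcs of any run anneal the block
shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TumorSpec:
    """Composition of the primary tumor.

    ``fraction_h`` is rounded to the nearest integer H-cell count; the E
    count absorbs the remainder.  In binary mode the H cells are split
    evenly into H1 and H2 (E:H1:H2 = 6:2:2 at the default fraction 0.4).
    """

    total_cells: int
    fraction_h: float = 0.4
    phenotype_mode: str = "single"  # single | binary | spectrum
    mu_h: float = 0.0
    mu_h1: float = 40.0
    mu_h2: float = 40.0
    mu_mean: float = 40.0
    mu_sigma: float = 0.0

    def counts(self) -> dict[str, int]:
        if not 0.0 <= self.fraction_h <= 1.0:
            raise ValueError("fraction_h must lie in [0, 1]")
        n_h = int(round(self.total_cells * self.fraction_h))
        n_e = self.total_cells - n_h
        if self.phenotype_mode == "binary":
            n_h1 = n_h // 2
            return {"E": n_e, "H1": n_h1, "H2": n_h - n_h1}
        return {"E": n_e, "H": n_h}


def assign_phenotypes(spec: TumorSpec, rng: np.random.Generator):
    """Random phenotype labels and per-cell μ for cell ids 1..total_cells.

    Returns ``(type_names, mu)`` where ``type_names[k]`` is the label of
    cell id k+1.  H identities are scattered uniformly over the tumor cell
    ids, which correspond to random positions inside the disk.
    """
    counts = spec.counts()
    labels = np.array(
        sum(([name] * cnt for name, cnt in counts.items()), []), dtype=object)
    order = rng.permutation(spec.total_cells)
    labels = labels[order]
    mu = np.zeros(spec.total_cells)
    if spec.phenotype_mode == "single":
        mu[labels == "H"] = spec.mu_h
    elif spec.phenotype_mode == "binary":
        mu[labels == "H1"] = spec.mu_h1
        mu[labels == "H2"] = spec.mu_h2
    elif spec.phenotype_mode == "spectrum":
        is_h = labels == "H"
        draws = rng.normal(spec.mu_mean, spec.mu_sigma, size=int(is_h.sum()))
        mu[is_h] = np.clip(draws, 0.0, None)
    else:
        raise ValueError(f"unknown phenotype mode {spec.phenotype_mode!r}")
    return labels, mu


def build_primary_tumor(spec: TumorSpec, lattice_size: int,
                        target_area: float = 25.0,
                        rng: np.random.Generator | None = None,
                        seed: int | None = 0):
    """Construct the initial lattice: a centered disk of block-shaped cells.

    Returns ``(grid, type_names, mu)``: the pixel → cell-id grid, the
    phenotype label per cell id (index 0 = "medium"), and the per-cell μ
    array (index 0 = 0).

    Raises ``ValueError`` if the tumor disk does not fit with a medium
    margin of at least one cell diameter around it.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    side = max(1, int(round(np.sqrt(target_area))))
    # candidate block positions, nearest-to-center first (deterministic ties)
    nblocks = int(np.ceil(np.sqrt(spec.total_cells))) * 2 + 3
    half = nblocks // 2
    cand = [(bi, bj) for bi in range(-half, half + 1)
            for bj in range(-half, half + 1)]
    cand.sort(key=lambda b: (b[0] ** 2 + b[1] ** 2, b))
    blocks = cand[:spec.total_cells]
    if len(blocks) < spec.total_cells:
        raise ValueError("internal block grid too small")  # pragma: no cover
    center = lattice_size // 2
    extent = max(max(abs(bi), abs(bj)) for bi, bj in blocks) + 1
    radius_px = (extent + 0.5) * side
    if center - radius_px < side or center + radius_px > lattice_size - side:
        raise ValueError(
            f"tumor of {spec.total_cells} cells (radius ~{radius_px:.0f} px) "
            f"does not fit a {lattice_size}x{lattice_size} lattice with a "
            "one-cell-diameter medium margin")
    grid = np.zeros((lattice_size, lattice_size), dtype=np.int64)
    for cell_id, (bi, bj) in enumerate(blocks, start=1):
        i0 = center + bi * side - side // 2
        j0 = center + bj * side - side // 2
        grid[i0:i0 + side, j0:j0 + side] = cell_id
    labels, mu = assign_phenotypes(spec, rng)
    type_names = np.concatenate([["medium"], labels])
    mu = np.concatenate([[0.0], mu])
    return grid, type_names, mu
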