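"""Snapshot and table output in portable text formats.

Snapshots are a plain integer grid (one lattice row per line) plus a
per-cell CSV; every CSV carries a header comment with the code version and
the full parameter set of the run that produced it, so outputs are
self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__


def save_grid(grid: np.ndarray, path) -> None:
    np.savetxt(path, grid, fmt="%d")


def load_grid(path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int64)


def write_csv(df: pd.DataFrame, path, params: dict | None = None,
              index: bool = False) -> None:
    """CSV with a ``#``-comment header recording version and parameters."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# cpmclusters {__version__}\n")
        if params is not None:
            fh.write(f"# params {json.dumps(params, sort_keys=True)}\n")
        df.to_csv(fh, index=index)


def read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def save_snapshot(sim, outdir, tag: str, params: dict | None = None) -> None:
    """Write the lattice grid and per-cell table for the current state."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_grid(sim.grid, outdir / f"grid_{tag}.txt")
    write_csv(sim.cells_dataframe(), outdir / f"cells_{tag}.csv", params=params)
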