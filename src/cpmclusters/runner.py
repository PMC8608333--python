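"""Experiment orchestration: parameter sets, sweeps, replicates, presets.

A run is fully described by a nested parameter dict (see
:data:`BASE_PARAMS`); a sweep is a manifest holding that base plus lists of
values for one or more swept parameters.  Outputs are plain CSVs: a sweep
table with one row per (parameter combination, replicate) holding the
end-of-run cluster statistics, and a time-series table sampled at a fixed
mcs cadence.  Everything (including the manifest itself) is written to the
output directory before execution, and outputs are a pure function of
(manifest, seed).

Presets encode the standard experiment regimes of the model.  The
baseline regime is: a 517-cell tumor (60% E, 40% H) on a 200×200 lattice,
J_EE = 2, γ_Em = 19, J_HH = 6, J_EH = max(J_EE, J_HH) = J_HH, T_E = T_H = 1,
λ_a = 1, a₀ = 25, τ = 50, measured at mcs = 50000 over 20 replicates.
The target area a₀ and the perimeter-constraint strength are not fixed by
the regime definitions; the values here are this package's calibrated
defaults.  Every preset also carries a "desk" profile (120×120 lattice,
~120 cells, 10000 mcs, 3 replicates) for laptop-scale runs.
"""

from __future__ import annotations

import copy
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clusters import summarize, time_series
from .config import dump_config
from .engine import CellTypeSpec, ContactTable, Simulation, TypeTable
from .io import save_snapshot, write_csv
from .scaling import SWEEP_COLUMNS
from .tumor import TumorSpec, build_primary_tumor

BASE_PARAMS: dict = {
    "lattice": {"size": 200, "shell": "dist2", "copy_shell": "moore8",
                "perimeter": "edge"},
    "tumor": {"total_cells": 517, "fraction_h": 0.4,
              "phenotype_mode": "single", "mu_h": 40.0,
              "mu_h1": 40.0, "mu_h2": 40.0,
              "mu_mean": 40.0, "mu_sigma": 0.0},
    "types": {
        "E": {"T": 1.0, "lambda_area": 1.0, "target_area": 25.0},
        "H": {"T": 1.0, "lambda_area": 1.0, "target_area": 25.0,
              "lambda_perim": 0.0, "target_perim": 0.0},
    },
    "contact": {"J_EE": 2.0, "J_HH": 6.0, "gamma_Em": 19.0,
                "gamma_Hm": 3.0, "J_EH": None, "gamma_Hm_H2": None},
    "motility": {"tau": 50, "mode": "com"},
    "run": {"mcs": 50000, "record_every": 1000, "replicates": 20, "seed": 0},
}

#: Shorthand sweep-axis names -> dotted parameter paths.
AXES = {
    "mu": "tumor.mu_h",
    "mu_h2": "tumor.mu_h2",
    "gamma": "contact.gamma_Hm",
    "gamma_h2": "contact.gamma_Hm_H2",
    "gamma_Em": "contact.gamma_Em",
    "J_EH": "contact.J_EH",
    "T_H": "types.H.T",
    "T_E": "types.E.T",
    "lambda_a": "types.H.lambda_area",
    "tau": "motility.tau",
    "p0": "types.H.target_perim",
    "sigma": "tumor.mu_sigma",
    "total_cells": "tumor.total_cells",
    "size": "lattice.size",
}


def set_param(params: dict, path: str, value) -> None:
    path = AXES.get(path, path)
    keys = path.split(".")
    node = params
    for key in keys[:-1]:
        node = node[key]
    if keys[-1] not in node:
        raise KeyError(f"unknown parameter {path!r}")
    node[keys[-1]] = value


def get_param(params: dict, path: str):
    node = params
    for key in AXES.get(path, path).split("."):
        node = node[key]
    return node


def build_simulation(params: dict, seed: int) -> Simulation:
    """Assemble the initial tumor state and engine for one run."""
    p = params
    mode = p["tumor"]["phenotype_mode"]
    spec = TumorSpec(
        total_cells=int(p["tumor"]["total_cells"]),
        fraction_h=p["tumor"]["fraction_h"],
        phenotype_mode={"single": "single", "binary": "binary",
                        "spectrum": "spectrum"}[mode],
        mu_h=p["tumor"]["mu_h"], mu_h1=p["tumor"]["mu_h1"],
        mu_h2=p["tumor"]["mu_h2"], mu_mean=p["tumor"]["mu_mean"],
        mu_sigma=p["tumor"]["mu_sigma"])
    h_names = {"single": ["H"], "spectrum": ["H"],
               "binary": ["H1", "H2"]}[mode]
    htype = p["types"]["H"]
    specs = [CellTypeSpec("E", **p["types"]["E"])]
    specs += [CellTypeSpec(name, **htype) for name in h_names]
    types = TypeTable(specs)
    c = p["contact"]
    J_EE, J_HH = c["J_EE"], c["J_HH"]
    J_Em = c["gamma_Em"] + J_EE / 2.0
    J_EH = c["J_EH"] if c["J_EH"] is not None else max(J_EE, J_HH)
    energies = {("E", "E"): J_EE, ("E", "medium"): J_Em}
    gam = {"H": c["gamma_Hm"], "H1": c["gamma_Hm"],
           "H2": c["gamma_Hm_H2"] if c["gamma_Hm_H2"] is not None
           else c["gamma_Hm"]}
    for name in h_names:
        energies[(name, name)] = J_HH
        energies[(name, "medium")] = gam[name] + J_HH / 2.0
        energies[(name, "E")] = J_EH
    if len(h_names) == 2:
        energies[("H1", "H2")] = J_HH
    contact = ContactTable(types, energies)
    grid, type_names, mu = build_primary_tumor(
        spec, int(p["lattice"]["size"]),
        target_area=htype.get("target_area", 25.0),
        rng=np.random.default_rng(seed))
    cell_types = np.array([types.index(name) for name in type_names])
    return Simulation(grid=grid, cell_types=cell_types, types=types,
                      contact=contact, mu=mu,
                      tau=int(p["motility"]["tau"]),
                      motility_mode=p["motility"].get("mode", "com"),
                      shell=p["lattice"]["shell"],
                      copy_shell=p["lattice"].get("copy_shell", "moore8"),
                      perimeter=p["lattice"]["perimeter"], seed=seed)


def run_single(params: dict, seed: int, record_every: int | None = None):
    """One replicate: returns (final Simulation, time-series DataFrame)."""
    total = int(params["run"]["mcs"])
    cadence = record_every or int(params["run"]["record_every"])
    sim = build_simulation(params, seed)
    rows = [summarize(sim)]
    done = 0
    while done < total:
        step = min(cadence, total - done)
        sim.run_mcs(step)
        done += step
        rows.append(summarize(sim))
    return sim, time_series(rows)


@dataclass
class ExperimentManifest:
    """A named sweep: base parameters plus axis value lists.

    ``sweep`` maps axis names (shorthand from :data:`AXES` or dotted paths)
    to value lists; the run grid is their Cartesian product times
    ``replicates``.
    """

    name: str
    params: dict = field(default_factory=lambda: copy.deepcopy(BASE_PARAMS))
    sweep: dict = field(default_factory=dict)
    notes: str = ""

    def combos(self) -> list[dict]:
        axes = list(self.sweep)
        values = [self.sweep[a] for a in axes]
        return [dict(zip(axes, combo))
                for combo in itertools.product(*values)]

    def to_json(self) -> str:
        return json.dumps({"name": self.name, "params": self.params,
                           "sweep": self.sweep, "notes": self.notes},
                          indent=2, sort_keys=True)


def run_experiment(manifest: ExperimentManifest, outdir,
                   snapshots: bool = False) -> Path:
    """Execute every (combination, replicate) cell of the manifest.

    Writes ``manifest.json`` up front, then ``sweep.csv`` (end-of-run
    statistics per run) and ``timeseries.csv``.  Replicate r of combination
    k runs with seed = base_seed + 100003*k + r, so any single cell can be
    reproduced in isolation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(manifest.to_json())
    base_seed = int(manifest.params["run"]["seed"])
    replicates = int(manifest.params["run"]["replicates"])
    sweep_rows = []
    ts_frames = []
    for k, combo in enumerate(manifest.combos()):
        params = copy.deepcopy(manifest.params)
        for axis, value in combo.items():
            set_param(params, axis, value)
        for rep in range(replicates):
            seed = base_seed + 100003 * k + rep
            sim, ts = run_single(params, seed)
            stats = summarize(sim)
            row = {"mu": get_param(params, "mu"),
                   "gamma": get_param(params, "gamma"),
                   "replicate": rep,
                   "n_mean": stats["n_mean"], "f_h": stats["f_h"],
                   "n_clusters": stats["n_clusters"],
                   "f_singlecell": stats["f_singlecell"]}
            row.update({f"axis_{a}": v for a, v in combo.items()})
            sweep_rows.append(row)
            for axis, value in combo.items():
                ts[f"axis_{axis}"] = value
            ts["replicate"] = rep
            ts_frames.append(ts)
            if snapshots:
                tag = "_".join([f"{a}{v}" for a, v in combo.items()]
                               + [f"rep{rep}"])
                save_snapshot(sim, outdir / "snapshots", tag, params=params)
    extra = [c for c in sweep_rows[0] if c not in SWEEP_COLUMNS] \
        if sweep_rows else []
    sweep = pd.DataFrame(sweep_rows, columns=SWEEP_COLUMNS + extra)
    write_csv(sweep, outdir / "sweep.csv", params=manifest.params)
    write_csv(pd.concat(ts_frames, ignore_index=True),
              outdir / "timeseries.csv", params=manifest.params)
    return outdir


# ----------------------------------------------------------------------
# figure-regime presets
# ----------------------------------------------------------------------

def _base(**overrides) -> dict:
    params = copy.deepcopy(BASE_PARAMS)
    for path, value in overrides.items():
        set_param(params, path, value)
    return params


def preset(name: str, desk: bool = False) -> ExperimentManifest:
    """Manifest for a standard experiment regime.

    With ``desk=True`` the run is scaled down (120×120 lattice, ~120 cells,
    10000 mcs, 3 replicates) for quick local execution; the full profile
    is hours–days of CPU.
    """
    builders = {
        "fig1_diffusive": lambda: ExperimentManifest(
            "fig1_diffusive",
            _base(**{"types.H.T": 6.0, "mu": 0.0}),
            sweep={"J_EH": [5, 6, 20, 25, 30, 35]},
            notes="fluctuation-driven dissemination, T_H=6, no active force"),
        "fig2_sweep": lambda: ExperimentManifest(
            "fig2_sweep", _base(),
            sweep={"gamma": [-1, 0, 1, 2, 3, 4],
                   "mu": [10, 20, 30, 40, 50]},
            notes="main (mu, Gamma) grid; tau=50, T_H=1, J_EH=J_HH"),
        "fig3_scaling": lambda: ExperimentManifest(
            "fig3_scaling", _base(),
            sweep={"gamma": [1, 2, 3, 4], "mu": [20, 30, 40, 50]},
            notes="collapse/fit subset of the main grid (Gamma > 0)"),
        "fig5_binary_mu": lambda: ExperimentManifest(
            "fig5_binary_mu",
            _base(**{"tumor.phenotype_mode": "binary",
                     "tumor.mu_h1": 40.0, "tumor.mu_h2": 35.0}),
            sweep={}, notes="two H subtypes, E:H1:H2 = 6:2:2, Gamma=3"),
        "fig6_deltamu": lambda: ExperimentManifest(
            "fig6_deltamu",
            _base(**{"tumor.phenotype_mode": "binary",
                     "tumor.mu_h1": 40.0}),
            sweep={"mu_h2": [20, 25, 30, 35, 40, 45, 50]},
            notes="delta-mu scan at mu(H1)=40, Gamma=3"),
        "fig7_spectrum": lambda: ExperimentManifest(
            "fig7_spectrum",
            _base(**{"tumor.phenotype_mode": "spectrum",
                     "tumor.mu_mean": 40.0}),
            sweep={"sigma": [0, 1, 2, 3, 5, 7, 10]},
            notes="mu ~ Normal(40, sigma) spectrum at Gamma=3"),
        "fig8_perimeter": lambda: ExperimentManifest(
            "fig8_perimeter",
            _base(**{"types.H.lambda_perim": 1.0}),
            sweep={"p0": [20, 22, 24, 25, 26, 28, 30],
                   "mu": [40, 50]},
            notes="perimeter-constrained H cells at Gamma=3; lambda_p "
                  "calibrated (source table not transcribed)"),
        "s1_JEH_TH": lambda: ExperimentManifest(
            "s1_JEH_TH", _base(**{"mu": 0.0}),
            sweep={"J_EH": [20, 25, 30, 35], "T_H": [2, 4, 6, 8]},
            notes="diffusive regime cross-scan"),
        "s4_TH_lambda": lambda: ExperimentManifest(
            "s4_TH_lambda", _base(),
            sweep={"T_H": [1, 2, 3, 4, 5, 6],
                   "lambda_a": [0.5, 1.0, 2.0, 4.0]},
            notes="fluctuation and bulk-modulus dependence at mu=40, Gamma=3"),
        "s5_gammaEm_TE": lambda: ExperimentManifest(
            "s5_gammaEm_TE", _base(),
            sweep={"gamma_Em": [4, 9, 14, 19], "T_E": [1, 2, 4],
                   "mu": [30, 40]},
            notes="E-cell rigidity and fluctuation dependence"),
        "s6_tau": lambda: ExperimentManifest(
            "s6_tau", _base(),
            sweep={"tau": [10, 20, 30, 40, 50, 75, 100], "mu": [40, 50]},
            notes="persistence-time dependence at Gamma=3"),
        "s8_system_size": lambda: ExperimentManifest(
            "s8_system_size", _base(),
            sweep={"total_cells": [517, 2109], "size": [200, 400]},
            notes="system-size check; run the matched (cells, size) pairs "
                  "to keep the H number density fixed"),
        "s10_deltaGamma": lambda: ExperimentManifest(
            "s10_deltaGamma",
            _base(**{"tumor.phenotype_mode": "binary"}),
            sweep={"gamma_h2": [1, 2, 3, 4, 5], "mu": [30, 40]},
            notes="two H subtypes differing in Gamma; Gamma(H1)=3"),
    }
    try:
        manifest = builders[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; "
                         f"choose from {sorted(builders)}") from None
    if desk:
        set_param(manifest.params, "run.mcs", 10000)
        set_param(manifest.params, "run.replicates", 3)
        set_param(manifest.params, "run.record_every", 2000)
        set_param(manifest.params, "lattice.size", 120)
        set_param(manifest.params, "tumor.total_cells", 120)
        if "total_cells" in manifest.sweep:
            manifest.sweep["total_cells"] = [120, 480]
            manifest.sweep["size"] = [120, 240]
    return manifest


PRESET_NAMES = ("fig1_diffusive", "fig2_sweep", "fig3_scaling",
                "fig5_binary_mu", "fig6_deltamu", "fig7_spectrum",
                "fig8_perimeter", "s1_JEH_TH", "s4_TH_lambda",
                "s5_gammaEm_TE", "s6_tau", "s8_system_size", "s10_deltaGamma")


def write_preset_config(name: str, path, desk: bool = False) -> None:
    """Write a preset's base parameters as a TOML config file."""
    manifest = preset(name, desk=desk)
    params = copy.deepcopy(manifest.params)
    params["sweep"] = {k: list(v) for k, v in manifest.sweep.items()}
    dump_config(params, path)
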