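"""Data collapse and power-law fits of the mean cluster size.

Across the (μ, Γ) sweep the mean released-cluster size follows an
approximate scaling law

    N̄ ≈ N₀ · Γ^m / μ^n        (Γ > 1, μ > μ_min(Γ))

recovered in three steps that mirror the simulation analysis:

1. normalize each Γ-curve by its value at a reference μ (= 50) and fit the
   collapsed curve to (50/μ)^n,
2. fit the Γ-dependence of the μ = 50 column, normalized at Γ = 2, to
   (Γ/2)^m,
3. fix (n, m), form x = Γ^m/μ^n and fit N̄(x) both by a straight line
   through the origin (slope N₀) and by a free power law A·x^p (p ≈ 1
   confirms linearity).

Fits are nonlinear least squares in linear space (replicate noise on N̄ is
roughly additive); a log-space option exists for diagnostics.  Reported
uncertainties are 1-sigma values from the fit covariance.  The module also
provides the synthetic sweep generator used for parameter-recovery checks,
and the dissemination-threshold estimator μ_min(Γ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

SWEEP_COLUMNS = ["mu", "gamma", "replicate", "n_mean", "f_h", "n_clusters",
                 "f_singlecell"]


@dataclass
class FitResult:
    value: float
    sigma: float


@dataclass
class ScalingFit:
    """Fitted exponents and prefactors of the collapse N̄ ~ Γ^m/μ^n."""

    n: FitResult
    m: FitResult
    N0: FitResult            # slope of the through-origin line in x
    p: FitResult             # exponent of the free power law in x
    amplitude: FitResult     # prefactor of the free power law
    n_fix: float
    m_fix: float


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean and std of N̄ per (μ, Γ) grid point."""
    g = table.groupby(["gamma", "mu"])["n_mean"]
    out = g.agg(n_mean="mean", n_std="std", n_rep="size").reset_index()
    out["n_std"] = out["n_std"].fillna(0.0)
    return out


def collapse_mu(table: pd.DataFrame, reference_mu: float = 50,
                gamma_min: float = 1.0) -> pd.DataFrame:
    """Each Γ-curve of N̄(μ) divided by its own value at the reference μ.

    Restricted to Γ > ``gamma_min``, the regime where the curves collapse.
    Raises if any retained Γ lacks the reference point.
    """
    agg = aggregate(table)
    agg = agg[agg["gamma"] > gamma_min].copy()
    out = []
    for gamma, grp in agg.groupby("gamma"):
        ref = grp.loc[grp["mu"] == reference_mu, "n_mean"]
        if ref.empty or not np.isfinite(ref.iloc[0]) or ref.iloc[0] <= 0:
            raise ValueError(
                f"no usable reference point mu={reference_mu} for "
                f"gamma={gamma}")
        grp = grp.copy()
        grp["n_norm"] = grp["n_mean"] / ref.iloc[0]
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def fit_exponent_n(collapsed: pd.DataFrame, reference_mu: float = 50,
                   log_space: bool = False) -> FitResult:
    """Fit the collapsed curve to (reference_mu/μ)^n."""
    d = collapsed.dropna(subset=["n_norm"])
    d = d[d["mu"] > 0]
    mu = d["mu"].to_numpy(float)
    y = d["n_norm"].to_numpy(float)
    if len(np.unique(mu)) < 4:
        raise ValueError("need at least 4 distinct mu values")
    if np.allclose(y, y[0]):
        if np.allclose(y, 1.0):
            return FitResult(0.0, 0.0)
        raise ValueError("degenerate collapsed data")
    return _fit_power(reference_mu / mu, y, log_space)


def fit_exponent_m(table: pd.DataFrame, reference_mu: float = 50,
                   reference_gamma: float = 2.0,
                   log_space: bool = False) -> FitResult:
    """Fit N̄_{μ=ref}(Γ)/N̄_{μ=ref}(Γ=2) to (Γ/2)^m."""
    agg = aggregate(table)
    col = agg[(agg["mu"] == reference_mu) & (agg["gamma"] > 0)]
    ref = col.loc[col["gamma"] == reference_gamma, "n_mean"]
    if len(col["gamma"].unique()) < 3 or ref.empty:
        raise ValueError("need >= 3 gamma values including the reference")
    y = (col["n_mean"] / ref.iloc[0]).to_numpy(float)
    x = (col["gamma"] / reference_gamma).to_numpy(float)
    if np.allclose(y, 1.0):
        return FitResult(0.0, 0.0)
    return _fit_power(x, y, log_space)


def fit_master_curve(table: pd.DataFrame, n_fix: float = 2.8,
                     m_fix: float = 2.0, gamma_min: float = 1.0,
                     weighted: bool = True):
    """Fit N̄ against x = Γ^m_fix/μ^n_fix two ways.

    Returns ``(N0, p, amplitude)`` where N0 is the slope of the
    through-origin straight line and (amplitude, p) parametrize the free
    power law A·x^p.  Points with Γ ≤ gamma_min, μ ≤ 0 or undefined N̄ are
    excluded (below the dissemination threshold N̄ is not defined).
    """
    agg = aggregate(table)
    d = agg[(agg["gamma"] > gamma_min) & (agg["mu"] > 0)].dropna(subset=["n_mean"])
    if len(d) < 3:
        raise ValueError("need at least 3 usable (mu, gamma) points")
    x = (d["gamma"] ** m_fix / d["mu"] ** n_fix).to_numpy(float)
    y = d["n_mean"].to_numpy(float)
    sigma = None
    if weighted and (d["n_std"] > 0).all() and (d["n_rep"] > 1).all():
        sigma = d["n_std"].to_numpy(float)
    popt, pcov = curve_fit(lambda x, N0: N0 * x, x, y, p0=[y.max() / x.max()],
                           sigma=sigma, absolute_sigma=False)
    N0 = FitResult(float(popt[0]), float(np.sqrt(pcov[0, 0])))
    popt, pcov = curve_fit(lambda x, A, p: A * np.power(x, p), x, y,
                           p0=[N0.value, 1.0], sigma=sigma,
                           absolute_sigma=False, maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    amplitude = FitResult(float(popt[0]), float(perr[0]))
    p = FitResult(float(popt[1]), float(perr[1]))
    return N0, p, amplitude


def fit_all(table: pd.DataFrame, reference_mu: float = 50,
            gamma_min: float = 1.0) -> ScalingFit:
    """The full pipeline: collapse, both exponents, then the master curve.

    The collapse variable x = Γ^m/μ^n uses the fitted exponents rounded to
    one decimal (the precision at which they are meaningful given their
    uncertainties); carrying more digits lets exponent noise propagate
    exponentially (≈ μ^Δn) into the slope N₀.
    """
    collapsed = collapse_mu(table, reference_mu, gamma_min)
    n = fit_exponent_n(collapsed, reference_mu)
    m = fit_exponent_m(table, reference_mu)
    n_fix = round(n.value, 1)
    m_fix = round(m.value, 1)
    N0, p, amplitude = fit_master_curve(table, n_fix=n_fix, m_fix=m_fix,
                                        gamma_min=gamma_min)
    return ScalingFit(n=n, m=m, N0=N0, p=p, amplitude=amplitude,
                      n_fix=n_fix, m_fix=m_fix)


@dataclass
class MuMinEstimate:
    mu_min: float | None          # None = above the scanned range
    bracket: tuple[float, float] | None
    epsilon: float

    @property
    def above_scan_range(self) -> bool:
        return self.mu_min is None


def estimate_mu_min(scan: pd.DataFrame, gamma: float,
                    epsilon: float = 0.05) -> MuMinEstimate:
    """Smallest scanned μ whose mean released fraction exceeds ``epsilon``.

    Operationalizes the dissemination threshold μ_min(Γ): below it
    essentially no H cells escape.  Returns the bracketing grid interval
    (largest sub-threshold μ, first supra-threshold μ), or an
    above-scan-range sentinel when no point passes.
    """
    d = scan[scan["gamma"] == gamma]
    if d.empty:
        raise ValueError(f"no scan rows at gamma={gamma}")
    f = d.groupby("mu")["f_h"].mean().sort_index()
    above = f[f > epsilon]
    if above.empty:
        return MuMinEstimate(None, None, epsilon)
    mu_min = float(above.index[0])
    below = f.index[f.index < mu_min]
    lo = float(below[-1]) if len(below) else float("-inf")
    return MuMinEstimate(mu_min, (lo, mu_min), epsilon)


def synthetic_sweep(mus, gammas, replicates: int = 20, N0: float = 35329.0,
                    n: float = 2.8, m: float = 2.0, noise: float = 0.10,
                    rng: np.random.Generator | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Synthetic SweepTable drawn from the scaling law plus replicate noise.

    N̄ per replicate is N₀Γ^m/μ^n times a multiplicative Gaussian factor of
    relative width ``noise`` (about the scatter of the replicate means in
    the simulated sweeps).  Used for the desk-scale parameter-recovery check
    of the fitting pipeline.
    """
    rng = rng or np.random.default_rng(seed)
    rows = []
    for gamma in gammas:
        for mu in mus:
            base = N0 * gamma ** m / mu ** n
            for rep in range(replicates):
                nb = base * (1.0 + noise * rng.standard_normal())
                rows.append({"mu": mu, "gamma": gamma, "replicate": rep,
                             "n_mean": max(nb, 1.0), "f_h": np.nan,
                             "n_clusters": np.nan, "f_singlecell": np.nan})
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def _fit_power(x: np.ndarray, y: np.ndarray, log_space: bool) -> FitResult:
    if log_space:
        mask = (x > 0) & (y > 0)
        coef, cov = np.polyfit(np.log(x[mask]), np.log(y[mask]), 1, cov=True)
        return FitResult(float(coef[0]), float(np.sqrt(cov[0, 0])))
    popt, pcov = curve_fit(lambda x, e: np.power(x, e), x, y, p0=[2.0],
                           maxfev=20000)
    return FitResult(float(popt[0]), float(np.sqrt(pcov[0, 0])))
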