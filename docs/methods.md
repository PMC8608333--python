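# Model and methods

## The model

`cpmclusters` simulates the first step of the metastatic cascade — motile
cells leaving a primary tumor as singles or small clusters — with a
two-dimensional Cellular Potts Model (CPM, Glazier–Graner–Hogeweg).  The
lattice is an n×n periodic grid of unit pixels; each biological cell is the
set of pixels carrying its integer index, and index 0 is the medium, a
special cell type with unconstrained area and perimeter.  The energy is

    H = H_contact + H_area + H_perimeter
    H_contact   = Σ_(i,j) neighbors  J[t(c_i), t(c_j)] (1 − δ_{c_i, c_j})
    H_area      = Σ_c λ_a (a_c − a₀)²
    H_perimeter = Σ_c λ_p (p_c − p₀)²

Dynamics proceed by pixel-copy attempts: a random target pixel and a random
copy-shell neighbor are drawn; if they hold different cell indices, the
neighbor's index is proposed for the target and accepted with the modified
Metropolis probability P = exp(−ΔH/T) for ΔH > 0 and P = 1 otherwise.  At a
boundary between two distinct cell types the lower of the two temperatures
is used; cell↔medium attempts use the cell's own temperature.  One Monte
Carlo step (mcs) is n×n attempts.

Two phenotypes populate the tumor: nonmotile epithelial (E) cells and
motile hybrid (H) cells, 60%/40% by default, with the H positions random
inside the initial disk.  The degree of EMT of the H cells enters through
two knobs:

* the cell–medium surface tension Γ ≡ γ_Hm = J_Hm − J_HH/2 (γ generally:
  γ_ab = J_ab − (J_aa + J_bb)/2, with J_mm = 0), and
* an active motile force μ acting along a persistent polarity n̂:
  H_motility = −Σ_c μ_c n̂_c·r⃗_c, entering the dynamics as the exact energy
  change −Σ μ_c n̂_c·Δr⃗_c of the center of mass in a proposed copy.

The polarity of each motile cell is refreshed every τ mcs to its normalized
mean center-of-mass velocity over the last τ mcs (equivalently, net
displacement over the window, normalized); a cell that did not move keeps
its previous polarity (the update rule is 0/0 there).  Between updates n̂ is
frozen, and ΔH_motility is evaluated with the pre-copy polarity.  Both the
gaining and the losing cell contribute when both are motile; the medium
contributes nothing.

A *released cluster* is a connected component of the cell-contact graph
containing only H cells; components containing at least one E cell —
including the rare all-E escapees — count as the tumor side and are
excluded from cluster statistics.  The reported statistics are the mean
released-cluster size N̄, the released fraction f̄_H (released H cells /
all H cells), the number of clusters, the single-cell fraction
f̄_singlecell, and the normalized size distribution P(N) (replicates pooled
before normalizing).  Stds of small groups use the population convention;
error bars on replicate aggregates are stds across replicates.

## Key parameters

| parameter | meaning | default | unit |
|---|---|---|---|
| J_EE, J_HH | cell–cell contact energies | 2, 6 | energy/link |
| γ_Em | E–medium surface tension | 19 (J_Em = 20) | energy/link |
| Γ = γ_Hm | H–medium surface tension | 3 (J_Hm = 6) | energy/link |
| J_EH | E–H contact energy | max(J_EE, J_HH) = 6 | energy/link |
| T_E, T_H | membrane-fluctuation temperatures | 1, 1 (6 for diffusive runs) | energy |
| λ_a, a₀ | area constraint | 1, 25 | —, pixels |
| λ_p, p₀ | perimeter constraint (H only, off by default) | 0, — | —, links |
| μ | motile force | experiment axis, 0–50 | energy·pixel⁻¹·mcs-scale |
| τ | polarity persistence time | 50 | mcs |
| lattice | box side | 200 (120 desk) | pixels |
| cells | tumor size | 517 (120 desk) | — |
| mcs | measurement epoch | 50000 (10000 desk) | mcs |
| replicates | per condition | 20 (3 desk) | — |

a₀ = 25 is a calibrated choice: unconstrained H cells then fluctuate around
an edge-count perimeter of ≈ 20–25, matching the observed mean perimeter of
≈ 25 in the perimeter-constraint experiments, whose p₀ axis spans 20–30.

## Numerical conventions

**Neighbor shells.**  H_contact sums every pixel pair within Euclidean
distance 2 (12 offsets: nearest, diagonal, and axial second-nearest), the
`dist2` shell.  Copy *sources*, however, are drawn from the 8-connected
`moore8` shell only: a copy from an axial distance-2 source would deposit a
pixel detached from the source cell, which measurably inflates
single-pixel fragmentation.  Both shells are configurable (`nn4`, `moore8`,
`dist2`) for sensitivity analysis; with a `moore8` energy shell the motile
cells fragment noticeably more at high μ.

**Perimeter.**  A cell's perimeter is the count of 4-connected pixel edges
facing a different index ("edge" convention; a 5×5 square has perimeter
20, shape index p/√a = 4, circularity 4πa/p² = π/4).  A "shell" convention
(count over the interaction shell) is available.

**Cluster adjacency.**  Two cells touch iff they share a pixel edge, so a
released cluster is exactly what a 4-connected pixel flood fill over its
member pixels joins, periodic wrap included.  The energy-shell adjacency
(available as an option) is looser than physical contact — under `dist2`
it links cells separated by a one-pixel medium gap — and inflates the
mesenchymal-limit N̄ from ≈1.04 to ≈1.12 in our measurements.

**Bookkeeping.**  Areas and perimeters are integers maintained
incrementally and checked against full recomputation; per-cell
center-of-mass sums are kept in unwrapped coordinates, assigning each
entering/leaving pixel the periodic image nearest the cell's current COM
(exact for cells of diameter < n/2).  A cell whose last pixel is copied
away keeps contributing λ_a a₀² (and λ_p p₀²) as a constant, so every ΔH
equals the difference of total energies and destroying a cell's last pixel
costs λ_a(2a₀ − 1).

**Motility formulation.**  The default is the center-of-mass form above.
Two pixel-kick variants are provided for sensitivity analysis
(`copyvector`: −(μ_new n̂_new + μ_old n̂_old)·v̂ with v̂ the unit copy vector;
`copyvector_gain`: the gaining cell only).  They are not defaults because
at μ comparable to tens of J, O(μ) kicks overpower a λ_a = 1 area
constraint: the both-cells variant rewards rear retraction and shrinks
cells to death, and the gain-only variant shreds cells into fragments over
long runs.

**Sampling caveat.**  The pixel-copy proposal is asymmetric (the forward
and reverse moves are proposed with different probabilities), so the
modified-Metropolis chain does not sample the Boltzmann distribution
exactly.  On a 3×3 two-cell system where the full transition matrix can be
enumerated, the stationary weight of the ground energy level is 0.64
versus the Boltzmann 0.72.  The test suite therefore validates the
dynamics against the exact chain stationary law and checks that level
weights are Boltzmann-ordered; energy-based statistics from this engine
should be read as properties of the standard CPM dynamics, not of exact
equilibrium sampling.

## What the experiments show, and known limitations

With these conventions the simulations reproduce the qualitative phase
structure of hybrid-cell dissemination: for Γ ≤ 0 released cells are
single (measured pooled N̄ ≈ 1.04, the excess being transient grazing
contacts at the measurement instant); for Γ > 0 there is a minimum motile
force μ_min(Γ), increasing with Γ, below which essentially nothing is
released; clusters released just above threshold are large and break up in
the medium; cells stay intact (no death, rare fragmentation).

One quantitative discrepancy is documented rather than tuned away: under
the center-of-mass motility form the dissemination threshold at Γ = 3 lies
above the studied force range (no release up to μ = 50 with the default
distance-2 shell; μ ≈ 45–50 with the moore8 shell) rather than at
≈ 20–25, and the released fraction at (μ = 50, Γ = 3) stays far below
85–90%.  The per-copy motility gain in
this form is μ·|Δr_com| ≈ μ·r/a ≲ 0.22·μ for any cell size, which cannot
match thresholds that imply per-copy gains of ≈ 0.3–0.4·μ against the
stated contact energies at T = 1; the pixel-kick variants that would supply
O(μ) gains destroy cells at λ_a = 1 (see above).  Statistics that depend
on copious dissemination at moderate μ (e.g. the residual-tumor fraction
at μ = 50) are therefore biased high in this implementation, and the
corresponding acceptance check is expected to fail honestly.

Desk-scale runs add a finite-size artifact worth knowing about: in a small
periodic box the released cells re-collide with the tumor; since J_EH =
J_Hm here, sitting against the tumor is energetically neutral and the rim
(≈ 200 px at desk scale) can host the entire H population, so f̄_H decays
after its early peak.  At the full 200×200 / 517-cell scale the rim holds
only ≈ a third of the H cells and the effect is correspondingly weaker.

The synthetic sweep generator (`scaling.synthetic_sweep`) draws replicate
N̄ values from the scaling law N₀Γ^m/μ^n with 10% multiplicative Gaussian
noise, about the replicate scatter of the simulated sweeps.  It emulates
the magnitude and noise structure of sweep tables, not the correlations
induced by shared initial conditions or the threshold cutoff at low μ;
passing parameter recovery on it shows the fitting pipeline is unbiased
with calibrated uncertainties, not that the engine produces the law.

Problem sizes used by the default test suite and the acceptance script:
120×120 lattice, 120 cells, 10000 mcs, 2–3 replicates per condition —
the package's desk profile.  The full profile (200×200, 517 cells,
50000 mcs, 20 replicates per grid point) is available through the presets
and takes a few minutes per run on one core; a full figure-regime sweep is
an overnight job.
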