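# Methods

This note records the models implemented in `mdbind`, the conventions and
default parameters that matter for interpreting its output, what the
synthetic-data generators do and do not emulate, and the numerical choices
made where the design was genuinely open.

## Units and constants

Lengths are nanometres throughout the library; the PDB boundary converts
Å ↔ nm (coordinates are written with the format's three decimals in Å, so a
write→read round-trip is exact to 1e-4 nm).  Times are picoseconds,
temperatures Kelvin, energies kJ/mol, and
R = 8.314462618 J/(mol·K).  Frame and atom indices are 0-based internally;
residue identifiers keep their 1-based PDB values.

## Superposition and fluctuation profiles

Rigid-body fits use the Kabsch algorithm, mass-unweighted (the analyses are
Cα-based, where masses are equal), with the determinant correction that
restricts the search to proper rotations — a mirror image therefore retains
a positive residual RMSD.  Fits need at least three non-collinear atoms.
The batch code path performs one 3×3 SVD per frame, vectorised over frames,
so aligning 2×10⁴ frames is cheap.

RMSF is computed about an iteratively refined mean: frames are fitted to
frame 0, a mean structure is formed, and fitting to the running mean
repeats until the mean moves by less than 1e-6 nm (at most 10 rounds).
This fit-to-mean convention (rather than fit-to-first-frame, available via
a flag) is what makes the identity tr(C) = Σᵢ RMSF²ᵢ hold exactly between
the fluctuation and essential-dynamics modules; both modules share the same
alignment routine, and the covariance uses the population (1/F)
normalisation for the same reason.

Per-residue RMSD is measured on a designated atom per residue (Cα by
default) after global superposition of each frame onto a reference —
by default the simulation starting structure.  ΔRMSD is the elementwise
difference of two such *time-averaged* profiles aligned by residue label;
whether to difference time-averaged or final-frame values was an open
choice, and time-averaged was selected as the statistically stabler
quantity (the reference and averaging window are configurable).  Profiles
with mismatched labels raise an error naming the offending residues rather
than silently realigning.

Statistical errors on trajectory averages use block averaging: the series
splits into n contiguous equal blocks (three by default, matching the
protocol the package reproduces; any remainder frames at the end are
dropped so blocks stay equal-weight), and
SE = stdev(block means, ddof = 1)/√n.

## Essential dynamics

The covariance matrix of a selection's positional fluctuations is
diagonalised with a symmetric eigensolver; eigenvalues below 1e-12 nm² are
clamped to zero and the reported trace is the clamped eigenvalue sum (so a
constant trajectory reports exactly zero total fluctuation).  Spectra are
summarised by their first 20 eigenvalues by default.

Projections onto an eigenvector pair (the "essential plane" for ranks
1–2) first superpose each frame onto the model's mean structure over the
model's own selection; the variance of the projection then equals the
corresponding eigenvalue identically.

Basin extraction histograms the plane on a 50×50 grid over the data
bounding box padded by 5%.  Local maxima are located on a smoothed copy of
the histogram (Gaussian, σ = 2 cells) and must reach at least 5% of the
densest cell — both choices suppress Poisson noise in sparse tails, which
otherwise fragments a single diffuse basin into spurious maxima.  Accepted
maxima must be pairwise separated by a Chebyshev distance of ≥ 2 cells;
equal-density ties break towards lower (p1, p2) cell centres for
determinism.  Each basin's representative frame is the frame nearest (in
the plane) to its maximum's cell centre; frame populations are
nearest-basin fractions.  Asking for more basins than the data supports
returns what exists together with a warning rather than failing.  Grid
size, smoothing and the floor are analysis parameters, not physical
claims.

Cross-system comparisons build one covariance from the concatenated
trajectories and project each system separately; the overlap coefficient
Σ_cells min(f_i, f_j) of per-system normalised histograms on a shared grid
is 1 for identical clouds and 0 for disjoint supports.

## Interaction geometry

A hydrogen bond exists in a frame iff the donor–acceptor distance is at
most 0.35 nm and the H–D–A angle at most 30°.  The underlying study states
only that the analysis engine's default criterion was used; these are that
engine's widely known defaults, and both cutoffs are configurable.

Ring planes come from the smallest principal axis of the ring-atom scatter
(least-squares plane; sign-free normal) with unweighted centroids — ring
atoms have nearly equal masses.  For a ring pair, with u the unit vector
between centroids and n_A the first ring's normal:

* r = centroid distance (nm),
* φ = 90° − arccos(|u·n_A|) ∈ [0°, 90°] — the elevation of u over the
  *first* ring's plane, so perfectly facing rings give φ = 90° and coplanar
  side-by-side rings φ = 0°,
* Ψ = arccos(|n_A·n_B|) ∈ [0°, 90°] — 0° means parallel planes.

The first ring is pinned to the receptor ring (the His-imidazole in the
motivating application); swapping the rings preserves r and Ψ but changes
the reference plane for φ, which is why the convention is explicit.  The
original study depicts its "interaction formed" region only graphically;
the default box used here (r ≤ 0.55 nm, φ ≥ 60°, Ψ ≤ 30°) is a package
decision, configurable and always echoed in output metadata.

## Thermodynamics

TI integrates per-λ sample means with trapezoid weights on the given
(possibly non-uniform) grid — robust and assumption-free; composite
Simpson is available as a flag for uniform odd-length grids.  Each λ's
standard error comes from the three-block scheme above (block count
configurable) and the result's error is √(Σ w²ₖ SE²ₖ).  The soft-core
metadata carried on a profile (α = 1.51, σ = 0.3 nm, Δλ = 0.001) documents
the provenance of the samples; the package never evaluates that potential.

Relative binding free energies subtract a reference system's value with
errors added in quadrature; the reference entry reports 0 ± 0 by
convention.  The two-temperature decomposition is the finite difference
ΔΔS = −(ΔΔG(T₂) − ΔΔG(T₁))/(T₂ − T₁), ΔΔH = ΔΔG(T₁) + T₁·ΔΔS, with linear
error propagation; "entropy consistent with zero" means |ΔΔS| ≤ SE(ΔΔS).
Applied to the bundled 300 K/323 K table this holds for all three ligands —
the affinity differences are enthalpic.

The tautomer equilibrium treats each conformer's solution free energy as
gas-phase relative + hydration free energy, sums Boltzmann factors per
tautomer with log-sum-exp (overflow-safe), and reports K = Z_a/Z_b with
Δμ = −RT·ln K.  The bundled six-conformer table is taken as printed, with
no additional standard-state correction (its gas-phase values already use a
1 M, 300 K standard state).  Direct summation over that table gives
K ≈ 0.061 (Δμ ≈ 7.0 kJ/mol), whereas the source study reports K = 0.21
(≈ 4.2 kJ/mol) from the same inputs; the exact combination rule behind the
published number cannot be reconstructed from the text, so the package
documents both and does not tune toward either.  The linkage ratio
[complex_a]/[complex_b] = K·exp(−(ΔΔμ_a − ΔΔμ_b)/RT) is monotone in both
arguments; with the published K = 0.21 and the bundled 300 K ΔΔμ values it
reproduces the published bound-tautomer ratio of ≈3.5×10⁻⁴.

The Cheng–Prusoff conversion always computes the full form
Ki = IC50/(1 + S/Km); when the two assays share S and Km this reduces to
RT·ln(IC50_b/IC50_a), and differing conditions trigger a warning rather
than silent reduction.

## Synthetic data: what it emulates and what it does not

Every generator is a bit-reproducible function of one integer seed and
plants exactly the statistical or geometric structure its paired analysis
recovers:

* `gen_gaussian_traj` — Gaussian fluctuations with a planted low-rank
  covariance plus an isotropic noise floor.  Planted directions should be
  *internal* modes (`internal_mode_basis` provides random directions
  orthogonal to the six rigid-body modes of the mean structure): a
  rigid-body component would be absorbed by superposition, and no analysis
  can recover it.  Default study conditions used by the tests and the
  acceptance script: variances (0.5, 0.3) nm², noise 0.001 nm², 100
  pseudo-atoms, 20000 frames — sizes at which sample eigenvalues
  concentrate within a few per cent.
* `gen_two_state_loop` — two jittered centres separated by a planted
  displacement, returning ground-truth labels; with ‖d‖ = 0.5 nm against
  √jitter = 0.01 nm the essential-plane projection is decisively bimodal.
* `gen_ring_pair_series` — hexagon/pentagon templates (side 0.14 /
  0.137 nm, geometric conveniences) placed so the scheduled (r, φ, Ψ) are
  reproduced exactly by construction; generator and measurement form an
  inverse pair to ~1e-12.
* `gen_hbond_series` — an exact planted occupancy: round(occupancy·n)
  formed frames (0.28 nm, in-axis hydrogen) and broken frames violating the
  distance cutoff by ≥ 0.05 nm, seed-shuffled.
* `gen_ti_samples` — the harmonic λ-coupling k(λ) = (1−λ)k₁ + λk₂, for
  which ∂H/∂λ = ½(k₂−k₁)x² with x ~ N(0, RT/k(λ)) and
  ΔF = (RT/2)·ln(k₂/k₁) exactly.

These generators emulate the *statistical signatures* real trajectories
feed into each analysis — they contain no force field, solvent, thermostat
artefacts, time correlation (frames are i.i.d., so block errors are purely
sampling errors), anharmonicity, or coupling between the planted features.
Passing tests therefore certify that the analysis machinery is correct and
well-calibrated on data of known structure, not that any physical
simulation is accurate.

## Degenerate inputs and tie-breaks

Fewer than three or collinear fit atoms raise a degenerate-fit error;
collinear ring atoms a degenerate-plane error; coincident ring centroids
(r < 1e-6 nm) an undefined-geometry error naming the frame.  An exactly
identical mobile/reference pair short-circuits to the exact identity
rotation and zero RMSD.  Selections matching nothing are valid and empty;
a malformed selection expression is an error.  λ grids must strictly
increase and span [0, 1] with at least two samples per window.

## Problem sizes

The default test-suite and acceptance-script sizes (20000 × 100 atoms for
mode recovery, 10⁴ frames for basins, 21 × 5000 TI samples) were chosen as
the smallest sizes at which the stated tolerances (5% eigenvalues, 5°
eigenvectors, 3-SE TI recovery, ±0.03 occupancy) hold with comfortable
margin under the generators' statistics.
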