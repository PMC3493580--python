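# mdbind

Comparative molecular-dynamics analysis and binding-thermodynamics toolkit
for rationalising protein–ligand affinity — built around the analysis
protocol used for non-zinc-binding inhibitors of the matrix
metalloproteinase MMP-2, but generic over any receptor/ligand MD output in
multi-model PDB form.

## Who this is for

Computational chemists and structural bioinformaticians who have MD
trajectories of an apo enzyme, its ligand complexes and the free ligands,
plus alchemical ∂H/∂λ samples, and want to turn them into the standard
comparative observables:

* **Fluctuation profiling** — Cα RMSD time series, per-atom RMSF
  (fit-to-iterated-mean), per-residue RMSD against the starting structure,
  and the ΔRMSD metric
  `ΔRMSD_i = RMSD_i(complex) − RMSD_i(apo)` that localises binding-induced
  structural perturbation (0 ⇒ the ligand leaves the average structure
  untouched).
* **Essential dynamics (ED)** — covariance matrix
  `C = ⟨(x−⟨x⟩)(x−⟨x⟩)ᵀ⟩` of positional fluctuations on a selection,
  eigenvalues (mean-square fluctuations, nm²) and eigenvectors (collective
  motions in 3N-space), essential-plane projections, conformational-basin
  extraction with representative frames, and overlap coefficients between
  systems projected on a common plane.
* **Interaction geometry** — geometric hydrogen-bond occupancy
  (D–A ≤ 0.35 nm, H–D–A ≤ 30° by default) and the π-stacking descriptors
  (r, φ, Ψ): ring-centroid distance, elevation of the centroid–centroid
  vector over the reference ring plane (90° = face-to-face) and the
  inter-normal angle (0° = parallel).
* **Thermodynamics** — thermodynamic integration
  `ΔF = ∫₀¹ ⟨∂H/∂λ⟩ dλ` with three-block standard errors propagated
  through the quadrature weights; relative binding free energies ΔΔμ°
  against a reference ligand; two-temperature entropy/enthalpy
  decomposition `ΔΔS = −∂ΔΔG/∂T`; Cheng–Prusoff conversion
  `Ki = IC50/(1 + S/Km)`; a multi-conformer tautomer equilibrium
  `K = Z_a/Z_b` by Boltzmann summation; and the linkage relation
  `[complex_a]/[complex_b] = K · exp(−(ΔΔμ_a − ΔΔμ_b)/RT)`.

A first-class **synthetic-data module** generates trajectories and
λ-coupling samples with planted, analytically known structure (low-rank
Gaussian covariance, two-state loop motion with ground-truth labels, exact
ring-geometry schedules, exact H-bond occupancy, a harmonic λ-coupled model
with closed-form ΔF = (RT/2)·ln(k2/k1)), so every analysis stage has an
independent oracle.

## Worked example

```python
import numpy as np
from mdbind import (HarmonicTIModel, datasets, gen_ti_samples, integrate_ti,
                    tautomer_equilibrium, bound_tautomer_ratio)

# tautomer equilibrium from the bundled conformer table
eq = tautomer_equilibrium(datasets.conformer_energies(), temperature=300.0)
print(f"K = [1a]/[1b]      = {eq.K:.4f}  (Delta mu = {eq.delta_mu:.2f} kJ/mol)")

# linkage cycle with the published K and binding free energies
ddg = datasets.binding_free_energies()
ratio = bound_tautomer_ratio(0.21, ddg["1a"][300.0].value,
                             ddg["1b"][300.0].value, temperature=300.0)
print(f"bound ratio        = {ratio:.2e}")

# TI oracle: harmonic coupling with known closed-form answer
model = HarmonicTIModel(k1=1.0, k2=4.0, temperature=300.0)
profile = gen_ti_samples(model, np.linspace(0, 1, 21), 5000, seed=1)
res = integrate_ti(profile)
print(f"TI Delta F         = {res.value:.3f} +/- {res.standard_error:.3f} kJ/mol"
      f"  (exact {model.exact_delta_f:.3f})")
```

prints

```
K = [1a]/[1b]      = 0.0606  (Delta mu = 6.99 kJ/mol)
bound ratio        = 3.44e-04
TI Delta F         = 1.718 +/- 0.008 kJ/mol  (exact 1.729)
```

The first line is the free-solution tautomer equilibrium obtained by direct
Boltzmann summation over the six bundled conformer free energies: tautomer
1b is the more stable species in water.  The second line couples the
tautomer constant 0.21 with the 300 K relative binding free energies
(16 vs 0 kJ/mol) through the linkage cycle: fewer than one bound complex in
a thousand carries the 1a proton position, so 1b is the active form.  The
third line shows thermodynamic integration over 21 λ-windows of harmonic
∂H/∂λ samples recovering the analytic free-energy difference within its
propagated block error.

## Command line

A `mdbind` console script orchestrates the full protocol from one YAML
configuration (`mdbind run --config config.yaml --seed 1 --out out/`) with
subcommands `simulate`, `fluct`, `ed`, `hbond`, `stack`, `ti`, `tautomer`,
`linkage` and `report`.  Each run writes per-stage CSV/JSON artifacts plus
a `report.json` with provenance (config hash, version, seed); stage
failures are isolated and reported without aborting independent stages.

## Documentation

`docs/methods.md` describes the models, conventions, default parameters,
numerical choices and the limitations of the synthetic generators.
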