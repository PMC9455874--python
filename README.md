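# phagospread

Axisymmetric moving-boundary simulation of phagocytic cell spreading on a
flat, ligand-coated substrate. The cell is a highly viscous fluid body of
constant volume bounded by a cortex under biphasic tension; spreading is
driven by short-range substrate adhesion ("Brownian zipper"), by an active
protrusion stress concentrated at the contact line ("protrusive zipper"),
or by protrusion with discrete receptor–ligand binding sites.

Components:

- `geometry` — axisymmetric cell contour (apex → contact line → substrate),
  curvature via moving-window cubic fits, body-fitted quadrilateral meshing,
  contour smoothing, resampling and volume correction.
- `constitutive` — biphasic cortical tension law, Laplace cortical stress,
  the short-range adhesion stress integral (closed-form plane part minus a
  graded quadrature over the contact disc), the contact-area-dependent
  protrusion stress with exponential spatial profile and temporal decay,
  the membrane-fluctuation bond-formation threshold, per-bond energetics
  and the Young–Dupré equilibrium map.
- `stokes` — perturbed Stokes FEM (equal-order bilinear elements, the
  near-incompressibility perturbation ∇·(v − ε∇p) = 0 with ε ≤ h²/2μ as
  stabilization), solved by an alternating velocity/pressure (Uzawa-style)
  iteration with a relative pressure-change criterion of 1e-6, or
  monolithically by a sparse direct factorization (cross-check route).
- `evolution` — Courant-limited time stepping (≤10% of an element per
  step), forward-Euler boundary advection, continuum and discrete
  contact-line updates, the full per-step cycle.
- `driver` — run configuration (YAML), the simulation loop, ligand-density
  sweeps, discrete-site ensembles averaged over lattice shifts, and the
  Young–Dupré equilibrium check for plateaued passive runs.
- `analysis` — sigmoid fits (spreading speed = slope at the inflection,
  maximum contact area = plateau average), early-phase log–log power-law
  exponents, benchmark comparison tables.

Units: lengths μm, time s, stress Pa; tensions are quoted in mN/m
(1 mN/m = 1000 Pa·μm) and adhesion energy densities in μJ/m² (= 1 Pa·μm).

## CLI

```bash
# single run from a YAML config (fields of phagospread.driver.RunConfig)
phagospread run --config run.yaml --out outdir

# ligand-density sweep (relative fractions for continuum variants,
# absolute μm⁻² densities for the discrete variant)
phagospread sweep --config run.yaml --densities 0.01,0.1,1.0 --out sweepdir

# discrete-adhesion ensemble averaged over lattice shifts
phagospread ensemble --config run.yaml --shifts 5 --out ensdir

# post-process a contact-area time series
phagospread analyze --timeseries outdir/timeseries.csv
```

A minimal config:

```yaml
variant: protrusive_continuum   # brownian | protrusive_continuum | protrusive_discrete
rho_rel: 0.0                    # relative ligand density (continuum)
t_end: 200.0
n_free: 100
```

Outputs are plain-text CSV time series (t, Δt, A_c, A_cell, V, τ, σ_prot,
bond count, solver iterations, max speed), a final contour table and a JSON
metadata file.

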