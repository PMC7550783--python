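# Methods

## Model

Transdermal delivery is modeled as transient Fickian diffusion through a
stack of homogeneous material layers: the patch reservoir (a drug-in-matrix
slab), the stratum corneum, and the viable epidermis. Each material `i` has
a diffusion tensor `D_i` (longitudinal `D_z`, transverse `D_xy`) and a
dimensionless drug capacity `K_i` relating local concentration to the drug
potential `psi`:

```
c_i = K_i * psi
K_i dpsi/dt = div( D_i K_i grad psi )
```

The potential is continuous across interfaces while concentration jumps by
the equilibrium partition coefficient `K_A/B = K_A / K_B`; solving in `psi`
therefore handles partitioning without interface conditions. The patch
capacity is fixed at `K_pt = 1` by convention, anchoring the potential scale
(`psi_surface = c_ini` at the loaded patch concentration).

### Boundary and initial conditions

- Top of the stack: zero flux (backing layer), or a fixed potential
  `psi = c_ini` under the *infinite-reservoir* regime, in which the patch
  layer is replaced by a Dirichlet surrogate.
- Bottom of the viable epidermis: perfect sink, `psi = 0` (uptake by the
  dermal capillary bed; the blood is a perfect acceptor).
- Initially the patch holds `c_ini` uniformly and the skin is drug-free.
- *Removal*: at the removal time the patch layer and its remaining mass are
  taken out of the domain, the skin surface becomes zero-flux and the run
  continues on the skin-only stack with the carried-over field.

### Base-case parameters

| quantity | value |
|---|---|
| reservoir | 40 mm square (16 cm²), 50 µm thick, c_ini = 80 kg m⁻³ (6.4 mg) |
| patch | D = 1e-13 m² s⁻¹, K = 1 |
| stratum corneum | 15 µm; D_z = 7.2e-15, D_xy = 1.05e-12 m² s⁻¹; K = 0.14 |
| viable epidermis | 70 µm; D = 2e-11 m² s⁻¹ (isotropic); K = 8.4e-4 |
| horizon / output cadence | 240 h / ≤600 s |

Site-specific sublayer thicknesses (mean ± sd, µm): dorsal forearm
18.3±4.9 / 56.6±11.5; shoulder 11.0±2.2 / 70.3±13.6; buttock 14.9±3.4 /
81.5±15.7; all-sites 14.8±4.8 / 69.9±17.0. Age enters through the
dorsal-forearm correlation `d_sc = (0.125*age + 11.8) µm`, calibrated for
ages 18–70.

The drug molecule itself (molecular weight, logKow) is informational: all
transport physics is carried by the per-layer `D` and `K`.

## Numerics

### 1D solver

Conservative cell-centered finite volumes. Interior face conductances use
the harmonic (series) combination of half-cell resistances,
`G = 1 / (h₁/(2 D₁K₁) + h₂/(2 D₂K₂))`, which is exact for steady
piecewise-constant-property diffusion and makes the discrete steady flux
match the series-resistance closed form to machine precision. Dirichlet
faces use the half-cell conductance `2DK/h`.

Meshes are geometrically graded toward every layer interface (default 40
cells per layer, ratio 1.2). Refinement level `l` doubles the cell count
and softens the grading ratio to `r^(1/2^l)` so that the *largest* interior
cell also shrinks; with a fixed ratio the interior cell size plateaus and
the discretization converges to a mesh-family limit rather than the
continuum (observed as a persistent ~0.2% flux bias before this was
corrected). Richardson extrapolation over levels (0, 1, 2) gives an
observed order ≈2 and a discretization error of the default mesh below
0.1% for the 72 h uptake.

Time integration: the semi-discrete system `M dpsi/dt = A psi + b` is stiff
(cell time scales span ~9 orders of magnitude on graded meshes) and is
integrated with BDF (`scipy.integrate.solve_ivp`, rtol 1e-9, constant
sparse Jacobian). Cumulative release and uptake are carried as two extra
quadrature states, so the mass ledger closes to integrator tolerance
(residuals ~1e-12, audited at every output time). The solver aborts if the
potential undershoots below −1e-8 of the potential scale; smaller
undershoot is clipped to zero.

Verification (always-on tests): dense matrix-exponential oracle on ≤40-cell
meshes (1e-8), single-slab analytic transient (0.1%), interface
concentration-jump convergence to `K_A/B`, steady solve vs closed form
(1e-10), mass-balance audit (≤1e-6), removal bookkeeping conservation.

### Multi-dimensional solver

Quarter-symmetric tensor-product grid (x, y lateral; z vertical) for a
square reservoir footprint on a laterally extended skin block (margin: 20
skin thicknesses, or 1.7 mm for the miniaturization study). 7-point finite
volumes with harmonic face conductances; footprint Dirichlet for the steady
infinite regime; sparse direct solves.

The anisotropic stratum corneum (D_xy/D_z ≈ 146) develops a contact
boundary layer at the footprint edge whose vertical scale is the lateral
scale times `sqrt(D_z/D_xy)` ≈ 1/12. The grid therefore grades the top
cells by that factor; without it the edge-flux enhancement is
underestimated by about 2× at 40 µm. The mesh-convergence log in the sweep
records the flux at successive refinement levels (≤1.3% change between the
last two at the smallest sizes).

Finite (depletable) micro-reservoirs are meshed explicitly above the
footprint and integrated with implicit Euler on a geometric time grid
(1 s × 1.2 per step, capped at 600 s), refactorizing the operator only when
the step size changes. Cells cut away when restricting the patch to the
footprint have their face conductances returned to the diagonal so the cut
faces are zero-flux walls (mass-conservation test enforces this).

### Sensitivity

Central differences with 1% relative perturbations:
`S = |(U(X(1+δ)) − U(X(1−δ))) / (2δ) / U_nominal(t)|`. Geometry parameters
re-mesh the perturbed domain. The scan reproduces the exact series-
resistance elasticities in the steady limit and S = 1 for the initial
concentration (the problem is linear in `c_ini`).

## Limitations

- The dermis is not modeled; uptake is a perfect sink at the base of the
  viable epidermis, so systemic pharmacokinetics (plasma levels, clearance)
  are out of scope.
- Layer properties are homogenized; appendages (follicles, glands),
  hydration state and metabolism in the viable epidermis are not
  represented.
- Partitioning is linear (constant K), valid below solubility limits; no
  binding saturation.
- The contact between patch and skin is ideal (no contact resistance,
  no delamination).
- Body-site and age variability enter only through layer thicknesses, not
  through site-dependent transport properties.
- The age correlation for stratum-corneum thickness is calibrated for ages
  18–70; evaluation outside that range warns.
- The 3D enhancement factors for micro-reservoirs are sensitive to how well
  the edge singularity is resolved; values reported here are from the
  documented mesh-convergence sequence of this solver.
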