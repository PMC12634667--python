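# Methods

`pillarmps` models the four physical stages of a pillar-array interfacial
barrier in a microphysiological system (MPS): the capillary burst valve the
barrier forms during cell loading, advection-diffusion solute transport from
the media channels into the cell chamber, steady oxygen metabolism of the
resident cardiac microtissue, and the finite-size scaling of tissue oxygen
consumption with tissue mass.  This note records the models, their
assumptions, the numerical choices, and the limits of what the synthetic
ensembles and reduced solvers can show.

## Device geometry

The barrier is a line of cylindrical pillars (default: 8 pillars in a
708 µm line, pore size 8 µm between pillar surfaces, giving a 79.5 µm
diameter under the end-gap convention of n+1 gaps).  Porosity is the
plan-view void fraction of the rectangular barrier region — with the
default region (125 × 708 µm) it is 0.551 at 8 µm pores and 0.466 at 2 µm
pores; porous volume is porosity × region area × pillar height, exactly
linear in height.  The end-gap convention is used because the pillars must
be separated from the chamber walls for the array to act as a barrier
rather than a wall.  A pore of width w and height h is compared to a
membrane pore through the hydraulic diameter D_h = 2hw/(h+w); the reference
configuration (8 × 2 µm) has D_h = 3.2 µm.

## Capillary burst valve

During loading, medium is pushed from the cell chamber against the barrier;
the air–water meniscus pins in the fenestra and bursts above a critical
pressure Δp_b ∝ γ_lv/D_h (reported nondimensionally as
p* = Δp_b·D_h/γ_lv).

**Model.** A 2D depth-averaged (Hele-Shaw) level-set reduction on the plan
view.  The interface is the zero contour of a signed-distance field
(positive in liquid) advected with normal speed proportional to the local
capillary disequilibrium,

    v_n = M [ p_applied − γ κ_in-plane + 2 γ cos(θ_c)/h(x) ],

where κ is the resolved in-plane curvature (positive on convex liquid
bulges), h(x) the local region depth (20 µm inlet chamber, 2 µm fenestra,
150 µm outlet) whose Young–Laplace term is a wicking suction for the
hydrophilic walls (θ_c = 66°), and M an arbitrary mobility: the scheme is a
relaxation toward quasi-static equilibria, so the pinned/burst outcome is
independent of M and of the pseudo-time scale.  The depth term that gates
the advance across a depth step is taken from the *invaded* (air) side,
which is the capillary entry condition of the region being entered.
Numerics: Godunov upwinding for the pressure/suction part, central
differencing for the (parabolic) curvature part, curvature computed on the
raw signed distance (pre-smoothing biases the pinned-bulge curvature
grid-dependently) and clamped to 0.6/dx, PDE reinitialisation every 10
steps, narrow-band update with the level set clamped to ±5 dx.  Burst =
front well clear of the fenestra mouth; pinned = front stationary to 1% of
the fenestra length over the trailing 20% of the step budget.  Burst
pressure by bisection (default tolerance 2% of the initial bracket
[0, 4γ/D_h]).

**In-plane wall condition.** The contact angle is applied through the
out-of-plane term only; in-plane the walls are neutral (90° ghost
extension).  Imposing θ_c in-plane through the ghost extension makes the
discrete contact line creep without bound around convex corners (grid
corners are rounded at the cell scale), destroying the Gibbs pinning at the
fenestra exit that sets the burst pressure, so the neutral treatment is the
documented reduction.  Its quasi-static consequence for a straight fenestra
of width w: ideal corner pinning sustains an in-plane curvature of up to
2/w (semicircle); the first-order discrete corner lets go somewhat earlier,
at κ ≈ 1.1/w, stably across grid halvings (the bisected burst pressure
changes by less than the 5% bisection tolerance between 1 µm and 0.5 µm
grids) and inside the analytic bracket [γ/w − suction, 2γ/w].  The
simulator gives p* ≈ 0.41 for the 8 × 2 µm straight fenestra (0.44 on the
shortened test domain).

**Known limitation (important).** The published values for this device
(p* ≈ 0.18 straight, ≈ 0.27 pillar, ratio 1.5, from a 3D two-phase finite
element model) are *not* reproduced by this reduction, and a sharp-interface
quasi-static analysis shows they cannot be: with θ_c = 66° both fenestrae
imbibe spontaneously and the valve is set by in-plane exit pinning, which
gives p* ≈ 0.7 for the straight mouth; and a smooth cylinder pair with the
same 8 µm throat is a strictly *weaker* in-plane valve than a
sharp-cornered mouth of equal width (the pinning curvature between two
cylinders of radius R and gap w is 1/√(Rw + w²/4) < 2/w), so the 2D model
orders the two fenestrae opposite to the 3D result (pillar/straight ≈ 0.08:
the pillar cell bursts at its wide 87.5 µm slot mouth, the straight
fenestra at its narrow 8 µm mouth).
The pillar fenestra is modelled as one periodic cell of the device layout
(pitch 87.5 µm, two half-cylinders on the symmetry walls, throat at
mid-fenestra).  The out-of-plane meniscus dynamics that the reduction
averages away are evidently decisive for the absolute threshold and the
ordering; results from this module should be read as the 2D quasi-static
answer, with sensitivity to the in-plane wall treatment documented above,
not as a replication of the 3D values.

## Barrier transport

**Flow.** Depth-averaged Stokes–Brinkman on a staggered (MAC) grid:

    μ ∇²_plane u − (12 μ / h²) u − ∇p = 0,      ∇·(h u) = 0,

with the local depth h(x,y) = 150 µm in channels and chamber, the
fenestration height (2–10 µm) in the barrier strips, 0 in pillars and
walls.  The Brinkman drag is the top/bottom Poiseuille friction of the
local depth; the resolved in-plane viscous term carries the side-wall drag
of the 100 µm-wide channels (aspect ratio ≈ 1, where a pure Hele-Shaw
conductance model underestimates the channel pressure drop severely) and of
the pores.  Both media channels are perfused at the stated flow rate
(uniform depth-averaged inlet velocity; zero reference pressure at the
outlets; chamber and barrier strips walled at the device ends).  The linear
system spans ~13 decades, so it is solved by direct factorisation after
row/column equilibration with three steps of iterative refinement.  On a
2 µm grid this gives chamber volume-averaged speeds of 0.47 µm/s (pillar
barrier, 8 µm pores) and 1.8 µm/s (no-pillar 2 µm slot) at 4800 µL/h,
against reported 3D values of 0.476 and 3.45 µm/s: the pillar case agrees
closely, the open-slot case within the expected factor-two of the
reduction, and the no-pillar/pillar ratio (≈ 3.8 vs 7.25) inherits the slot
discrepancy.

**Solute.** Transient advection–diffusion of albumin
(D = 9.3×10⁻⁷ cm²/s, inlet concentration c₀ = 7.46 nM) on the same grid:
backward-Euler in time with the operator factorised once (default step
0.05 h), first-order upwind advection on the steady face fluxes, advective
outflow at the outlets, no-flux at solids.  The chamber-averaged transient
yields the equilibration time (first crossing of 0.95 c₀, linearly
interpolated; the threshold is configurable since "equilibration" has no
published definition) and the permeability at half saturation,
P = V_ch (dc/dt)|_{0.5c₀} / (A_b · 0.5 c₀).  On a 2 µm grid the
equilibration times at 20 µL/h span ≈ 3–48 h across fenestration heights
10–2 µm, matching the reported 12–48 h window at the bottom end.

**Permeability reference area.** A_b defaults to the chamber-side interface
area (both sides, device length × chamber height), the vessel-wall
convention under which the computed values (≈ 2×10⁻⁷ cm/s for the 2 µm
barrier) are of the same order as in-vivo endothelial references; the
open-pore convention (fenestration height × open pore length) is available
as a config option and gives values ~250× larger.  The convention is
recorded in the run metadata.

**Peclet number.** Pe = v̄L/D with L defaulting to the chamber width
(300 µm).  The published Pe/velocity pairs back-solve to L ≈ 273 µm; since
L is not stated there, it is an explicit config parameter and only Pe
*ratios* are treated as comparable.

## Oxygen metabolism

Steady reaction–diffusion in a box microtissue with Michaelis–Menten
uptake:

    0 = ∇·(D ∇c) − sOCR·ρ_c·c/(k_m + c),

with side walls at 0.21 mol/m³ (medium-facing), a no-flux glass bottom, and
a Robin PDMS top (inward flux k_pdms(c_amb − c); default
k_pdms = D_PDMS/t_PDMS with D_PDMS = 3.4×10⁻⁹ m²/s through 2 mm,
c_amb = 0.21 mol/m³ — the published model cites a PDMS flux term without
parameters, so this slab-conductance default is our choice and is exposed
in config).  Parameters: k_m = 6.9×10⁻³ mol/m³, cell density
ρ_c = 1.95×10¹⁴ m⁻³, single-cell OCR (sOCR) mean 4.67×10⁻¹⁷ mol/s.  The
tissue oxygen diffusivity is not published for this system; the default is
2×10⁻⁹ m²/s (a typical cardiac-tissue value) and viability conclusions are
swept over [1–3]×10⁻⁹ m²/s.  Geometries: V1 = 243.8×621.6×62.35 µm,
V2 = V1 with doubled height, V3 = 288×950×124.7 µm (the published volumes
0.8/1.6/3.1×10⁷ µm³ are slightly below the box products, implying non-box
features; the boxes are used).

Discretisation: cell-centered finite differences; damped Picard (0.7) on
the linearised uptake with a Newton fallback, converged to a relative
nonlinear residual of 10⁻⁸.  Tissue OCR B is the surface integral of inward
flux computed with the discrete boundary fluxes of the same stencil, so the
discrete divergence theorem makes it equal the volume-integrated
consumption to the nonlinear tolerance.  B changes by <1% between 16×40×10
and 32×80×20 grids on V1.

## Population of models and scaling collapse

Biological variability enters through sOCR, drawn lognormal with the
measured mean and cv 0.69 (the measurement is a histogram, not a named
family; lognormality is chosen for positivity and right skew, and empirical
resampling is supported).  The same draws are reused across geometries
(common random numbers), each geometry re-solved once per draw; solves
warm-start from the neighbouring draw and use a frozen factorised
mean-uptake operator as a quasi-Newton preconditioner.  Population size
defaults to 10,000 as in the study, with 1,000–3,000 used in tests and in
the reproduction script (problem sizes chosen to keep a full run on one
core in minutes); the scaling exponent moves by <0.01 between N = 300 and
N = 1500 at fixed seed.

The distributions p(B) for V1–V3 are collapsed under the scaling ansatz
p(B | ⟨m⟩, β) = B^(−β) F(B/⟨m⟩^δ) with β = 1 fixed; mass m defaults to
ρ_c × volume (the exponent is invariant to a common factor on m, asserted
in a test).  Curves are rescaled (x = B/⟨m⟩^δ, y = p(B)·B^β), compared in
log–log with linear interpolation onto each curve's abscissae, and the
summed pairwise mean absolute difference over the overlap (the
probability-contiguity distance) is minimised by differential evolution
over δ ∈ [0.3, 1.5] with a fixed seed; a dense grid scan cross-checks the
optimiser in the tests, and generative ensembles (B = m^δ₀·X) with
δ₀ ∈ {0.6, 0.75, 1.0} are recovered within ±0.05.

**Known limitation (important).** With the published boxes and boundary
conditions, the horizontal diffusion half-widths of V1–V3 are nearly equal
(122 → 144 µm), so B is almost proportional to volume and the collapse
returns δ ≈ 0.996–0.999 across the whole diffusivity band — not the
published sub-isometric α = 0.8825.  The collapse machinery itself is
validated by exact synthetic recovery; the gap is in the physical inputs
the publication does not fully specify (tissue diffusivity, PDMS flux
parameterisation), on which near-isometry vs allometry hinges.  The
pipeline reports what the stated parameters produce.

## Synthetic data

The generators are the test bed for every stage.  Tissue-morphometry
ensembles draw volume (mean 1.91×10⁷ µm³, cv 0.33) and cell density (mean
1.95×10¹⁴ m⁻³, cv 0.26) lognormally and derive the cell count as
density×volume (mean ≈ 3720, consistent with the observed 3685 within 2%);
per-axis shape factors with the observed per-axis cvs (0.05, 0.28, 0.95)
are rescaled isotropically to the drawn volume, because independent
per-axis draws would imply a volume cv near 1, inconsistent with the
observed 0.33 (the real axes are correlated).  Chamber-filling traces are
exponential with known rate, so permeability and equilibration time have
closed forms the estimators must match exactly.  Scaling ensembles obey
B = m^δ₀·X exactly.  All generators are deterministic under a seed.  What
passing these tests shows is that the estimators are correct on data obeying
the model assumptions; they do not probe deviations real tissues exhibit
(correlated axis growth, non-lognormal metabolic tails, active transport).

## Degenerate inputs and error behaviour

Zero flow gives identically zero velocity; zero surface tension bursts at
any positive pressure; zero consumption gives the uniform boundary field
and zero OCR; cv = 0 collapses all draws to the mean; identical
distributions make the collapse objective flat and the result is flagged
degenerate rather than returned silently; traces that never cross the
threshold raise a not-reached error; infeasible layouts, invalid brackets
and non-converged solves raise with diagnostics rather than returning
values.
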