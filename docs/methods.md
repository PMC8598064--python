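# Methods

## Model

`tissuemix` simulates a sample of soft tissue as a saturated mixture of
`n + 2` continuum components: interstitial fluid (index 0), one or more cell
subpopulations, and the extracellular matrix (ECM, last index). Each
component is described by its volume fraction `u_i(x, t)` and obeys the
mass balance

    ∂u_i/∂t + ∇·(u_i v_i) = g_i ,

with two global constraints: no voids, `Σ_i u_i = 1`, and no net volume
production, `Σ_i g_i = 0` (everything is made from something already in the
mixture). Inertia and body forces are negligible at tissue scales, so each
component also satisfies a quasi-static momentum balance in which the only
forces are a common interphase pressure `p`, a component-specific isotropic
*excess pressure* `Ψ_i`, and pairwise Stokes-type drag
`α̂_ij u_i u_j (v_j − v_i)`.

The constitutive choice for the excess pressure is deliberately minimal:

    Ψ_i = k_i (u0_opt − u0)+ ,     Ψ_0 = 0.

Tissue is "under stress" exactly where the interstitial-fluid fraction has
been squeezed below its optimum `u0_opt`; the strain-stress coefficient
`k_i` (kg·mm²/day²) sets how strongly component `i` responds. The `(·)+`
operator is `max(·, 0)` with one-sided derivative 0 at the kink.

Summing the momentum balances eliminates `∇p = −∇Σ_j u_j Ψ_j`; substituting
the zero-net-flux solution `u_0 v_0 = −Σ_{j≥1} u_j v_j` of the
incompressibility condition then closes the system. The crucial numerical
device is to solve for the **advective fluxes** `q_i = u_i v_i` rather than
the velocities: the resulting local linear systems

    A q = r,   A_ii = α̂_i0 u_i + Σ_{j≠i} α̂_ij u_j,
               A_ij = u_i (α̂_i0 − α̂_ij),
               r_i  = u_i ∇(Σ_j u_j Ψ_j) − ∇(u_i Ψ_i)

remain nonsingular where a component's fraction vanishes. Because the
`Ψ_i` are velocity-independent, the system couples components only
pointwise, so it is solved face-by-face (one spatial direction at a time)
as batched dense solves of size `n + 1`; the fluid flux is recovered as
`q_0 = −Σ q_j`, making the net flux zero at every face identically. With
equal drags and `Σ u = 1` the matrix reduces to `α̂·I`, and in the
two-phase case `q_1 = −u_0 ∇(u_1 Ψ_1)/α̂` — components drain *down* the
excess-pressure gradient, which is what fills wounds and pushes a growing
tumor's surroundings outward. (A restatement of the momentum balance
elsewhere in the source literature carries the opposite sign; that sign
would drive components *into* compressed regions, so the derivation's sign
is used. It is switchable via `Numerics.rhs_sign` for sensitivity runs.)

### Rate laws

Net production rates close the mass balances; `g_0 = −Σ_{i≥1} g_i` always.

* **Regeneration** (fluid, cells, ECM): cells divide at
  `b1 = b1_max · u0 · ‖∇(u0 − u0_opt)+‖₂` — the Euclidean norm of the
  gradient of the excess-fluid deviation, non-zero only at tissue
  irregularities such as a wound rim. The ECM is secreted by cells when
  below optimum: `b2 = b2_max · u0 · u1 · (u2_opt − u2)+`. The *norm* (not
  its square) is used: the worst case of `b1` is then
  `b1_max (1 − u0_opt)/h`, the form that appears in the time-step stability
  bound, and the simulated healing then matches the ~20-step figures of the
  source study; the squared form heals an order of magnitude faster and
  reverses the stiffness ordering.
* **Oxygen-coupled healing** (fluid, live, dead, ECM): growth is gated by
  `(1 + tanh(R2(o − T2)))/2` and death by
  `d̂1(u0_opt − u0)+/u0_opt + d̃1(1 − tanh(R1(o − T1)))/2`, with hypoxic
  thresholds `T1 = 2`, `T2 = 10` mmHg. Dying cells enter a dead pool that
  disintegrates into fluid at rate `d2`.
* **Tumor/ECM** (fluid, normal, tumor, ECM): normal cells starve
  (`−d̂1 u1 (u0_opt − u0)+`), tumor cells proliferate with available fluid
  (`(b̂2 u0 − d̂2 (u0_opt − u0)+) u2`), and the ECM is rebuilt by normal
  cells toward a target `(1 + α u2) u3_opt` that the presence of tumor
  inflates — the *active response*, in addition to the *passive* mechanical
  response through `k_3`.

### Chemicals

Chemical transport is much faster than cell motion, so oxygen is relaxed to
steady state at every mechanical stage:

    −D̂ u0^δ Δo + ∇o·(u0 v0 − D̂ ∇u0^δ) + o g0 + o u0 Σ_j c_j u_j = r ,

with Dirichlet values `ō` on the boundary ring and `õ` on a set of
capillary cells (per-source randomized values are supported and
seed-controlled). Consumption by live cells is `c1 = ℓ1 + ℓ2 b1` — a base
metabolic rate plus the extra cost of division. Since `g0` and `b1` depend
on `o` through the tanh responses, the problem is nonlinear; it is solved
by damped Newton iteration with an analytic sparse Jacobian for the
transport part and a per-cell finite-difference derivative of the (purely
local) reaction part. The advection term is centered where the cell Péclet
number `|w|h/2D ≤ 1` and first-order upwind beyond, which preserves
second-order behavior on smooth problems (verified by the residual-order
test) while keeping the scheme monotone where the diffusivity collapses.

**Diffusivity exponent.** The source material states `δ > 1` but tabulates
`δ = 0.5`. These cannot both hold, and the choice is observable: with
`δ = 0.5` and the tabulated diffusion scale and consumption rates, the
steady-state oxygen floor on the 0.3 mm domain is 19.2 mmHg *with no
capillaries at all* (the boundary ring dominates), so no hypoxic region
(PO2 < 10 mmHg) can ever form and capillary damage has no physiological
effect. The vascular examples therefore default to `δ = 2`, the simplest
exponent satisfying `δ > 1`, under which an intact capillary map keeps the
tissue well oxygenated while clearing the capillaries near the wound
produces a genuine hypoxic region and measurably slower healing. Any
`δ > 0` (including 0.5) is accepted in configuration.

## Discretization

Space is a uniform cell-centered grid of spacing `h` (mm) with half-index
face locations: scalars (`u_i`, `o`, `Ψ_i`, `g_i`) live at cell centers,
fluxes and gradients at faces, and the divergence maps conservatively back
to centers, so `div∘grad` is the 5-point Laplacian and the discrete
divergence theorem holds to round-off. Boundary faces carry zero flux: the
sample is sealed, and with `g ≡ 0` every component's total mass is
conserved to ~1e-15 per step.

Time stepping is the Heun (trapezoidal) two-stage Runge-Kutta: fluxes,
chemical steady states and rates are evaluated at the current state and at
the Euler-predicted state, and their tendencies averaged. Only the
structural components are integrated; the fluid fraction is recovered from
the no-voids condition after every stage, so `Σ u_i = 1` holds exactly. A
limiter then clamps negative fractions to zero and caps the total
non-fluid fraction at `β` (proportional rescale), guaranteeing a minimal
fluid fraction `1 − β` everywhere; the clamped mass is logged per step.
`β` caps how densely packed tissue may become (0.90–0.98 in the shipped
configurations; the precise role of this parameter in the source is
under-documented, and the cap-on-packing reading is this package's design
choice).

The worst-case stability bound

    Δt ≤ 1 / ( b_cell(1 − u0_opt)/h + b_ecm·u_ecm_opt + 4A(Σk_i)u0_opt/h² )

is evaluated at startup under both readings of the drag factor `A`
(literal `α̂`, and `1/α̂`, the default — fluxes scale as `k/α̂`). With
tabulated parameter values neither reading admits the Δt the source study
states it used, so the runner warns rather than aborts; in practice the
Heun corrector plus limiter is stable at the shipped Δt for every packaged
scenario, which is itself evidence the printed bound is very conservative
(it is a worst-case over states never reached).

## Scenarios and generated geometry

The wound of the regeneration examples and the capillary maps are not
published; both are generated by seeded routines and accept user-supplied
index lists instead. The wound is a random-walk blob covering 10% of the
domain (irregular and connected, like the published picture); capillaries
are 20 cells placed uniformly in the interior, and the "damaged
vasculature" variant removes those within 8 cells of the wound centroid.
The tumor seed defaults to a single central cell at fraction 0.7; because
the source leaves the footprint open, 1–3-cell footprints are swept where
end-state ECM maxima are compared (the passive-run maximum moves from
0.094 at one cell to 0.111 at three — the single number most sensitive to
this choice).

The heterogeneous-ECM variant initializes
`u3 = (ζ/40)(sin 100x + sin 100y) + 0.1 + r(x, y)` with `r` uniform on
±0.0012 and pins the optimal fluid/ECM fields to the initial state, so the
"normal" architecture is itself heterogeneous.

## Calibration

The tumor sub-model (all non-tumor kinetics off; `h = 0.01`, `Δt = 0.25`,
80 steps, `β = 0.9`) is fitted to time/volume growth data by minimizing
`S = Σ_i (v_i − M(t_i))²`, where `M(t)` is the simulated total tumor volume
fraction normalized to 1 at `t = 0` and day `t` maps to step `t/Δt`. Free
parameters are `(b̂2, d̂2, k2)`, bounded below by 0, optimized by
trust-region reflective least squares from a deterministic 3×3×3
multi-start grid; the best start of each `k2` stratum is polished, because
the objective is flattest along the stress coefficient and screening alone
collapses onto a single basin. Two clinically derived, rescaled data sets
(9 and 11 points, day 0–19) ship with the package.

The objective carries a near-degenerate ridge across `(b̂2, d̂2, k2)`:
distinct parameter triples reproduce the data to ~1% RMS. Goodness of fit
(R² ≈ 0.994–0.997) and holdout prediction errors (2–7% on the final point)
are therefore the meaningful outputs; point estimates of individual
parameters are not identifiable from nine points and should be read as one
representative of the ridge. The noiseless-recovery test (fit to a curve
the model itself generated) recovers the generating parameters to machine
precision, confirming the optimizer finds the global basin when one exists.

## What the generated data do and do not show

All inputs are generated: wounds, capillary maps, the heterogeneous ECM
field, and the synthetic calibration curves. Passing tests therefore
demonstrate internal consistency (conservation, closure, oracle
equivalence, order of accuracy) and reproduction of the study's qualitative
orderings and summary statistics — not agreement with any real tissue. The
model has no chemotaxis/haptotaxis, no viscous stresses, no vascular
remodeling, 2-D geometry only, and parameter values chosen for qualitative
plausibility rather than measured for a specific tissue.

## Numerical choices and degenerate inputs

* Flux systems at faces where every structural fraction vanishes are
  replaced by `εI` (q = 0 there); regular faces are solved exactly.
* Newton tolerance is `1e-9·max(ō, õ)`, floored at the round-off level of
  the transport operator (`~1e-14·|J|·ō`); non-convergence after 50
  damped iterations is an error carrying the residual norm.
* `‖∇f‖²` at a cell averages the squared face gradients over the cell's
  two faces per direction, keeping all rate laws symmetric under the grid's
  dihedral group (a centered tumor stays 8-fold symmetric to 1e-10 over
  hundreds of steps).
* Chemical fields are re-solved at both Heun stages by default
  (`Numerics.chem_every_stage = False` gives the cheaper lagged mode).
* Problem sizes: grids up to 41×41 and 500 steps per run; a full
  encapsulation run takes ~2 s and a calibration fit 1–3 min on one core.
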