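# Methods

## Model

`bioheatfd` simulates heat transfer in a small cuboidal patch of the human
forehead — scalp, skull and cerebrospinal fluid (CSF) in series — while a
cool wet cloth rests on the skin (tepid sponging during fever). Living
tissue is modelled with the Pennes bioheat equation,

    ρc ∂T/∂t = k ∇²T + m_b c_b (T_A − T) + Q_m + Q_e ,

where `k, ρ, c` are the layer's conductivity, density and specific heat,
`m_b c_b (T_A − T)` is the blood-perfusion exchange with arterial blood at
temperature `T_A` (during fever, the fever temperature), `Q_m` is metabolic
heat and `Q_e` an optional external volumetric source. The cloth acts
through the surface boundary condition; `Q_e` defaults to zero.

Boundary conditions on the box:

* **skin surface (x = 0)** — Robin exchange with the cloth,
  `k ∂T/∂x = h_e (T − T_w)`, or a hard clamp `T = T_w`;
* **deep face (x = L)** — arterial clamp `T = T_A` (default) or zero flux;
* **four lateral faces** — zero flux (the patch is treated as the centre of
  a wider sponged area).

All temperatures are °C; every term involves only differences, so the
Celsius/Kelvin offset never enters.

An immediate consequence worth stating: with depth-only layering,
depth-only sources and zero-flux lateral faces, the exact solution is
*independent of the lateral coordinates*. The 3D solver reproduces this
(it is one of the symmetry tests), and it is the main reason the published
reference tables — which show strong lateral variation — cannot be
reproduced by a consistent discretization of this model; see
"Reference-table comparisons" below.

## Discretization

Uniform lattice of spacing `h` (default 2 mm), depth index `i = 0..nx`,
centred lateral indices `j, k`. The steady equation becomes the 7-point
stencil

    ΣT_neighbours − (6 + a_n) T_n = −b_n ,
    a_n = h² m_b c_b / k_n ,   b_n = (h²/k_n)(m_b c_b T_A + Q_m,n + Q_e) ,

with per-node layer constants (a node's layer is decided by its depth,
half-open intervals, ties to the deeper layer; no conductivity averaging at
interfaces — an deliberate match to the whole-node per-subdomain
coefficients of the reference computation). The matrix is strictly
diagonally dominant whenever perfusion is active, so the direct sparse
factorization cannot fail; an iterative option (BiCGStab, rtol 1e-12)
exists for refined grids. The solve post-condition is
`‖MT − N‖∞ ≤ 1e-10 ‖N‖∞`.

**Robin surface.** Ghost-node elimination at second order:
`k (T₁ − T_ghost)/(2h) = h_e (T₀ − T_w)` keeps surface nodes as unknowns.
A first-order one-sided variant (`robin_order: 1`) exists for sensitivity
checks; the convergence harness shows order ≈ 2 vs ≈ 1 respectively.

**Lateral zero flux.** Two treatments:

* `copy_face` (default): lateral face slices are dependent copies of the
  adjacent inner slice, i.e. the mirror plane sits half a cell inside the
  face. This reproduces the compact reference system exactly — 27 interior
  unknowns on the default grid when the surface is clamped (36 with the
  Robin surface patch).
* `ghost_mirror`: face nodes remain unknowns and zero flux is imposed with
  second-order mirror ghosts on the face itself (100/75 unknowns on the
  default grid).

For every laterally-uniform scenario (all shipped presets, all slab
verifications) the two produce identical fields; they differ only for
hypothetical laterally non-uniform sources.

## Time stepping

The transient march is the consistent forward-time centred-space (FTCS)
update, implemented as `T ← T + dt · s · (M T − N)` with
`s = k/(ρ c h²)` per node and `M T = N` the steady system. Reusing the
steady operator makes the steady solution an exact fixed point of the
march, so the long-time transient equals the steady solve by construction
up to the convergence of the march itself.

**Stability.** Every update weight stays non-negative only for
`dt ≤ ρc h²/(k |M_nn|)`; interior rows give the familiar per-layer bound
`ρc h²/(6k + h² m_b c_b)`. At `h = 2 mm` with the shipped constants the
binding layer is the skull: 2.4749 s (scalp 7.5084 s, CSF 6.3799 s). A
Robin surface adds `2h·h_e/k` to its own rows and is included in the
returned bound. Steps above the bound raise `StabilityError` — there is no
silent damping. `run_transient` substeps internally at
`safety_factor × limit` (default 0.9) and hits every output/reset time
exactly with a shortened final substep. The reading interval of 2 minutes
is an *output* cadence; it exceeds the explicit limit by ~50× and is never
used as an integration step. An unconditionally stable backward-Euler
stepper (`method="backward_euler"`) is provided to probe what large steps
would produce.

**Initial condition.** The surface plane starts at `T_w`, the deep plane at
`T_A`; the interior defaults to linear interpolation in depth
(`linear_depth`), with `uniform_arterial` and `uniform_body` (37 °C)
alternatives. The contraction test shows the choice is forgotten within a
few minutes of simulated time.

**Cloth resets.** Every `reset_interval_s` (default 120 s) the surface
plane is clamped back to `T_w` (`clamp_surface_dirichlet`); between resets
the surface follows the Robin condition. Captures that coincide with a
reset tick are taken *before* the reset, so a 2-minute reading reflects the
full warming interval. `refresh_robin_reference` models re-wetting the
cloth without touching the skin nodes — with a constant `T_w` that is a
no-op, which is exactly what the steady-limit tests need.

## Parameters

Shipped constants (per the published parameter table):

| quantity | scalp | skull | CSF | unit |
|---|---|---|---|---|
| k | 0.342 | 0.651 | 0.217 | W m⁻¹ K⁻¹ |
| ρ | 1070 | 1520 | 880 | kg m⁻³ |
| c | 3600 | 1590 | 2360 | J kg⁻¹ K⁻¹ |
| Q_m | 0 (outer) / 1800 (inner) | 0 | 300 | W m⁻³ |

Shared: `m_b = 6.06e-3 kg m⁻³ s⁻¹`, `c_b = 4010 J kg⁻¹ K⁻¹`,
`T_w = 7 °C`, fever cases `T_A ∈ {38.0, 39.5, 41.0} °C`. Layer
thicknesses: scalp 4.5 mm, skull 3.5 mm, CSF 2 mm (10 mm total). The
scalp's avascular/vascular metabolic split depth is not published; it is
set at mid-thickness (2.25 mm) and configurable (`split_fraction`). The
perfusion rate is listed for scalp only but enters every subdomain's
equation in the reference formulation, so it is a shared constant here.

**The surface exchange coefficient h_e.** The published table prints
6.4×10⁻¹ W m⁻² K⁻¹. That value is physically implausible for wet-cloth
contact — it is below free convection in still air (≈ 5–10), while pure
conduction through a millimetre-scale water film is already of order
2×10² — and it renders the surface effectively insulated (steady skin
temperature ≈ 37.9 °C), contradicting the same source's reported surface
temperatures of 8.5–9.7 °C, which require h_e of order 10². The presets
therefore use **6.4×10² W m⁻² K⁻¹**, reading the printed exponent as a
slip. The printed value remains one config line away (`shared.he`), and
the frozen slab-oracle values in the test suite evaluate the closed form
at 0.64 as printed.

**Grid presets.** The published discretization is ambiguous: 4 subintervals
of 2 mm (8 mm, deep clamp at i = 4, the 27-unknown system) versus a 10 mm
anatomical stack with the deep clamp at i = 5. Both readings ship:
`case1_38C` (8 mm, default) and `case1_38C_deep10mm` (10 mm). Neither is
claimed canonical.

## Verification

* **Fin-equation oracle.** The steady 1D slab
  `k T'' − w(T − T_A) + Q = 0` with `w = m_b c_b` has the closed form
  `T = T_A + Q/w + A cosh(mx) + B sinh(mx)`, `m = √(w/k)`, with `A, B`
  from the 2×2 Robin/Dirichlet end-condition system (quadratic profile for
  `w = 0`). The closed form is itself cross-checked against a 10,000-node
  1D finite-difference solve (< 1e-6 °C agreement) and against a symbolic
  second-derivative residual (sympy, < 1e-8).
* **Degeneracy.** On a laterally insulated homogeneous box the 3D solver
  must carry the 1D profile at every lateral position; asserted to
  round-off flatness.
* **Convergence.** Richardson-style refinement h = 2, 1, 0.5 mm against the
  oracle gives observed order 2.00 (second-order Robin) and ≈ 0.94
  (first-order option).
* **Independent dense solve.** The 27-unknown clamped-surface system is
  re-derived with plain loops and dense linear algebra inside the test
  suite and must agree to 1e-10 °C.
* **Structural checks.** Discrete maximum principle and [T_w, T_A]
  perfusion bounds on randomized admissible configurations
  (hypothesis-driven), exact fixed point of the uniform insulated field,
  cell-volume-weighted energy conservation under all-insulated zero-source
  marching, update-weight positivity exactly at the stability bound,
  mirror-symmetry preservation to round-off.

## Reference-table comparisons

The six published temperature tables are shipped verbatim as CSV fixtures
(including their internal mirror-symmetry violations, e.g. 32.19 vs 31.19
at (3, 0, ±1) in the 41 °C steady table — flagged by the symmetry audit,
never silently "corrected"). `compare_reference` produces per-node
deviations, summary statistics, a ±0.5 °C assessment and the violation
list; suspect rows can be excluded from the headline maximum but are never
dropped from the report.

These comparisons are *reports, not assertions*. As noted above, the
model's zero-flux lateral boundaries force a laterally uniform field, while
the tables vary laterally by up to ~9 °C at fixed depth; the tables also
conflict with the printed h_e and with their own symmetry. The shipped
presets land within ~2.7–6.5 °C of the printed values depth-for-depth; the
full per-node breakdown is what `bioheatfd compare` prints.

## Numerical choices and limitations

* Direct sparse factorization everywhere (systems are ≤ a few thousand
  unknowns); no preconditioning needed.
* Interface nodes take whole-node layer coefficients (no harmonic
  averaging), matching the reference formulation; this costs accuracy at
  layer interfaces relative to a flux-conservative scheme and is the main
  deliberate fidelity-over-accuracy choice.
* First-order-in-time explicit scheme; halving the substep changes the
  6-minute readings by < 1e-3 °C on the default presets.
* The geometry is an idealized cuboid: no curvature, hair, air gap,
  sweating/evaporation physics, or temperature-dependent properties.
* The pipeline contains no randomness: identical configs give byte-identical
  long-format outputs.
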