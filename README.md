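# bioheatfd

Finite-difference simulation of heat transfer through the peripheral
layers of the human head — scalp, skull and cerebrospinal fluid (CSF) —
while a cool wet cloth rests on the forehead (tepid sponging, a common
physical treatment for fever).

The package is for people who want a small, fully verifiable bioheat
solver: it discretizes the Pennes bioheat equation

    ρc ∂T/∂t = k ∇²T + m_b c_b (T_A − T) + Q_m + Q_e

on a cuboidal forehead patch with a 7-point stencil, a Robin (or
Dirichlet) cooled surface `k ∂T/∂x = h_e (T − T_w)`, an arterial clamp
`T = T_A` at the deep face and zero-flux lateral faces. It provides

* a **steady solver** (sparse direct solve of the stencil system, with the
  compact 27-interior-unknown lattice of the reference formulation as a
  preset),
* a **transient solver** (consistent FTCS update with a hard stability
  guard at `dt ≤ ρc h²/(6k + h² m_b c_b)` per layer, internal substepping,
  a 2-minute wet-cloth reset schedule, and an optional backward-Euler
  stepper),
* a **verification suite** (closed-form fin-equation slab oracle,
  grid-convergence order estimation, maximum-principle and symmetry
  audits, and per-node diffing against the published temperature tables,
  shipped as fixtures),
* a **CLI** (`bioheatfd run / verify / compare / presets`) and YAML
  scenario configs with three fever presets (T_A = 38.0, 39.5, 41.0 °C).

See `docs/methods.md` for the model, discretization, parameter choices and
known limitations.

## Worked example

```python
import bioheatfd as bh

cfg = bh.load_preset("case1_38C")          # 38.0 C fever, 7 C cloth, h = 2 mm
steady = bh.solve_steady(cfg)
print([round(steady.at(i, 0, 0), 2) for i in range(5)])

cfg_t = cfg.with_(mode="transient")        # readings at 2/4/6 min, resets every 2 min
caps = bh.run_transient(cfg_t)
times, temps = bh.cooling_curve(caps, (0, 0, 0))
print([float(t) for t in times], [round(float(t), 2) for t in temps])

print(f"explicit stability limit: {bh.stability_limit(cfg_t):.4f} s")
```

prints

```
[8.95, 16.23, 23.5, 30.75, 38.0]
[120.0, 240.0, 360.0] [8.89, 8.93, 8.94]
explicit stability limit: 2.4749 s
```

The first line is the steady centerline depth profile: the sponged skin
sits at 8.95 °C, and temperature rises monotonically to the arterial
38 °C at the deep face 8 mm in. The second line shows the skin-centre
readings taken just before each 2-minute cloth reset — with the shipped
surface exchange coefficient the surface settles within a fraction of a
degree of its steady value inside the first cycle. The third line is the
explicit-scheme stability bound, set by the skull layer; the transient
solver substeps at 0.9× this value.

Comparing a run against a published table:

```
$ bioheatfd run --preset case1_38C --mode steady --out results
$ bioheatfd compare --result results/case1_38C_steady_long.csv --fixture table1
comparison against table1: 72 tabulated values
  max |dT|  = 6.60 C
  mean |dT| = 2.59 C
  within +/-0.50 C: 7/72
  fixture symmetry violations: 40 pairs (worst 0.32 C)
  values outside tolerance: 65 (see misses())
```

The large deviations are expected and documented rather than hidden: the
published tables vary laterally although the model's own zero-flux lateral
boundaries make the exact solution laterally uniform, and the printed
surface-exchange coefficient is inconsistent with the tables' own surface
temperatures (`docs/methods.md` discusses both).

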