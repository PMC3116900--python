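# morphocanvas

Finite-element simulation of growing, polarised tissue sheets.

`morphocanvas` is for researchers in computational morphogenesis who want to
ask: *given a pattern of gene-like regulatory factors on a tissue, and growth
rates oriented by a propagating polarity signal, what shape emerges?*  The
tissue ("canvas") is a continuous sheet with two surfaces and a thickness,
discretised as six-node wedge (pentahedral) finite elements.  Regional
identity factors and diffusible signalling factors live on the canvas; a
distinguished signalling factor, the POLARISER (POL), defines a local axis
through its gradient, anchored at plus/minus organiser regions.

## The model

Growth is split into two notions:

- **Specified growth** — the strain an element would undergo per unit time if
  it grew in mechanical isolation.  It is parameterised per element by rates
  parallel (k∥) and perpendicular (k⊥) to the polarity axis on each surface,
  plus a thickness rate, giving a symmetric tensor
  `dt · (k∥ u⊗u + k⊥ v⊗v + k_n n⊗n)` per through-thickness quadrature layer.
- **Resultant growth** — what actually happens once the tissue's continuity
  is enforced.  The velocity-gradient field ∇v decomposes into a symmetric
  resultant strain rate ε (principal growth rates/directions are its
  eigenpairs) and a skew vorticity ω (local rotation).  Rotations are always
  resultant, never specified.

A specified strain field is generally *incompatible* — it violates the
St. Venant condition
`ε_ij,kl + ε_kl,ij − ε_ik,jl − ε_jl,ik = 0` — so it cannot be realised as a
deformation.  Equilibrium minimises the residual-strain energy
`½∫(Du − ε_spec) : C : (Du − ε_spec) dV` with an isotropic stiffness C
(Poisson ratio ν = 0.3 by default; the overall stiffness scale cancels).
The per-step residual `ε_spec − ε_resultant` can be dissipated or retained
as stored pre-stress, which cutting or constraint release reveals.
Signalling factors diffuse, are produced and decayed, and are diluted as
their carrying volume expands; the mesh refines itself by two-threshold edge
splitting with butterfly interpolation.

Twenty-seven presets (`A`–`Z` plus `invagination`) wire these pieces into a
ladder of case studies: uniform anisotropic growth, differential isotropic
growth, frozen vs live vs externally imposed polarity, out-of-plane spikes
and spurs, a simplified corolla tube with growth reorientation,
residual-strain retention/cutting experiments, threshold patterning on a
disc, and furrow invagination driven by opposite-signed growth on the two
surfaces.

## Worked example

Uniform anisotropic growth (preset A): a square sheet with POL clamped to 1
along the bottom edge and 0 along the top, growth k∥ = 1 parallel to the
frozen gradient and k⊥ = 0.

```python
from morphocanvas.presets import get_preset
from morphocanvas.simulation import summarize

sim = get_preset("A")(resolution=10, total_time=1.2)
sim.config.snapshot_every = 0.4
print(summarize(sim.run()).round(4).to_string(index=False))
```

```
 time  area_multiple  max_resultant_anisotropy  mean_clone_anisotropy  residual_norm  element_count
  0.0         1.0000                      0.00                 1.0000            0.0            200
  0.4         1.4775                      0.05                 1.4775            0.0            200
  0.8         2.1829                      0.05                 2.1829            0.0            600
  1.2         3.2251                      0.05                 3.2251            0.0            600
```

The square stretches only along the polarity: the areal multiple and the
clone anisotropy track the closed form e^(k∥·t) (e^1.2 ≈ 3.32; the ≈3%
deficit is the first-order time stepping at the default 10% growth cap —
shrink `max_step_growth` and it converges).  The element count jumps when
the remesher splits stretched edges.  Residual norm stays zero because
dissipation is the default.

The same models run from the shell, writing VTK snapshots, a CSV summary
and a JSON manifest:

```
morphocanvas run A --resolution 10 --time 1.2 --out out/
morphocanvas run model.yaml --out out/     # factor declarations in YAML
morphocanvas list
```

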