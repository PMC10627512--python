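# hipsaxs

Solution small-angle X-ray scattering (SAXS) analysis and modelling for
C2-symmetric protein complexes, built around the *E. coli* HipBST
toxin–antitoxin heterohexamer, plus a classifier for the Gly-rich-loop
phosphosite motifs of HipT-like kinases.

HipBST is a tripartite toxin–antitoxin system in which the kinase toxin
HipT is neutralized by the antitoxin HipS while HipB dimerizes the complex
into a 2:2:2 heterohexamer.  In solution such complexes are dynamic: they
partially oligomerize, domains move, and — depending on the phosphorylation
state of the HipT Gly-rich loop — whole subunits can be absent.  This
package provides the quantitative machinery to study that behaviour from
1-D scattering curves:

* **Primary analysis** — Guinier fit (ln I = ln I₀ − q²R_g²/3), molar mass
  from forward scattering (M = I₀N_A/(cΔρ_m²), Δρ_m = 2.00×10¹⁰ cm g⁻¹),
  indirect Fourier transform to the pair distance distribution p(r) with
  maximum dimension D_max, and the normalized Kratky transform
  (qR_g)²I/I₀ vs qR_g.
* **Forward model** — Debye-equation form factor over coarse-grained
  scattering centers with Gaussian smearing (σ = 1 Å) and an optional
  dummy-atom hydration shell; orientation-averaged amplitude ⟨A(q)⟩; the
  two-parameter oligomerization structure factor
  S(q) = 1 + (N−1)sin(qD)/(qD); total intensity in the decoupling
  approximation I ∝ P + ⟨A⟩²(S−1).  A distance-histogram accelerator
  reproduces the O(n²) Debye sum to <10⁻³ relative error.
* **Restrained rigid-body refinement** — the 3+1+3 body scheme (HipB
  1–31/32–43/44–107, HipS, HipT 2–59/60–169/170–331) under exact C2
  symmetry, harmonic distance restraints at domain boundaries and between
  subunits, a soft excluded-volume term, simultaneous refinement of N and
  D, and best-of-n simulated-annealing runs selected by lowest reduced χ²
  with a deterministic Powell polish.
* **Synthetic data** — seeded generators for bead-model complexes
  (including a heterohexamer stand-in sized to the 135 Å crystal
  structure), noisy curves with a realistic error model, and complete
  recovery scenarios, so the entire pipeline is testable offline.
* **Motif classification** — phospho-window triplets (SΨS, (S/T)ΨT,
  (S/T)ΨP, SΨQ, ΨΨT with Ψ ∈ {I,L,V}) from FASTA input, with per-position
  frequency tables for consensus/logo work.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Simulate the packaged solution scenario — the heterohexamer stand-in with
partial dimerization (N = 1.8, D = 80 Å) and 2% noise — and run the primary
analysis:

```python
import hipsaxs as h
from hipsaxs.synthetic_data import recovery_suite

bundle = recovery_suite()                  # the default solution scenario
curve = bundle.curve                       # q, I, sigma (200 points)

g = h.guinier_fit(curve)
print(f"Guinier: Rg = {g.rg:.1f} A, I0 = {g.i0:.3f}")
pr = h.ift(curve)
print(f"IFT: Dmax = {pr.dmax:.0f} A, chi2_red = {pr.chi2_reduced:.2f}")
print(f"single hexamer: Rg = {h.model_rg(bundle.truth_full):.1f} A, "
      f"max diameter = {h.max_diameter(bundle.truth_full):.1f} A")
```

prints

```
Guinier: Rg = 58.4 A, I0 = 1.784
IFT: Dmax = 182 A, chi2_red = 0.84
single hexamer: Rg = 46.5 A, max diameter = 131.5 A
```

The numbers tell the solution story directly: the apparent R_g (58.4 Å) and
D_max (182 Å) are much larger than the single complex (46.5 Å, 131.5 Å)
because the sample partially dimerizes, and the forward scattering
I₀ = 1.784 ≈ N reads off the mean oligomer mass.  Refining the rigid-body
model against this curve recovers the generating parameters:

```python
fit = h.refine_rigid_body(bundle.truth_half, bundle.scheme, curve,
                          h.FitConfig(n_runs=10, seed=7, t_start=0.5),
                          start_state=bundle.start_state)
print(fit.chi2_reduced, fit.oligomer.N, fit.oligomer.D)
# 1.24  N = 1.82  D = 77.2 A
```

A thin CLI wraps the same functions: `hipsaxs analyze`, `hipsaxs simulate`,
`hipsaxs refine`, `hipsaxs classify` (see `--help` on each).

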