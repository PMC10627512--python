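# Methods

`hipsaxs` models the solution behaviour of C2-symmetric protein complexes —
built around the HipBST toxin–antitoxin heterohexamer — from small-angle
X-ray scattering (SAXS) curves, and classifies the Gly-rich-loop phospho
windows of HipT-like kinases.  This note records the models, the parameters
that matter, the numerical choices, and what the synthetic data do and do
not demonstrate.

## Coarse-grained scattering model

A structure is a set of point scattering centers.  Every non-hydrogen
protein atom (or bead, in synthetic models) carries the same average excess
scattering length `b = 1` in relative units; since the overall intensity
scale is always refined against the data, only relative contrasts matter,
and absolute units re-enter solely through the molar-mass formula.  An
optional hydration layer is a single shell of dummy centers placed on a
cubic grid (pitch `grid_spacing`, default 3.5 Å) at distances
`[shell_distance, shell_distance + grid_spacing)` (default shell 3 Å) from
the nearest protein center, with a user-chosen contrast `dummy_b`
(default 0, i.e. no hydration contribution, which makes oracle comparisons
exact; positive values add the shell to every term of the forward model).

The forward intensity of a dilute, partially oligomerized solution is the
decoupling approximation

    I(q) = scale · [ P(q) + ⟨A(q)⟩² (S(q) − 1) ],

with the Debye form factor
`P(q) = exp(−q²σ²) Σᵢⱼ bᵢbⱼ sinc(q dᵢⱼ) / (Σᵢbᵢ)²`, the
center-of-mass amplitude
`⟨A(q)⟩ = exp(−q²σ²/2) Σᵢ bᵢ sinc(q dᵢ,CM) / Σᵢbᵢ`, and the two-parameter
structure factor `S(q) = 1 + (N−1) sinc(qD)` describing partial
oligomerization with mean copy number `N ≥ 1` and inter-particle distance
`D`.  The Gaussian smearing width is σ = 1.0 Å.  `P(0) = ⟨A(0)⟩ = 1` by
construction, so `I(0)/scale = N`: forward scattering reports oligomer
mass.  `⟨A⟩² ≤ P` holds pointwise (Cauchy–Schwarz) and is tested.

### Histogram acceleration

The exact Debye sum is O(n²) per q value.  The accelerated path bins pair
distances once (bin width 0.15 Å) and evaluates each bin at its mean pair
distance, which cancels the first-order binning error; the residual is
O((q·Δ)²) and measures (3–6)×10⁻⁴ relative against the direct sum for
2000-center structures over q ≤ 0.35 Å⁻¹.  0.15 Å was chosen as the widest
bin that keeps this error below 10⁻³ across the fixtures; the cost is
dominated by the distance computation either way.

## Primary curve analysis

* **Guinier fit** — weighted linear regression of ln I on q² over the
  largest low-q window with q·Rg ≤ 1.3 (the usual convention for globular
  particles), iterated to self-consistency; returns Rg = √(−3·slope) and
  I0 = exp(intercept).
* **Molar mass** — M = I0·N_A /(c·Δρₘ²) with Δρₘ = 2.00×10¹⁰ cm g⁻¹, the
  typical protein excess scattering length per unit mass; exact arithmetic.
* **Indirect Fourier transform** — p(r) on a histogram basis (100 bins over
  [0, Dmax], p(0) = p(Dmax) = 0) fitted to the curve through
  I(q) = 4π Σⱼ p(rⱼ) sinc(q rⱼ) Δr by error-weighted least squares with a
  second-difference (Tikhonov) penalty and, by default, non-negativity
  (NNLS).  `alpha="auto"` takes the L-curve corner (maximum curvature over a
  log-spaced grid).  `dmax="auto"` scans 25 candidates between 2·Rg and
  5·Rg and keeps the smallest Dmax whose χ² is within 5% of the minimum — a
  parsimonious-support rule.  The reported reduced χ² divides by the number
  of data points, because a regularized fit has no well-defined free
  parameter count.  Note that Dmax is resolvable only to roughly the noise
  level of the curve: particles whose pair-distance density fades smoothly
  into the support edge (e.g. random bead globules) come out a few percent
  short, while sharp-edged bodies (spheres) are recovered within the stated
  5%.
* **Normalized Kratky transform** — (qRg, (qRg)²·I/I0), no smoothing.  A
  Guinier-shaped (compact) curve peaks at (√3, 3/e); a coil plateaus.

## Restrained rigid-body refinement

The model is the asymmetric half of a C2 assembly divided into rigid bodies
(for HipBST: HipB 1–31 / 32–43 / 44–107, HipS whole, HipT 2–59 / 60–169 /
170–331).  Each body carries an axis-angle rotation about its reference
centroid plus a translation; the symmetry mate is regenerated from the
transformed half at every evaluation, so all intermediate models are
exactly two-fold symmetric.  The all-zero state reproduces the input
bit-exactly.

The objective is

    χ²_red (analytic optimal scale) + restraints + excluded volume.

* χ²_red uses the closed-form scale s* = Σ(IₘIₑ/σ²)/Σ(Iₘ²/σ²) and degrees
  of freedom n_points − (1 + 6·n_bodies + 2); the parameter count is
  configurable since conventions differ.
* Restraints are harmonic in distance, weight 10 Å⁻² by default, anchored
  at the CA centers of named residues; targets are measured in the
  starting (reference) structure.  The packaged HipBST set comprises the
  six inter-domain pairs (Glu A107–Val D101, Pro B55–Gly C154,
  Trp B65–Gly C60, Gly D100–Asp F188, Leu D6–Arg F291, Val C147–Gly B94;
  chains A/E = HipB, B/D = HipS, C/F = HipT) plus chain-continuity
  restraints at the four intra-chain body boundaries (A31–A32, A43–A44,
  C59–C60, C169–C170).  Without the boundary set, small bodies that touch
  the data only weakly (HipB 1–31 is ~3% of the mass) are essentially
  unconstrained.
* Excluded volume: weight·Σ(cutoff − d)² over inter-body center pairs
  closer than 4 Å (weight 0.1 Å⁻²), continuous at the cutoff, intra-body
  pairs ignored.

**Search.**  `n_runs` (default 10) independent simulated-annealing runs,
each seeded deterministically from (seed, run index): Gaussian per-body
proposals (σ_trans 2 Å, σ_rot 5°), lognormal steps on N and D reflected at
their bounds (N ∈ [1,4], D ∈ [20,300] Å), geometric cooling (0.97 every 10
iterations) with proposal widths shrinking as √(T/T₀) down to a floor.
T₀ = 2 by default; 0.5 is appropriate when the start is already
restraint-consistent.  A fraction of proposals (10%) are basin hops: a
large rotation of one body about the centroid of its restraint anchors,
which relocates the body substantially while disturbing the restraint
distances far less than a random jump of the same size.

The best few annealing runs (`polish_top_k`, default 2) are then polished
deterministically, and the overall minimum-χ² result is reported.  The
polish has three parts: (i) a joint Powell descent over all body transforms
plus (N, D); (ii) block-coordinate sweeps, one 6-parameter Powell
sub-problem per body followed by a 2-parameter (N, D) step; and (iii)
inside each block step, a restraint-valley scan.  The scan exists because
the distance restraints fix at most rank-of-Jacobian of a body's six rigid
degrees of freedom, leaving a low-dimensional valley along which only the
weak data term varies, typically with several shallow minima separated by
barriers no local descent crosses.  The scan computes the restraint-distance
Jacobian of the body numerically, takes its null directions (SVD), steps
±2.5–12 Å along each, re-projects every step onto the valley by minimizing
the restraint penalty alone (cheap — no scattering evaluation), and starts
the local descent from the best candidate.  Polished results replace a
run's summary only if they do not worsen its χ²_red, so the reported fit
always equals the minimum over the per-run summaries.

When a hydration shell with positive contrast is configured, the shell is
rebuilt only every 25 accepted moves during annealing (it moves rigidly
with the model in between) and exactly for the final reported model.

**Gauge freedom.**  Rotations about the C2 axis and translations along it
change neither the orientation-averaged scattering nor any internal
distance; refined models are therefore defined only up to this subgroup.
`gauge_align` removes it in closed form before models are compared — the
analogue of superposition before an RMSD.

## Synthetic data

The generator reproduces the data-generating process the analysis assumes,
at the conditions of the solution study this package is built around:

* **Heterohexamer stand-in** — one bead per residue, each rigid body a
  uniform-density bead globule (radius 3.14·n^⅓ Å, i.e. ~130 Å³ per
  residue), bodies laid out with ≥5 Å surface gaps (so the reference state
  has zero clash penalty) and the assembled C2 dimer spanning ~135 Å —
  the maximum diameter of the crystallographic hexamer it stands in for.
  It is labelled synthetic everywhere; it reproduces coarse dimensions and
  mass distribution, not fold-level detail.
* **Oligomerization truth** — N = 1.8, D = 80 Å, the anchor values of the
  solution study.
* **Noise** — σ(q) = 0.02·I(q) + 10⁻⁴·I(0), multiplicative with an
  additive floor as for a laboratory-source instrument, and the scatter is
  drawn from that same σ, so the truth model scores χ²_red ≈ 1 on its own
  curve by construction.
* **Start states** — the default recovery scenario displaces the HipS body
  by exactly 8 Å in a seeded random direction, the others starting at
  truth; `perturb_bodies`/`displace_bodies` generate broader or exact
  perturbations for other experiments.
* **q grid** — 200 log-spaced points, 0.008–0.35 Å⁻¹ (a typical
  laboratory-source range).

What passing these tests shows: the pipeline recovers its own generating
parameters under realistic noise, discriminates topologies (a model missing
a 19%-of-mass domain fits data from the omitted complex far better than the
full model, and vice versa), and is deterministic.  The oligomer
parameters and the reduced χ² are recovered robustly across noise
realizations; how closely the displaced body's centroid returns to truth
depends on the realization and the displacement direction, because the
data term along the restraint valley is shallow — single-Angstrom
placement claims from curves like these should always be treated with that
caveat.  What it does not show:
agreement with any particular experimental curve — the underlying
experimental data are not publicly deposited, so the printed fit statistics
of the original study serve as recovery anchors, not reproduction targets.

## Motif classification

The phospho window of a HipT-like Gly-rich loop is a three-residue string
whose center must be aliphatic (Ψ ∈ {I, L, V}).  Flanks are matched in
precedence order SΨS → (S/T)ΨT → (S/T)ΨP → SΨQ → ΨΨT → other; the order
only disambiguates overlapping patterns (SΨS before (S/T)ΨT so that S_S is
not swallowed by the T-flank group), and every triplet maps to exactly one
group.  By default the window is located by a regular expression anchored
on the Gly-rich stretch (an aliphatic-centered triplet followed by a
glycine within two residues); explicit coordinates override the search,
which is the right choice when an alignment is available.  Ambiguity codes
classify as "other" with a warning.  The 48-sequence fixture reproduces the
observed class distribution across HipT orthologues, with SΨS the dominant
group (30/48).

## Problem sizes and runtimes

The shipped scenarios were sized so the whole suite runs comfortably on a
single CPU: 1080-bead hexamer models (one bead per residue), 2000-center
accelerator fixtures, ~2700-center sphere quadratures, 200-point curves,
10×400 annealing iterations plus a ~2500-evaluation polish per refinement.
At these sizes one objective evaluation costs ~20 ms and a full 10-run
refinement a few minutes.  All randomness flows from explicit integer
seeds; reruns are bit-identical.

## Known limitations

* Per-element atomic form factors, slit smearing, and polydispersity beyond
  the two-parameter S(q) are out of scope.
* The IFT is a deterministic regularized histogram fit; it makes no
  evidence-based (Bayesian) choice of smoothness, and its Dmax inherits the
  support-edge resolution limit discussed above.
* The refinement explores rigid-body space only — no torsions, no
  ensembles; restraint targets come from the reference structure, which
  presumes the reference contacts are to be preserved.
* The hydration shell is a single-layer grid construction with a free
  contrast parameter, not a fitted water model.
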