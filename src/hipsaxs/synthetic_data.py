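"""Synthetic structures, scenarios and noisy curves.

The experimental curves this package's methods were designed for are not
publicly deposited, so every pipeline stage is exercised against synthetic
data whose generating process matches the analysis assumptions: a
coarse-grained C2-symmetric heterohexamer stand-in (bead globules per rigid
body, labelled with the HipBST chain/residue conventions), partial
dimerization described by the two-parameter structure factor (N ~ 1.7-1.8,
inter-hexamer distance ~ 80 A), and multiplicative Gaussian noise with a
small additive floor.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .primary_analysis import SAXSCurve, save_curve
from .scattering import DEFAULT_QGRID, DEFAULT_SIGMA_SMEAR, OligomerModel, intensity_decoupled
from .structure_model import (
    BodyScheme,
    BodyState,
    CoarseStructure,
    apply_body_state,
    apply_c2,
    concat_structures,
    load_default_scheme,
    partition_bodies,
    write_pdb,
)


class SyntheticError(ValueError):
    pass


#: Bead spacing used for chain-like topologies (CA-CA distance, Angstrom).
BEAD_SPACING = 3.8

#: Bead number density matching globular protein (one residue per ~130 A^3);
#: a globule of n beads gets radius BEAD_RADIUS_COEF * n^(1/3).
BEAD_RADIUS_COEF = 3.14

#: Heterohexamer stand-in: per-body globule layout of the asymmetric half
#: (chain, first residue, last residue, centroid x/y/z).  The C2 axis is z
#: through the origin; mate chains follow the A->E, B->D, C->F convention.
#: Centroids were placed so that all inter-body surface gaps exceed 5 A
#: (no excluded-volume penalty in the reference state) and the assembled
#: dimer reproduces the ~135 A maximum diameter of the crystal structure.
HEXAMER_LAYOUT = [
    # label     chain first last  centroid
    ("hipB_n",    "A",   1,  31, (12.0,  22.0,   0.0)),
    ("hipB_mid",  "A",  32,  43, (10.0,   0.0,   0.0)),
    ("hipB_core", "A",  44, 107, (12.0, -28.0,  14.0)),
    ("hipS",      "B",   1, 102, (44.0,   3.0, -29.0)),
    ("hipT_n",    "C",   1,  59, (37.0,  33.0,  -6.0)),
    ("hipT_mid",  "C",  60, 169, (37.0,   0.0,   8.0)),
    ("hipT_c",    "C", 170, 331, (36.0, -35.0, -14.0)),
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise with an additive floor:
    I_obs = I (1 + eps), eps ~ N(0, rel_sigma);
    sigma = rel_sigma * I + floor_fraction * I(0)."""
    rel_sigma: float = 0.02
    floor_fraction: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.rel_sigma < 0 or self.floor_fraction < 0:
            raise SyntheticError("noise parameters must be non-negative")


@dataclass
class ScenarioSpec:
    """A complete, reproducible test scenario."""
    topology: str = "hexamer_like"        # hexamer_like | domain_omitted | sphere | dumbbell
    oligomer: OligomerModel = field(default_factory=lambda: OligomerModel(N=1.8, D=80.0))
    noise: NoiseModel = field(default_factory=NoiseModel)
    qgrid: np.ndarray = field(default_factory=lambda: DEFAULT_QGRID.copy())
    seed: int = 0
    beads_per_residue: int = 1
    perturbed_bodies: tuple = ("hipS",)   # bodies displaced in the start state
    max_shift: float = 8.0                # start-state displacement, A (exact)
    max_angle_deg: float = 0.0            # start-state rotation, deg (exact)
    sphere_radius: float = 30.0
    sphere_n: int = 2000
    dumbbell_radius: float = 15.0
    dumbbell_separation: float = 60.0
    sigma_smear: float = DEFAULT_SIGMA_SMEAR


# ---------------------------------------------------------------------------
# bead structures
# ---------------------------------------------------------------------------

def sphere_cloud(n: int, radius: float, seed: int = 0) -> np.ndarray:
    """n points uniform in a sphere (seeded, exact radial inversion)."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def _bead_structure(coords, chain, first_res, provenance) -> CoarseStructure:
    n = len(coords)
    return CoarseStructure(
        coords, np.ones(n), np.zeros(n, np.uint8), np.full(n, chain),
        np.arange(first_res, first_res + n), np.full(n, "ALA"),
        np.full(n, "CA"), provenance,
    )


def make_hexamer_half(seed: int = 0, omit_hipS: bool = False) -> CoarseStructure:
    """Asymmetric half of the synthetic heterohexamer stand-in.

    One bead per residue, grouped into per-body globules laid out per
    ``HEXAMER_LAYOUT``; chains A (HipB), B (HipS), C (HipT).  This is a
    synthetic stand-in for the deposited crystal structure, sized to match
    its overall dimensions.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for label, chain, first, last, centroid in HEXAMER_LAYOUT:
        if omit_hipS and chain == "B":
            continue
        n = last - first + 1
        radius = BEAD_RADIUS_COEF * n ** (1.0 / 3.0)
        pts = sphere_cloud(n, radius, seed=int(rng.integers(2**31))) + np.asarray(centroid)
        parts.append(_bead_structure(pts, chain, first, f"blob {label}"))
    return concat_structures(*parts, provenance=f"synthetic hexamer half (seed={seed})")


def make_bead_complex(spec: ScenarioSpec) -> CoarseStructure:
    """Build the scenario's truth structure (full assembly)."""
    if spec.topology in ("hexamer_like", "full_hexamer_like"):
        half = make_hexamer_half(spec.seed)
        return apply_c2(half)
    if spec.topology == "domain_omitted":
        half = make_hexamer_half(spec.seed, omit_hipS=True)
        return apply_c2(half)
    if spec.topology == "sphere":
        pts = sphere_cloud(spec.sphere_n, spec.sphere_radius, spec.seed)
        return _bead_structure(pts, "A", 1, f"sphere R={spec.sphere_radius}")
    if spec.topology == "dumbbell":
        half_sep = spec.dumbbell_separation / 2.0
        n = spec.sphere_n // 2
        a = sphere_cloud(n, spec.dumbbell_radius, spec.seed) + [half_sep, 0, 0]
        b = sphere_cloud(n, spec.dumbbell_radius, spec.seed + 1) - [half_sep, 0, 0]
        return concat_structures(
            _bead_structure(a, "A", 1, "lobe A"),
            _bead_structure(b, "B", 1, "lobe B"),
            provenance="synthetic dumbbell",
        )
    raise SyntheticError(f"unknown topology {spec.topology!r}")


# ---------------------------------------------------------------------------
# curve simulation
# ---------------------------------------------------------------------------

def simulate_curve(
    structure: CoarseStructure,
    oligomer: OligomerModel,
    noise: NoiseModel,
    qgrid=None,
    sigma_smear: float = DEFAULT_SIGMA_SMEAR,
    use_histogram: bool = False,
    bin_width: float = 0.15,
) -> SAXSCurve:
    """Simulate a noisy observed curve from the decoupled forward model.

    The error column is sigma = rel_sigma * I_model + floor * I_model(0)
    (multiplicative noise with an additive floor, as for a lab-source
    instrument) and the noise is drawn consistently from it,
    I_obs = I_model + sigma * z with z ~ N(0, 1), so the truth model scores
    a reduced chi^2 of ~1 against its own curve.
    """
    q = DEFAULT_QGRID if qgrid is None else np.asarray(qgrid, dtype=float)
    model = intensity_decoupled(structure, oligomer, q, sigma_smear=sigma_smear,
                                use_histogram=use_histogram, bin_width=bin_width)
    i_model = model.intensity
    rng = np.random.default_rng(noise.seed)
    sigma = noise.rel_sigma * i_model + noise.floor_fraction * i_model[0]
    if np.any(sigma <= 0):
        sigma = np.maximum(sigma, 1e-12 * max(abs(i_model[0]), 1.0))
    scatter = sigma if noise.rel_sigma > 0 else 0.0
    return SAXSCurve(q, i_model + scatter * rng.standard_normal(i_model.shape),
                     sigma)


def perturb_bodies(
    state: BodyState,
    max_shift: float,
    max_angle_deg: float,
    seed: int = 0,
) -> BodyState:
    """Seeded random start-state: each body gets a rotation of angle
    uniform in (0, max_angle_deg] about a random axis and a translation
    uniform in the ball of radius ``max_shift``."""
    if max_shift < 0 or max_angle_deg < 0:
        raise SyntheticError("perturbation magnitudes must be non-negative")
    rng = np.random.default_rng(seed)
    out = state.copy()
    for k in range(state.n_bodies):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(max_angle_deg) * rng.random()
        out.rotvecs[k] = out.rotvecs[k] + axis * angle
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        out.translations[k] = (out.translations[k]
                               + direction * max_shift * rng.random() ** (1.0 / 3.0))
    return out


def displace_bodies(state: BodyState, labels: list, which, shift: float,
                    angle_deg: float, seed: int = 0) -> BodyState:
    """Exact-magnitude start-state displacement of selected bodies.

    Each body named in ``which`` ("all" for every body) is translated by
    exactly ``shift`` Angstrom in a seeded random direction and rotated by
    exactly ``angle_deg`` about a seeded random axis."""
    rng = np.random.default_rng(seed)
    out = state.copy()
    targets = list(labels) if which == "all" else list(which)
    for k, lab in enumerate(labels):
        if lab not in targets:
            continue
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        out.translations[k] = out.translations[k] + shift * direction
        if angle_deg > 0:
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            out.rotvecs[k] = out.rotvecs[k] + np.deg2rad(angle_deg) * axis
    return out


# ---------------------------------------------------------------------------
# packaged scenarios
# ---------------------------------------------------------------------------

@dataclass
class RecoveryBundle:
    """Everything needed for an end-to-end recovery experiment."""
    spec: ScenarioSpec
    truth_half: CoarseStructure | None
    truth_full: CoarseStructure
    scheme: BodyScheme | None
    truth_state: BodyState | None
    start_state: BodyState | None
    oligomer: OligomerModel
    curve: SAXSCurve
    tolerances: dict


def recovery_suite(spec: ScenarioSpec | None = None,
                   out_dir: str | Path | None = None) -> RecoveryBundle:
    """Package a complete refinement test scenario.

    The default "paper-anchor" scenario is the heterohexamer stand-in with
    partial dimerization N = 1.8, D = 80 A and 2% noise; the start state
    perturbs every body (translations up to ``max_shift``, rotations up to
    ``max_angle_deg``).  With ``out_dir`` the truth/start structures, curve
    and ground-truth parameters are written as PDB/dat/YAML text files.
    """
    spec = spec or ScenarioSpec()
    if spec.topology in ("hexamer_like", "full_hexamer_like", "domain_omitted"):
        omit = spec.topology == "domain_omitted"
        half = make_hexamer_half(spec.seed, omit_hipS=omit)
        full = apply_c2(half)
        scheme = load_default_scheme()
        if omit:
            scheme = BodyScheme(
                bodies=[b for b in scheme.bodies if b.chain != "B"],
                symmetry=scheme.symmetry,
                restraints=[r for r in scheme.restraints
                            if {r.chain_a, r.chain_b}.isdisjoint({"B", "D"})],
            )
        bodies = partition_bodies(half, scheme)
        truth_state = BodyState.identity(len(bodies))
        start_state = displace_bodies(truth_state, list(bodies),
                                      spec.perturbed_bodies, spec.max_shift,
                                      spec.max_angle_deg, seed=spec.seed + 1)
    else:
        half, scheme, truth_state, start_state = None, None, None, None
        full = make_bead_complex(spec)
    curve = simulate_curve(full, spec.oligomer, spec.noise, spec.qgrid,
                           spec.sigma_smear)
    tolerances = {
        "n_range": (1.65, 1.95),
        "d_rel_tol": 0.10,
        "chi2_max": 1.5,
        "centroid_tol": 3.0,
    }
    bundle = RecoveryBundle(spec, half, full, scheme, truth_state, start_state,
                            spec.oligomer, curve, tolerances)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: RecoveryBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "truth.pdb").write_text(write_pdb(bundle.truth_full))
    save_curve(out_dir / "curve.dat", bundle.curve)
    truth = {
        "topology": bundle.spec.topology,
        "seed": int(bundle.spec.seed),
        "N": float(bundle.oligomer.N),
        "D": float(bundle.oligomer.D),
        "rel_sigma": float(bundle.spec.noise.rel_sigma),
        "tolerances": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in bundle.tolerances.items()},
    }
    (out_dir / "truth.yaml").write_text(yaml.safe_dump(truth))
    if bundle.start_state is not None:
        half = apply_body_state(
            bundle.truth_half.coords,
            partition_bodies(bundle.truth_half, bundle.scheme),
            bundle.start_state,
        )
        start_full = apply_c2(bundle.truth_half.with_coords(half))
        (out_dir / "start.pdb").write_text(write_pdb(start_full))


# ---------------------------------------------------------------------------
# Gly-rich-loop sequence fixtures
# ---------------------------------------------------------------------------

#: Non-aliphatic flank alphabet (no I/L/V, so flanks cannot create spurious
#: phospho-window anchors; G allowed).
_FLANK_AA = list("ACDEFGHKMNPQRSTWY")

#: Ground-truth motif composition of the 48-orthologue-like fixture: the
#: SpsiS class dominates, mirroring the distribution seen across HipT-like
#: kinases.
LOOP_FIXTURE_COMPOSITION = [
    ("S{c}S", "SpsiS", 30),
    ("T{c}T", "(S/T)psiT", 6),
    ("S{c}P", "(S/T)psiP", 5),
    ("S{c}Q", "SpsiQ", 4),
    ("I{c}T", "psipsiT", 2),
    ("A{c}A", "other", 1),
]


def make_loop_records(n_total: int = 48, seed: int = 0):
    """Synthetic Gly-rich-loop sequences with known motif classes.

    Returns a list of ``(id, sequence, true_group)``; each sequence embeds a
    phospho-window triplet followed by a Gly-rich stretch, flanked by
    residues that cannot match the window anchor.  Composition follows
    ``LOOP_FIXTURE_COMPOSITION`` (scaled if ``n_total`` differs from 48).
    """
    rng = np.random.default_rng(seed)
    comp = LOOP_FIXTURE_COMPOSITION
    counts = [c for _, _, c in comp]
    if n_total != sum(counts):
        scaled = np.maximum(1, np.round(np.array(counts) * n_total / sum(counts)))
        scaled[0] += n_total - scaled.sum()
        counts = [int(c) for c in scaled]
    records = []
    i = 0
    for (template, group, _), count in zip(comp, counts):
        for _ in range(count):
            center = "ILV"[rng.integers(3)]
            triplet = template.format(c=center)
            flank1 = "".join(rng.choice(_FLANK_AA, size=8))
            flank2 = "".join(rng.choice(_FLANK_AA, size=6))
            seq = flank1 + triplet + "AGSGDF" + flank2
            records.append((f"orth{i:03d}", seq, group))
            i += 1
    return records


def write_loop_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec[0]}\n{rec[1]}\n")
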