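"""Coarse-grained structural models for solution scattering.

A macromolecule is represented as a set of point scattering centers: one
center per non-hydrogen atom (or per bead, for synthetic models), each with
an excess scattering length ``b``.  Because the overall intensity scale is
always fitted to data, ``b`` is kept in relative units with all protein
atoms sharing the same average value.  Hydration water is represented by an
optional shell of dummy centers whose contrast may take any sign.

The module also defines rigid-body machinery: a partition of the chains into
bodies with inclusive residue ranges, per-body rigid transforms, distance
restraints between residue anchors, and the C2 symmetry operation used for
homodimeric complexes such as HipBST (two copies each of HipB, HipS and
HipT related by a two-fold axis through the HipB dimer).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import yaml
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

logger = logging.getLogger("hipsaxs")

#: Average excess scattering length assigned to every non-hydrogen protein
#: atom (relative units; the absolute scale is fitted).
PROTEIN_B = 1.0

KIND_PROTEIN = 0
KIND_DUMMY = 1

#: Chain identity convention for the HipBST heterohexamer, inferred from the
#: deposited restraint anchors: A/E are HipB, B/D are HipS, C/F are HipT.
HIPBST_CHAIN_MAP = {"A": "E", "B": "D", "C": "F"}

_AA_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class StructureError(ValueError):
    """Raised for malformed structural input or empty selections."""


# ---------------------------------------------------------------------------
# core container
# ---------------------------------------------------------------------------

@dataclass
class CoarseStructure:
    """Ordered set of scattering centers with chain/residue annotation.

    Fields are parallel numpy arrays of length ``n_centers``.  ``kind`` is
    ``KIND_PROTEIN`` (0) or ``KIND_DUMMY`` (1); dummy centers model the
    hydration shell and are excluded from geometric measures by default.
    """

    coords: np.ndarray          # (n, 3) float64, Angstrom
    b: np.ndarray               # (n,) float64, relative excess scattering length
    kind: np.ndarray            # (n,) uint8
    chain: np.ndarray           # (n,) str
    resnum: np.ndarray          # (n,) int64
    resname: np.ndarray         # (n,) str
    atom_name: np.ndarray       # (n,) str
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.b = np.asarray(self.b, dtype=float).reshape(n)
        self.kind = np.asarray(self.kind, dtype=np.uint8).reshape(n)
        self.chain = np.asarray(self.chain, dtype="U4").reshape(n)
        self.resnum = np.asarray(self.resnum, dtype=np.int64).reshape(n)
        self.resname = np.asarray(self.resname, dtype="U3").reshape(n)
        self.atom_name = np.asarray(self.atom_name, dtype="U4").reshape(n)
        if n == 0:
            raise StructureError("structure has no scattering centers")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        prot = self.kind == KIND_PROTEIN
        if np.any(self.b[prot] <= 0):
            raise StructureError("protein centers must have b > 0")
        if self.b.sum() <= 0:
            raise StructureError("total scattering length must be positive")
        uniq = np.unique(self.coords, axis=0)
        if len(uniq) < n:
            raise StructureError("coincident scattering centers")

    @property
    def n_centers(self) -> int:
        return len(self.coords)

    @property
    def is_protein(self) -> np.ndarray:
        return self.kind == KIND_PROTEIN

    def select(self, mask: np.ndarray, provenance: str | None = None) -> "CoarseStructure":
        """Subset of centers (order preserved)."""
        idx = np.asarray(mask)
        return CoarseStructure(
            self.coords[idx], self.b[idx], self.kind[idx], self.chain[idx],
            self.resnum[idx], self.resname[idx], self.atom_name[idx],
            provenance if provenance is not None else self.provenance,
        )

    def with_coords(self, coords: np.ndarray) -> "CoarseStructure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(str(c))
        return list(seen)


def concat_structures(*parts: CoarseStructure, provenance: str = "") -> CoarseStructure:
    """Concatenate centers of several structures, preserving order."""
    return CoarseStructure(
        np.concatenate([p.coords for p in parts]),
        np.concatenate([p.b for p in parts]),
        np.concatenate([p.kind for p in parts]),
        np.concatenate([p.chain for p in parts]),
        np.concatenate([p.resnum for p in parts]),
        np.concatenate([p.resname for p in parts]),
        np.concatenate([p.atom_name for p in parts]),
        provenance,
    )


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def read_structure(
    pdb_text: str,
    include_hydrogens: bool = False,
    include_hetero: bool = False,
    b: float = PROTEIN_B,
) -> CoarseStructure:
    """Parse PDB-format text into a coarse scattering model.

    Every non-hydrogen atom becomes one center with the same average
    scattering length ``b`` (relative units).  Waters, and by default all
    HETATM ligands, are excluded; alternate locations keep only the first
    conformer encountered.
    """
    if "ATOM" not in pdb_text and "HETATM" not in pdb_text:
        raise StructureError("no ATOM/HETATM records in input")
    try:
        if pdb_text.lstrip().startswith("data_"):  # mmCIF content
            doc = gemmi.cif.read_string(pdb_text)
            st = gemmi.make_structure_from_block(doc[0])
        else:
            st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line
        raise StructureError(f"malformed PDB input: {exc}") from exc
    st.setup_entities()
    coords, chains, resnums, resnames, atnames = [], [], [], [], []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            if res.het_flag == "H" and not include_hetero:
                continue
            seen_alt: set[str] = set()
            for atom in res:
                if atom.is_hydrogen() and not include_hydrogens:
                    continue
                if atom.name in seen_alt:
                    continue
                seen_alt.add(atom.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                chains.append(chain.name)
                resnums.append(res.seqid.num)
                resnames.append(res.name)
                atnames.append(atom.name)
    if not coords:
        raise StructureError("selection is empty after filtering")
    n = len(coords)
    return CoarseStructure(
        np.array(coords), np.full(n, b), np.zeros(n, np.uint8),
        np.array(chains), np.array(resnums), np.array(resnames),
        np.array(atnames), provenance="read_structure",
    )


def write_pdb(structure: CoarseStructure) -> str:
    """Serialize centers as PDB ATOM records (3-decimal coordinates)."""
    lines = []
    for i in range(structure.n_centers):
        x, y, z = structure.coords[i]
        name = str(structure.atom_name[i])[:4]
        pad = name if len(name) == 4 else f" {name:<3s}"
        lines.append(
            f"ATOM  {(i + 1) % 100000:5d} {pad} {str(structure.resname[i]):>3s} "
            f"{str(structure.chain[i])[:1]:1s}{int(structure.resnum[i]) % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# chain-level editing
# ---------------------------------------------------------------------------

def omit_chains(structure: CoarseStructure, chains) -> CoarseStructure:
    """Remove all centers belonging to the named chains.

    Mirrors model-building with a subunit left out (e.g. a HipS-omitted
    heterohexamer); remaining center order is preserved.
    """
    chains = set(chains)
    available = set(structure.chains())
    unknown = chains - available
    if unknown:
        raise StructureError(
            f"unknown chain(s) {sorted(unknown)}; available: {sorted(available)}"
        )
    mask = ~np.isin(structure.chain, list(chains))
    if not mask.any():
        raise StructureError("omitting all chains leaves an empty structure")
    return structure.select(mask, provenance=f"{structure.provenance}; omit {sorted(chains)}")


# ---------------------------------------------------------------------------
# ideal-helix stand-in for a disordered terminus
# ---------------------------------------------------------------------------

#: Centers generated per residue of the helix stand-in: one CA plus one CB
#: pseudo-atom (CA only for glycine).
HELIX_CENTERS_PER_RESIDUE = 2
HELIX_RISE = 1.5          # Angstrom per residue
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.3        # CA helix radius, Angstrom
HELIX_CB_OFFSET = 1.5     # radial CB offset beyond CA, Angstrom


def build_helix_standin(
    sequence: str,
    start_residue: int = 1,
    attach_point=(0.0, 0.0, 0.0),
    direction=(0.0, 0.0, 1.0),
    chain: str = "A",
) -> CoarseStructure:
    """Ideal alpha-helix stand-in for a disordered segment.

    Generates CA (and CB for non-Gly) pseudo-atoms on an ideal helix (1.5 A
    rise, 100 deg twist per residue) running along ``direction`` with the
    first CA placed exactly at ``attach_point``.  Used to restore segments
    missing from a crystal structure, such as a helical N-terminal extension,
    so the model mass matches the full-length protein.
    """
    sequence = sequence.upper()
    if not sequence:
        raise StructureError("empty helix sequence")
    bad = set(sequence) - set(_AA_3)
    if bad:
        raise StructureError(f"invalid residue letter(s): {sorted(bad)}")
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise StructureError("helix direction must be non-zero")
    axis = direction / nrm

    coords, resnums, resnames, atnames = [], [], [], []
    for i, aa in enumerate(sequence):
        theta = np.deg2rad(HELIX_TWIST * i)
        ca = np.array([HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta),
                       HELIX_RISE * i])
        coords.append(ca)
        resnums.append(start_residue + i)
        resnames.append(_AA_3[aa])
        atnames.append("CA")
        if aa != "G":
            r_cb = HELIX_RADIUS + HELIX_CB_OFFSET
            coords.append(np.array([r_cb * np.cos(theta), r_cb * np.sin(theta),
                                    HELIX_RISE * i]))
            resnums.append(start_residue + i)
            resnames.append(_AA_3[aa])
            atnames.append("CB")
    local = np.array(coords)
    local -= local[0]  # first CA at origin
    # rotate local z onto the requested axis
    rot, _ = Rotation.align_vectors(np.atleast_2d(axis), [[0.0, 0.0, 1.0]])
    world = rot.apply(local) + np.asarray(attach_point, dtype=float)
    n = len(world)
    return CoarseStructure(
        world, np.full(n, PROTEIN_B), np.zeros(n, np.uint8),
        np.full(n, chain), np.array(resnums), np.array(resnames),
        np.array(atnames), provenance="helix_standin",
    )


# ---------------------------------------------------------------------------
# hydration shell
# ---------------------------------------------------------------------------

def add_hydration_layer(
    structure: CoarseStructure,
    shell_distance: float = 3.0,
    grid_spacing: float = 3.5,
    dummy_b: float = 0.0,
) -> CoarseStructure:
    """Add a dummy-atom hydration shell around the protein envelope.

    Candidate points on a cubic grid of pitch ``grid_spacing`` are kept when
    their distance to the nearest protein center falls in
    ``[shell_distance, shell_distance + grid_spacing)``: a one-layer shell
    hugging the envelope, guaranteed at least ``grid_spacing`` apart and
    never inside the protein.  Dummy centers carry contrast ``dummy_b``
    (zero leaves the forward intensity unchanged).
    """
    if grid_spacing <= 0:
        raise StructureError("grid_spacing must be positive")
    if shell_distance < 0:
        raise StructureError("shell_distance must be non-negative")
    prot = structure.coords[structure.is_protein]
    if len(prot) == 0:
        raise StructureError("no protein centers to hydrate")
    pad = shell_distance + 2 * grid_spacing
    lo = prot.min(axis=0) - pad
    hi = prot.max(axis=0) + pad
    axes = [np.arange(lo[k], hi[k] + grid_spacing, grid_spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d, _ = cKDTree(prot).query(grid, workers=-1)
    keep = (d >= shell_distance) & (d < shell_distance + grid_spacing)
    shell = grid[keep]
    if len(shell) == 0:
        return structure
    n = len(shell)
    return CoarseStructure(
        np.concatenate([structure.coords, shell]),
        np.concatenate([structure.b, np.full(n, float(dummy_b))]),
        np.concatenate([structure.kind, np.full(n, KIND_DUMMY, np.uint8)]),
        np.concatenate([structure.chain, np.full(n, "W")]),
        np.concatenate([structure.resnum, np.arange(1, n + 1)]),
        np.concatenate([structure.resname, np.full(n, "DUM")]),
        np.concatenate([structure.atom_name, np.full(n, "DUM")]),
        provenance=(f"{structure.provenance}; "
                    f"+hydration({shell_distance},{grid_spacing},{dummy_b})"),
    )


# ---------------------------------------------------------------------------
# rigid bodies, restraints, symmetry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BodySpec:
    """One rigid body: a chain and an inclusive residue range (``first``/
    ``last`` of ``None`` select the whole chain)."""
    label: str
    chain: str
    first: int | None = None
    last: int | None = None


@dataclass(frozen=True)
class DistanceRestraint:
    """Harmonic distance restraint between two residue anchors.

    Anchors name (chain, residue number[, residue name]); the representative
    center is the CA atom of that residue.  The target distance is measured
    in the reference structure at setup unless given explicitly.
    """
    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    name_a: str = ""
    name_b: str = ""
    weight: float = 1.0
    target_distance: float | None = None

    def __post_init__(self):
        if self.weight < 0:
            raise StructureError("restraint weight must be >= 0")
        if self.target_distance is not None and self.target_distance <= 0:
            raise StructureError("restraint target distance must be positive")


@dataclass
class BodyScheme:
    """Rigid-body partition plus symmetry and restraints."""
    bodies: list[BodySpec]
    symmetry: str = "none"          # "none" | "C2"
    restraints: list[DistanceRestraint] = field(default_factory=list)

    @classmethod
    def from_dict(cls, cfg: dict) -> "BodyScheme":
        bodies = [BodySpec(b["label"], str(b["chain"]), b.get("first"), b.get("last"))
                  for b in cfg["bodies"]]
        restraints = [
            DistanceRestraint(
                str(r["chain_a"]), int(r["res_a"]), str(r["chain_b"]), int(r["res_b"]),
                r.get("name_a", ""), r.get("name_b", ""), float(r.get("weight", 1.0)),
            )
            for r in cfg.get("restraints", [])
        ]
        return cls(bodies, cfg.get("symmetry", "none"), restraints)

    @classmethod
    def from_yaml(cls, text: str) -> "BodyScheme":
        return cls.from_dict(yaml.safe_load(text))


def load_default_scheme() -> BodyScheme:
    """The packaged HipBST scheme: three bodies for HipB (1-31, 32-43,
    44-107), one for HipS, three for HipT (2-59, 60-169, 170-331), C2
    symmetry, and the six inter-domain distance restraints."""
    text = importlib.resources.files("hipsaxs").joinpath(
        "data/hipbst_scheme.yaml").read_text()
    return BodyScheme.from_yaml(text)


def partition_bodies(structure: CoarseStructure, scheme: BodyScheme) -> dict[str, np.ndarray]:
    """Resolve a body scheme against a structure.

    Returns ``{label: index array}`` covering every protein center of the
    scheme's chains exactly once.  Residues outside all ranges of their
    chain are assigned to the nearest-in-sequence body (with a warning);
    overlapping ranges or empty bodies are errors.
    """
    prot_idx = np.flatnonzero(structure.is_protein)
    out: dict[str, list[int]] = {b.label: [] for b in scheme.bodies}
    by_chain: dict[str, list[BodySpec]] = {}
    for b in scheme.bodies:
        by_chain.setdefault(b.chain, []).append(b)
    # overlap check within each chain
    for ch, specs in by_chain.items():
        ranges = []
        for s in specs:
            ranges.append((s.first if s.first is not None else -10**9,
                           s.last if s.last is not None else 10**9, s.label))
        ranges.sort()
        for (a1, b1, l1), (a2, b2, l2) in zip(ranges, ranges[1:]):
            if a2 <= b1:
                raise StructureError(f"overlapping body ranges {l1!r} and {l2!r} in chain {ch}")
    n_orphans = 0
    for i in prot_idx:
        ch = str(structure.chain[i])
        if ch not in by_chain:
            continue
        rn = int(structure.resnum[i])
        hit = None
        for s in by_chain[ch]:
            lo = s.first if s.first is not None else rn
            hi = s.last if s.last is not None else rn
            if lo <= rn <= hi:
                hit = s
                break
        if hit is None:
            # nearest-in-sequence body of the same chain
            def seq_dist(s: BodySpec) -> int:
                lo = s.first if s.first is not None else rn
                hi = s.last if s.last is not None else rn
                return min(abs(rn - lo), abs(rn - hi))
            hit = min(by_chain[ch], key=seq_dist)
            n_orphans += 1
        out[hit.label].append(int(i))
    if n_orphans:
        logger.warning("partition_bodies: %d residues outside all ranges were "
                       "assigned to the nearest-in-sequence body", n_orphans)
    result = {}
    for label, idx in out.items():
        if not idx:
            raise StructureError(f"body {label!r} selects no centers")
        result[label] = np.array(idx, dtype=np.int64)
    return result


@dataclass
class BodyState:
    """Per-body rigid transforms of the asymmetric half.

    Rotations are axis-angle rotation vectors (radians) applied about each
    body's reference centroid, followed by a translation in Angstrom.  The
    symmetry mate is regenerated from the transformed half, never moved
    independently.  The all-zero state reproduces the input bit-exactly.
    """
    rotvecs: np.ndarray       # (n_bodies, 3)
    translations: np.ndarray  # (n_bodies, 3)

    @classmethod
    def identity(cls, n_bodies: int) -> "BodyState":
        return cls(np.zeros((n_bodies, 3)), np.zeros((n_bodies, 3)))

    @property
    def n_bodies(self) -> int:
        return len(self.rotvecs)

    def copy(self) -> "BodyState":
        return BodyState(self.rotvecs.copy(), self.translations.copy())


def apply_body_state(
    coords: np.ndarray,
    bodies: dict[str, np.ndarray],
    state: BodyState,
    centroids: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Apply per-body rigid transforms to reference coordinates.

    ``centroids`` are the rotation pivots (reference body centroids by
    default).  Bodies with a zero transform are passed through untouched so
    the identity state is bit-exact.
    """
    out = coords.copy()
    for k, (label, idx) in enumerate(bodies.items()):
        rv = state.rotvecs[k]
        tr = state.translations[k]
        if not rv.any() and not tr.any():
            continue
        pivot = (centroids[label] if centroids is not None
                 else coords[idx].mean(axis=0))
        out[idx] = Rotation.from_rotvec(rv).apply(coords[idx] - pivot) + pivot + tr
    return out


def _next_free_chain(used: set[str]) -> str:
    for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789":
        if c not in used:
            used.add(c)
            return c
    raise StructureError("ran out of chain identifiers for the symmetry mate")


def c2_matrix(axis_direction) -> np.ndarray:
    """Rotation matrix for a 180-degree turn about ``axis_direction``."""
    n = np.asarray(axis_direction, dtype=float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise StructureError("C2 axis direction must be non-zero")
    n = n / nn
    return 2.0 * np.outer(n, n) - np.eye(3)


def c2_image_coords(coords: np.ndarray, axis_point, axis_direction) -> np.ndarray:
    """Coordinates rotated 180 degrees about the given axis."""
    p0 = np.asarray(axis_point, dtype=float)
    return (coords - p0) @ c2_matrix(axis_direction).T + p0


def apply_c2(
    half_structure: CoarseStructure,
    axis_point=(0.0, 0.0, 0.0),
    axis_direction=(0.0, 0.0, 1.0),
    chain_map: dict[str, str] | None = None,
) -> CoarseStructure:
    """Complete a C2-symmetric assembly from its asymmetric half.

    The returned structure is the half followed by its 180-degree image
    about the axis.  Mate chains are renamed via ``chain_map`` (HipBST
    convention A->E, B->D, C->F by default; unmapped chains get the next
    free identifier).
    """
    img = c2_image_coords(half_structure.coords, axis_point, axis_direction)
    cmap = dict(HIPBST_CHAIN_MAP if chain_map is None else chain_map)
    used = set(half_structure.chains()) | set(cmap.values())
    for ch in half_structure.chains():
        if ch not in cmap:
            cmap[ch] = _next_free_chain(used)
    mate_chain = np.array([cmap[str(c)] for c in half_structure.chain], dtype="U4")
    mate = CoarseStructure(
        img, half_structure.b.copy(), half_structure.kind.copy(), mate_chain,
        half_structure.resnum.copy(), half_structure.resname.copy(),
        half_structure.atom_name.copy(), provenance="C2 mate",
    )
    return concat_structures(half_structure, mate,
                             provenance=f"{half_structure.provenance}; C2")


def fit_c2_axis(full_structure: CoarseStructure, chain_map: dict[str, str] | None = None):
    """Least-squares C2 axis of an assembled symmetric structure.

    Pairs each chain with its mate via ``chain_map`` (HipBST convention by
    default), fits the proper rotation carrying the half onto the mate
    (Kabsch), and returns ``(axis_point, axis_direction)``.  The axis point
    is the overall centroid projected onto the rotation axis; for an exact
    C2 structure the returned operation reproduces the mate to rounding.
    """
    cmap = dict(HIPBST_CHAIN_MAP if chain_map is None else chain_map)
    half_mask = np.isin(full_structure.chain, list(cmap.keys()))
    mate_mask = np.isin(full_structure.chain, list(cmap.values()))
    if not half_mask.any() or not mate_mask.any():
        raise StructureError("chain map does not match the structure")
    a = full_structure.coords[half_mask]
    bb = full_structure.coords[mate_mask]
    if len(a) != len(bb):
        raise StructureError("half and mate have different center counts")
    ca, cb = a.mean(axis=0), bb.mean(axis=0)
    rot, _ = Rotation.align_vectors(bb - cb, a - ca)
    rv = rot.as_rotvec()
    ang = np.linalg.norm(rv)
    axis = rv / ang if ang > 0 else np.array([0.0, 0.0, 1.0])
    centroid = full_structure.coords.mean(axis=0)
    # fixed point: solve (I - R) p = cb - R @ ca in the plane normal to axis
    rmat = rot.as_matrix()
    lhs = np.eye(3) - rmat
    rhs = cb - rmat @ ca
    p, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
    # pin the free component along the axis to the centroid
    p = p + axis * np.dot(centroid - p, axis)
    return p, axis


# ---------------------------------------------------------------------------
# geometric measures
# ---------------------------------------------------------------------------

def max_diameter(structure: CoarseStructure, include_dummies: bool = False) -> float:
    """Maximum pairwise center distance (Angstrom); hydration dummies are
    excluded by default."""
    pts = structure.coords if include_dummies else structure.coords[structure.is_protein]
    if len(pts) < 2:
        raise StructureError("max_diameter needs at least two centers")
    if len(pts) > 50:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    return float(pdist(pts).max())


def model_rg(structure: CoarseStructure) -> float:
    """Scattering-length-weighted radius of gyration (Angstrom)."""
    w = structure.b
    tot = w.sum()
    if tot <= 0:
        raise StructureError("total scattering length must be positive")
    cm = (w[:, None] * structure.coords).sum(axis=0) / tot
    d2 = ((structure.coords - cm) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / tot))
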