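"""Structure handling: parsing, coarse-graining, symmetry, geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import hipsaxs as h
from hipsaxs.structure_model import (
    HELIX_RISE,
    StructureError,
    c2_image_coords,
    load_default_scheme,
)
from hipsaxs.synthetic_data import sphere_cloud

from conftest import bead_structure

_AA3 = {"A": "ALA", "G": "GLY"}


def make_pdb(residues, chain="A"):
    """Minimal PDB text: residues is a list of (resname, [(atom, x, y, z)])."""
    lines = []
    serial = 1
    for i, (resname, atoms) in enumerate(residues, start=1):
        for name, x, y, z in atoms:
            pad = f" {name:<3s}" if len(name) < 4 else name
            element = name.strip()[0]
            lines.append(
                f"ATOM  {serial:5d} {pad} {resname:>3s} {chain}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
            )
            serial += 1
    return "\n".join(lines) + "\nEND\n"


def poly_ala_pdb(n_res=10, chain="A"):
    """Ideal-ish poly-Ala trace: 5 non-hydrogen atoms per residue."""
    residues = []
    for i in range(n_res):
        base = np.array([3.8 * i, 0.0, 0.0])
        atoms = [("N", *(base + [0.0, 0.5, 0.0])),
                 ("CA", *(base + [0.8, 1.2, 0.3])),
                 ("C", *(base + [1.9, 0.9, 0.1])),
                 ("O", *(base + [2.2, 0.2, 1.0])),
                 ("CB", *(base + [0.9, 2.4, -0.6]))]
        residues.append(("ALA", atoms))
    return make_pdb(residues, chain)


class TestReadStructure:
    def test_hydrogens_excluded(self):
        text = make_pdb([("ALA", [("C", 0, 0, 0), ("CA", 1, 0, 0), ("H", 2, 0, 0)])])
        st = h.read_structure(text)
        assert st.n_centers == 2
        assert set(st.atom_name) == {"C", "CA"}

    def test_poly_ala_center_count(self):
        st = h.read_structure(poly_ala_pdb(10))
        assert st.n_centers == 50
        assert np.all(st.b == 1.0)
        assert list(np.unique(st.resnum)) == list(range(1, 11))

    def test_waters_excluded(self):
        text = make_pdb([("ALA", [("CA", 0, 0, 0)]), ("HOH", [("O", 9, 9, 9)])])
        assert h.read_structure(text).n_centers == 1

    def test_empty_input_raises(self):
        with pytest.raises(StructureError):
            h.read_structure("REMARK nothing here\n")

    def test_mmcif_ingestion(self, hexamer_half):
        import gemmi
        st = gemmi.read_pdb_string(h.write_pdb(hexamer_half))
        st.setup_entities()
        cif_text = st.make_mmcif_document().as_string()
        back = h.read_structure(cif_text)
        assert back.n_centers == hexamer_half.n_centers

    def test_roundtrip_preserves_coordinates(self, hexamer_half):
        text = h.write_pdb(hexamer_half)
        back = h.read_structure(text)
        assert back.n_centers == hexamer_half.n_centers
        # PDB format carries 3 decimals
        assert np.allclose(back.coords, hexamer_half.coords, atol=5.1e-4)
        assert list(back.chain) == list(hexamer_half.chain)


class TestOmitChains:
    def test_removes_exact_count(self, hexamer_full):
        n_hips = int(np.sum(np.isin(hexamer_full.chain, ["B", "D"])))
        trimmed = h.omit_chains(hexamer_full, {"B", "D"})
        assert trimmed.n_centers == hexamer_full.n_centers - n_hips
        assert not set(trimmed.chains()) & {"B", "D"}

    def test_empty_set_is_identity(self, hexamer_full):
        same = h.omit_chains(hexamer_full, set())
        assert np.array_equal(same.coords, hexamer_full.coords)

    def test_omit_everything_raises(self, hexamer_half):
        with pytest.raises(StructureError):
            h.omit_chains(hexamer_half, set(hexamer_half.chains()))

    def test_unknown_chain_lists_available(self, hexamer_half):
        with pytest.raises(StructureError, match="available"):
            h.omit_chains(hexamer_half, {"Z"})

    def test_omit_then_concat_restores_multiset(self, hexamer_full):
        kept = h.omit_chains(hexamer_full, {"B"})
        removed = hexamer_full.select(hexamer_full.chain == "B")
        merged = h.concat_structures(kept, removed)
        assert sorted(map(tuple, merged.coords.tolist())) == \
            sorted(map(tuple, hexamer_full.coords.tolist()))


class TestHelixStandin:
    def test_single_residue_anchored(self):
        frag = h.build_helix_standin("A", attach_point=(5.0, -2.0, 1.0))
        assert np.allclose(frag.coords[0], [5.0, -2.0, 1.0], atol=1e-12)
        assert len(np.unique(frag.resnum)) == 1

    def test_35_residue_length(self):
        frag = h.build_helix_standin("A" * 35, direction=(0, 0, 1))
        ca = frag.coords[frag.atom_name == "CA"]
        length = np.linalg.norm(ca[-1] - ca[0])
        assert abs(length - 34 * HELIX_RISE) < 1.0

    def test_direction_reversal_mirrors_axis_projection(self):
        up = h.build_helix_standin("AAAA", direction=(0, 0, 1))
        down = h.build_helix_standin("AAAA", direction=(0, 0, -1))
        pu = up.coords[:, 2] - up.coords[0, 2]
        pd = down.coords[:, 2] - down.coords[0, 2]
        assert np.allclose(pu, -pd, atol=1e-9)

    def test_invalid_letter_raises(self):
        with pytest.raises(StructureError, match="invalid"):
            h.build_helix_standin("AXB?")

    def test_glycine_has_no_cb(self):
        frag = h.build_helix_standin("GAG")
        assert np.sum(frag.atom_name == "CB") == 1


class TestHydrationLayer:
    def test_zero_contrast_leaves_intensity_unchanged(self, sphere_points):
        q = np.geomspace(0.01, 0.3, 30)
        bare = h.form_factor_debye(sphere_points, q)
        wet = h.add_hydration_layer(sphere_points, dummy_b=0.0)
        assert wet.n_centers > sphere_points.n_centers
        hydrated = h.form_factor_debye(wet, q)
        assert np.max(np.abs(hydrated - bare) / bare) < 1e-12

    def test_single_atom_shell_distances(self):
        st = bead_structure([[0.0, 0.0, 0.0]])
        wet = h.add_hydration_layer(st, shell_distance=3.0, grid_spacing=3.5)
        shell = wet.coords[~wet.is_protein]
        d = np.linalg.norm(shell, axis=1)
        assert len(shell) > 0
        assert d.min() >= 3.0
        assert d.max() < 3.0 + 3.5

    def test_globule_dummy_count_matches_shell_area(self):
        radius, shell, spacing = 20.0, 3.0, 3.5
        st = bead_structure(sphere_cloud(500, radius, seed=4))
        wet = h.add_hydration_layer(st, shell_distance=shell, grid_spacing=spacing)
        n_dummy = int(np.sum(~wet.is_protein))
        # one-layer shell of thickness `spacing` around radius R + shell:
        # expected count ~ 4 pi (R + shell)^2 / spacing^2.  A random bead
        # surface is rough, so allow a generous band.
        expected = 4 * np.pi * (radius + shell) ** 2 / spacing**2
        assert 0.5 * expected < n_dummy < 2.0 * expected

    def test_negative_spacing_raises(self, sphere_points):
        with pytest.raises(StructureError):
            h.add_hydration_layer(sphere_points, grid_spacing=-1.0)


class TestPartitionBodies:
    def test_default_scheme_gives_seven_bodies(self, hexamer_half):
        bodies = h.partition_bodies(hexamer_half, load_default_scheme())
        assert len(bodies) == 7
        n_assigned = sum(len(v) for v in bodies.values())
        assert n_assigned == hexamer_half.n_centers
        flat = np.concatenate(list(bodies.values()))
        assert len(np.unique(flat)) == len(flat)

    def test_whole_chain_body(self, hexamer_half):
        scheme = h.BodyScheme([h.BodySpec("all_hipS", "B")])
        bodies = h.partition_bodies(hexamer_half, scheme)
        assert len(bodies["all_hipS"]) == int(np.sum(hexamer_half.chain == "B"))

    def test_overlapping_ranges_raise(self, hexamer_half):
        scheme = h.BodyScheme([h.BodySpec("x", "B", 1, 60),
                               h.BodySpec("y", "B", 50, 102)])
        with pytest.raises(StructureError, match="overlap"):
            h.partition_bodies(hexamer_half, scheme)

    def test_empty_body_raises(self, hexamer_half):
        scheme = h.BodyScheme([h.BodySpec("x", "B", 1, 102),
                               h.BodySpec("ghost", "B", 500, 600)])
        with pytest.raises(StructureError):
            h.partition_bodies(hexamer_half, scheme)


class TestC2:
    def test_point_on_axis_is_fixed(self):
        pts = np.array([[0.0, 0.0, 5.0], [3.0, 1.0, 0.0]])
        img = c2_image_coords(pts, (0, 0, 0), (0, 0, 1))
        assert np.allclose(img[0], pts[0], atol=1e-12)

    def test_double_application_is_identity(self, hexamer_half):
        once = c2_image_coords(hexamer_half.coords, (1.0, 2.0, 3.0), (1.0, 1.0, 0.5))
        twice = c2_image_coords(once, (1.0, 2.0, 3.0), (1.0, 1.0, 0.5))
        assert np.max(np.abs(twice - hexamer_half.coords)) < 1e-9

    def test_assembly_is_c2_invariant(self, hexamer_full):
        img = c2_image_coords(hexamer_full.coords, (0, 0, 0), (0, 0, 1))
        a = np.sort(np.round(hexamer_full.coords, 6).view([('', float)] * 3), axis=0)
        b = np.sort(np.round(img, 6).view([('', float)] * 3), axis=0)
        assert np.array_equal(a, b)

    def test_center_count_doubles_and_rg_grows(self, hexamer_half, hexamer_full):
        assert hexamer_full.n_centers == 2 * hexamer_half.n_centers
        assert h.model_rg(hexamer_full) >= h.model_rg(hexamer_half)

    def test_fit_c2_axis_recovers_axis(self, hexamer_full):
        point, axis = h.fit_c2_axis(hexamer_full)
        assert abs(abs(axis[2]) - 1.0) < 1e-6
        assert np.linalg.norm(point[:2]) < 1e-6


class TestGeometry:
    def test_two_points(self):
        st = bead_structure([[0, 0, 0], [10, 0, 0]])
        assert h.max_diameter(st) == pytest.approx(10.0)

    def test_random_sphere_bound(self):
        st = bead_structure(sphere_cloud(1000, 30.0, seed=2))
        d = h.max_diameter(st)
        assert 58.0 <= d <= 60.0

    def test_diameter_rigid_invariance(self, hexamer_half):
        d0 = h.max_diameter(hexamer_half)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        moved = hexamer_half.with_coords(rot.apply(hexamer_half.coords) + [5, 6, 7])
        assert abs(h.max_diameter(moved) - d0) < 1e-9

    def test_single_center_diameter_raises(self):
        with pytest.raises(StructureError):
            h.max_diameter(bead_structure([[0, 0, 0]]))

    def test_rg_single_center_and_dumbbell(self):
        assert h.model_rg(bead_structure([[1, 2, 3]])) == 0.0
        st = bead_structure([[-7.0, 0, 0], [7.0, 0, 0]])
        assert h.model_rg(st) == pytest.approx(7.0)

    def test_rg_uniform_sphere(self, sphere_quadrature):
        expected = np.sqrt(3.0 / 5.0) * 30.0
        assert h.model_rg(sphere_quadrature) == pytest.approx(expected, rel=0.01)

    def test_rg_rigid_invariance_and_scaling(self, hexamer_half):
        rg0 = h.model_rg(hexamer_half)
        rot = Rotation.from_rotvec([1.0, 0.2, -0.4])
        moved = hexamer_half.with_coords(rot.apply(hexamer_half.coords) - [9, 0, 4])
        assert abs(h.model_rg(moved) - rg0) < 1e-9
        scaled = hexamer_half.with_coords(2.5 * hexamer_half.coords)
        assert h.model_rg(scaled) == pytest.approx(2.5 * rg0, rel=1e-12)


class TestBodyState:
    def test_identity_is_bit_exact(self, hexamer_half):
        from hipsaxs.structure_model import apply_body_state
        bodies = h.partition_bodies(hexamer_half, load_default_scheme())
        state = h.BodyState.identity(len(bodies))
        out = apply_body_state(hexamer_half.coords, bodies, state)
        assert np.array_equal(out, hexamer_half.coords)

    def test_synthetic_hexamer_diameter_matches_crystal_scale(self, hexamer_full):
        # generator design target: the stand-in reproduces the ~135 A
        # maximum diameter of the crystallographic heterohexamer
        assert h.max_diameter(hexamer_full) == pytest.approx(135.0, abs=5.0)
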