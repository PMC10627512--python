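"""Fit statistics, restraints, excluded volume, and the refinement engine."""

import numpy as np
import pytest

import hipsaxs as h
from hipsaxs.refine import FitConfig, RefineError, RefinementContext, _polish
from hipsaxs.structure_model import (
    StructureError,
    apply_body_state,
    load_default_scheme,
    partition_bodies,
)
from hipsaxs.synthetic_data import recovery_suite, ScenarioSpec

from conftest import bead_structure


def flat_curve(n=50, value=1.0, sigma=0.1):
    q = np.linspace(0.01, 0.3, n)
    return h.SAXSCurve(q, np.full(n, value), np.full(n, sigma))


class TestChi2:
    def test_perfect_model_scores_zero(self):
        c = flat_curve()
        res = h.chi2_reduced(c.I.copy(), c, n_free_params=1)
        assert res.value == pytest.approx(0.0, abs=1e-25)
        assert res.scale == pytest.approx(1.0)

    def test_scale_is_profiled_out(self):
        c = flat_curve(value=2.0)
        res = h.chi2_reduced(c.I / 2.0, c, n_free_params=1)
        assert res.scale == pytest.approx(2.0)
        assert res.value == pytest.approx(0.0, abs=1e-25)

    def test_unit_noise_gives_chi2_near_one(self):
        rng = np.random.default_rng(3)
        n = 200
        q = np.linspace(0.01, 0.3, n)
        model = 10.0 + q * 0.0
        data = model + rng.standard_normal(n)
        curve = h.SAXSCurve(q, data, np.ones(n))
        res = h.chi2_reduced(model, curve, n_free_params=1)
        assert res.value == pytest.approx(1.0, abs=0.2)

    def test_too_few_points_raises(self):
        c = flat_curve(n=5)
        with pytest.raises(RefineError):
            h.chi2_reduced(c.I, c, n_free_params=5)


class TestRestraints:
    def test_unperturbed_reference_scores_zero(self, hexamer_full):
        scheme = load_default_scheme()
        assert h.restraint_penalty(hexamer_full, scheme.restraints) == 0.0

    def test_quadratic_displacement(self):
        ref = bead_structure([[0.0, 0, 0], [10.0, 0, 0]])
        restraints = [h.DistanceRestraint("A", 1, "A", 2, weight=1.0)]
        rs = h.RestraintSet(ref, restraints)
        moved = ref.coords.copy()
        moved[1, 0] += 2.0   # displaced along the inter-anchor axis
        assert rs.penalty(moved) == pytest.approx(4.0)

    def test_named_interdomain_anchors_resolve_on_hexamer(self, hexamer_full):
        scheme = load_default_scheme()
        named = [r for r in scheme.restraints if r.name_a]
        assert len(named) == 6
        rs = h.RestraintSet(hexamer_full, named)
        assert len(rs.targets) == 6
        assert np.all(rs.targets > 0)

    def test_unresolvable_anchor_raises(self, hexamer_full):
        bad = [h.DistanceRestraint("A", 9999, "B", 1)]
        with pytest.raises(StructureError, match="A9999"):
            h.RestraintSet(hexamer_full, bad)


class TestExcludedVolume:
    def test_separated_bodies_score_zero(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        ids = np.array([0, 1])
        assert h.excluded_volume_penalty(coords, ids, cutoff=4.0) == 0.0

    def test_two_centers_at_two_angstrom(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        ids = np.array([0, 1])
        assert h.excluded_volume_penalty(coords, ids, cutoff=4.0,
                                         weight=1.0) == pytest.approx(4.0)

    def test_intra_body_contacts_ignored(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        ids = np.array([0, 0])
        assert h.excluded_volume_penalty(coords, ids, cutoff=4.0) == 0.0

    def test_continuity_at_cutoff(self):
        ids = np.array([0, 1])
        vals = []
        for d in (3.999, 4.0, 4.001):
            coords = np.array([[0.0, 0, 0], [d, 0, 0]])
            vals.append(h.excluded_volume_penalty(coords, ids, cutoff=4.0, weight=1.0))
        assert vals[0] < 1e-5
        assert vals[1] == 0.0
        assert vals[2] == 0.0

    def test_monotone_in_overlap(self):
        ids = np.array([0, 1])
        pen = [h.excluded_volume_penalty(
            np.array([[0.0, 0, 0], [d, 0, 0]]), ids, cutoff=4.0, weight=1.0)
            for d in np.linspace(3.5, 0.5, 7)]
        assert all(b > a for a, b in zip(pen, pen[1:]))


@pytest.fixture(scope="module")
def small_bundle():
    """Paper-anchor scenario with an exactly-reproducible forward path
    (histogram Debye on both sides) and no noise."""
    spec = ScenarioSpec()
    bundle = recovery_suite(spec)
    noiseless = h.simulate_curve(
        bundle.truth_full, bundle.oligomer,
        h.NoiseModel(rel_sigma=0.0, floor_fraction=1e-4, seed=0),
        use_histogram=True)
    return bundle, noiseless


class TestObjective:
    def test_truth_state_scores_zero_on_self_simulated_data(self, small_bundle):
        bundle, curve = small_bundle
        ctx = RefinementContext(bundle.truth_half, bundle.scheme, curve,
                                FitConfig(), (0, 0, 0), (0, 0, 1), None)
        obj, fit, rp, ev = ctx.evaluate(bundle.truth_state, bundle.oligomer)
        assert obj < 1e-6
        assert rp == 0.0 and ev == 0.0

    def test_objective_dominates_chi2(self, small_bundle):
        bundle, curve = small_bundle
        ctx = RefinementContext(bundle.truth_half, bundle.scheme, curve,
                                FitConfig(), (0, 0, 0), (0, 0, 1), None)
        obj, fit, rp, ev = ctx.evaluate(bundle.start_state, bundle.oligomer)
        assert obj >= fit.value
        assert obj == pytest.approx(fit.value + rp + ev)

    def test_every_model_is_exactly_c2(self, small_bundle):
        from hipsaxs.structure_model import c2_image_coords
        bundle, curve = small_bundle
        ctx = RefinementContext(bundle.truth_half, bundle.scheme, curve,
                                FitConfig(), (0, 0, 0), (0, 0, 1), None)
        coords = ctx.full_coords(bundle.start_state)
        img = c2_image_coords(coords, (0, 0, 0), (0, 0, 1))
        n = len(coords) // 2
        assert np.max(np.abs(img[:n] - coords[n:])) < 1e-9
        assert np.max(np.abs(img[n:] - coords[:n])) < 1e-9


class TestRefineRigidBody:
    def test_start_at_truth_stays_at_truth(self, small_bundle):
        bundle, curve = small_bundle
        cfg = FitConfig(n_runs=1, seed=3, n_iterations=40, polish_maxfev=200,
                        polish_sweeps=0)
        res = h.refine_rigid_body(bundle.truth_half, bundle.scheme, curve, cfg,
                                  start_state=bundle.truth_state,
                                  start_oligomer=bundle.oligomer)
        assert res.chi2_reduced < 1e-6
        bodies = partition_bodies(bundle.truth_half, bundle.scheme)
        moved = apply_body_state(bundle.truth_half.coords, bodies, res.best_state)
        disp = np.linalg.norm(moved - bundle.truth_half.coords, axis=1)
        assert disp.max() < 0.1

    def test_determinism_bit_identical(self, small_bundle):
        bundle, curve = small_bundle
        cfg = FitConfig(n_runs=2, seed=9, n_iterations=30, polish_maxfev=100,
                        polish_sweeps=0)
        r1 = h.refine_rigid_body(bundle.truth_half, bundle.scheme, curve, cfg,
                                 start_state=bundle.start_state)
        r2 = h.refine_rigid_body(bundle.truth_half, bundle.scheme, curve, cfg,
                                 start_state=bundle.start_state)
        assert r1.chi2_reduced == r2.chi2_reduced
        assert np.array_equal(r1.best_state.rotvecs, r2.best_state.rotvecs)
        assert np.array_equal(r1.best_state.translations, r2.best_state.translations)
        assert r1.oligomer == r2.oligomer
        assert [s.chi2_reduced for s in r1.runs] == [s.chi2_reduced for s in r2.runs]

    def test_best_of_n_is_the_run_minimum(self, small_bundle):
        bundle, curve = small_bundle
        cfg = FitConfig(n_runs=3, seed=5, n_iterations=30, polish_maxfev=0)
        res = h.refine_rigid_body(bundle.truth_half, bundle.scheme, curve, cfg,
                                  start_state=bundle.start_state)
        assert res.chi2_reduced == min(s.chi2_reduced for s in res.runs)

    def test_wrong_start_state_size_raises(self, small_bundle):
        bundle, curve = small_bundle
        with pytest.raises(RefineError):
            h.refine_rigid_body(bundle.truth_half, bundle.scheme, curve,
                                FitConfig(n_runs=1, n_iterations=5),
                                start_state=h.BodyState.identity(3))
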