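"""Restrained rigid-body refinement against a solution scattering curve.

The model is a C2-symmetric assembly: rigid bodies of the asymmetric half
(e.g. three bodies for HipB, one for HipS, three for HipT) move under
rotations/translations while the symmetry mate is regenerated from the half
at every evaluation, so all intermediate models are exactly two-fold
symmetric.  The oligomerization parameters N and D of the structure factor
are refined simultaneously with the body transforms.

The objective combines three terms: the error-weighted reduced chi^2 of the
model intensity against the data (with the overall scale profiled out in
closed form), harmonic distance restraints between residue anchors at the
domain boundaries, and a soft excluded-volume penalty between bodies.  The
search is simulated annealing with Gaussian rigid-body proposals; several
independent seeded runs are performed and the run with the lowest reduced
chi^2 is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .primary_analysis import SAXSCurve
from .scattering import (
    DEFAULT_SIGMA_SMEAR,
    OligomerModel,
    amplitude_cm,
    histogram_debye,
    structure_factor,
)
from .structure_model import (
    BodyScheme,
    BodyState,
    CoarseStructure,
    DistanceRestraint,
    StructureError,
    apply_body_state,
    apply_c2,
    c2_image_coords,
    partition_bodies,
)


class RefineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chi2Result:
    value: float   # reduced chi^2
    scale: float   # analytic optimal scale s*


def chi2_reduced(model_I, curve: SAXSCurve, n_free_params: int) -> Chi2Result:
    """Reduced chi^2 with the overall scale profiled out analytically:
    s* = sum(Im Ie / s^2) / sum(Im^2 / s^2),
    chi2_red = sum(((s* Im - Ie)/s)^2) / (n_points - n_free_params)."""
    im = np.asarray(model_I, dtype=float)
    if im.shape != curve.q.shape:
        raise RefineError("model intensity and curve grids are not aligned")
    dof = curve.n_points - n_free_params
    if dof <= 0:
        raise RefineError("not enough data points for the free parameters")
    w = 1.0 / curve.sigma**2
    denom = np.sum(w * im * im)
    if denom == 0:
        raise RefineError("model intensity is identically zero")
    scale = float(np.sum(w * im * curve.I) / denom)
    chi2 = float(np.sum(w * (scale * im - curve.I) ** 2))
    return Chi2Result(value=chi2 / dof, scale=scale)


# ---------------------------------------------------------------------------
# restraints
# ---------------------------------------------------------------------------

class RestraintSet:
    """Distance restraints resolved against a reference structure.

    Each anchor resolves to the CA center of the named (chain, residue);
    target distances default to the values measured in the reference, so
    the unperturbed structure has zero penalty.
    """

    def __init__(self, reference: CoarseStructure,
                 restraints: list[DistanceRestraint]):
        self.idx_a = np.empty(len(restraints), np.int64)
        self.idx_b = np.empty(len(restraints), np.int64)
        self.weights = np.array([r.weight for r in restraints], dtype=float)
        self.restraints = list(restraints)
        for k, r in enumerate(restraints):
            self.idx_a[k] = self._resolve(reference, r.chain_a, r.res_a)
            self.idx_b[k] = self._resolve(reference, r.chain_b, r.res_b)
        d_ref = np.linalg.norm(
            reference.coords[self.idx_a] - reference.coords[self.idx_b], axis=1)
        self.targets = np.array(
            [r.target_distance if r.target_distance is not None else d_ref[k]
             for k, r in enumerate(restraints)])

    @staticmethod
    def _resolve(structure: CoarseStructure, chain: str, resnum: int) -> int:
        mask = ((structure.chain == chain) & (structure.resnum == resnum)
                & structure.is_protein)
        idx = np.flatnonzero(mask & (structure.atom_name == "CA"))
        if len(idx) == 0:           # bead models may carry a single center
            idx = np.flatnonzero(mask)
        if len(idx) != 1:
            raise StructureError(
                f"restraint anchor {chain}{resnum} resolves to {len(idx)} centers")
        return int(idx[0])

    def penalty(self, coords: np.ndarray) -> float:
        """sum_i w_i (d_i - d_i,target)^2 over anchor pairs."""
        d = np.linalg.norm(coords[self.idx_a] - coords[self.idx_b], axis=1)
        return float(np.sum(self.weights * (d - self.targets) ** 2))


def restraint_penalty(structure: CoarseStructure,
                      restraints: list[DistanceRestraint],
                      reference: CoarseStructure | None = None) -> float:
    """Harmonic restraint penalty of ``structure``; targets come from
    ``reference`` (defaults to ``structure`` itself, giving zero)."""
    rs = RestraintSet(reference if reference is not None else structure, restraints)
    return rs.penalty(structure.coords)


def excluded_volume_penalty(coords: np.ndarray, body_ids: np.ndarray,
                            cutoff: float = 4.0, weight: float = 1.0) -> float:
    """Soft steric penalty: weight * sum over inter-body pairs closer than
    ``cutoff`` of (cutoff - d)^2; intra-body pairs are ignored.  Continuous
    (value and slope zero) at d = cutoff."""
    if cutoff <= 0:
        raise RefineError("cutoff must be positive")
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    inter = body_ids[pairs[:, 0]] != body_ids[pairs[:, 1]]
    if not inter.any():
        return 0.0
    pairs = pairs[inter]
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return float(weight * np.sum((cutoff - d) ** 2))


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Search settings for the multi-start annealing refinement."""
    n_runs: int = 10
    seed: int = 0
    n_iterations: int = 400
    trans_step: float = 2.0          # A, Gaussian proposal sd
    rot_step_deg: float = 5.0        # deg, Gaussian proposal sd
    t_start: float = 2.0             # initial temperature (objective units)
    cooling: float = 0.97            # geometric factor
    cool_interval: int = 10          # iterations between cooling steps
    restraint_weight: float = 10.0   # per A^2
    excl_weight: float = 0.1         # per A^2
    clash_cutoff: float = 4.0        # A
    n_bounds: tuple[float, float] = (1.0, 4.0)
    d_bounds: tuple[float, float] = (20.0, 300.0)
    olig_step: float = 0.05          # lognormal sd for N, D proposals
    p_olig_move: float = 0.2         # probability of an (N, D) move
    p_large_move: float = 0.1        # probability of a basin-hopping body move
    large_factor: float = 4.0        # width multiplier for large moves
    step_floor: float = 0.15         # minimum proposal-width scale
    polish_maxfev: int = 2500        # Powell descent budget per polished run (0 = off)
    polish_sweeps: int = 2           # block-coordinate sweeps after the joint descent
    polish_top_k: int = 2            # how many of the best annealing runs to polish
    bin_width: float = 0.15          # histogram Debye bin, A
    sigma_smear: float = DEFAULT_SIGMA_SMEAR
    refine_oligomer: bool = True
    converge_chi2: float = 5.0       # chi2_red above this flags non-convergence
    hydration_b: float = 0.0         # >0 adds a dummy shell (regenerated lazily)
    hydration_refresh: int = 25      # accepted moves between shell rebuilds

    def __post_init__(self):
        if self.n_runs < 1:
            raise RefineError("n_runs must be >= 1")
        if self.n_bounds[0] > self.n_bounds[1] or self.d_bounds[0] > self.d_bounds[1]:
            raise RefineError("parameter bounds must be ordered")


@dataclass
class RunSummary:
    run: int
    chi2_reduced: float
    objective: float
    accepted: int


@dataclass
class FitResult:
    best_state: BodyState
    oligomer: OligomerModel
    scale: float
    chi2_reduced: float
    restraint_penalty: float
    excluded_volume_penalty: float
    objective: float
    runs: list[RunSummary]
    structure: CoarseStructure       # transformed full (C2) model
    converged: bool
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# the refinement engine
# ---------------------------------------------------------------------------

class RefinementContext:
    """Precomputed quantities shared by all runs."""

    def __init__(self, half: CoarseStructure, scheme: BodyScheme,
                 curve: SAXSCurve, config: FitConfig,
                 axis_point, axis_direction, chain_map):
        self.config = config
        self.curve = curve
        self.axis_point = np.asarray(axis_point, dtype=float)
        self.axis_direction = np.asarray(axis_direction, dtype=float)
        self.chain_map = chain_map
        self.half = half
        self.bodies = partition_bodies(half, scheme)
        self.labels = list(self.bodies)
        self.centroids = {lab: half.coords[idx].mean(axis=0)
                          for lab, idx in self.bodies.items()}
        self.reference_full = apply_c2(half, axis_point, axis_direction, chain_map)
        self.restraints = (RestraintSet(self.reference_full, scheme.restraints)
                           if scheme.restraints else None)
        n_half = half.n_centers
        body_ids = np.empty(n_half, np.int64)
        for k, idx in enumerate(self.bodies.values()):
            body_ids[idx] = k
        self.body_ids_full = np.concatenate([body_ids, body_ids + len(self.bodies)])
        self.b_full = np.concatenate([half.b, half.b])
        self.n_free = 1 + 6 * len(self.bodies) + (2 if config.refine_oligomer else 0)
        # reference anchor pivot per body: centroid of the body's restraint
        # anchors (large proposals rotate about it, approximately preserving
        # restraint distances); bodies without anchors pivot on their centroid
        self.anchor_pivots = {}
        n_half_centers = half.n_centers
        for k, (lab, idx) in enumerate(self.bodies.items()):
            pts = []
            if self.restraints is not None:
                for a in np.concatenate([self.restraints.idx_a,
                                         self.restraints.idx_b]):
                    a_half = a % n_half_centers   # mate anchors map to half
                    if body_ids[a_half] == k:
                        pts.append(half.coords[a_half])
            self.anchor_pivots[k] = (np.mean(pts, axis=0) if pts
                                     else self.centroids[lab])

    def full_coords(self, state: BodyState) -> np.ndarray:
        half = apply_body_state(self.half.coords, self.bodies, state, self.centroids)
        mate = c2_image_coords(half, self.axis_point, self.axis_direction)
        return np.concatenate([half, mate])

    def make_shell(self, coords: np.ndarray) -> CoarseStructure | None:
        """Hydration dummy shell for the given protein coordinates, or None
        when the configured shell contrast is zero."""
        if self.config.hydration_b <= 0:
            return None
        from .structure_model import add_hydration_layer
        hydrated = add_hydration_layer(self.reference_full.with_coords(coords),
                                       dummy_b=self.config.hydration_b)
        return hydrated.select(~hydrated.is_protein)

    def model_intensity(self, coords: np.ndarray, olig: OligomerModel,
                        shell: CoarseStructure | None = None) -> np.ndarray:
        cfg = self.config
        st = self.reference_full.with_coords(coords)
        if cfg.hydration_b > 0:
            if shell is None:
                shell = self.make_shell(coords)
            from .structure_model import concat_structures
            st = concat_structures(st, shell)
        p = histogram_debye(st, self.curve.q, cfg.sigma_smear, cfg.bin_width)
        a2 = amplitude_cm(st, self.curve.q, cfg.sigma_smear) ** 2
        s = structure_factor(olig, self.curve.q)
        return p + a2 * (s - 1.0)

    def evaluate(self, state: BodyState, olig: OligomerModel,
                 shell: CoarseStructure | None = None):
        coords = self.full_coords(state)
        im = self.model_intensity(coords, olig, shell)
        fit = chi2_reduced(im, self.curve, self.n_free)
        rp = (self.restraints.penalty(coords) if self.restraints is not None else 0.0)
        rp *= self.config.restraint_weight
        ev = excluded_volume_penalty(coords, self.body_ids_full,
                                     self.config.clash_cutoff,
                                     self.config.excl_weight)
        return fit.value + rp + ev, fit, rp, ev


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect a proposal back into [lo, hi]."""
    span = hi - lo
    if span <= 0:
        return lo
    t = (x - lo) % (2 * span)
    return lo + (span - abs(t - span))


def _anneal_run(ctx: RefinementContext, run: int, start_state: BodyState,
                start_olig: OligomerModel):
    cfg = ctx.config
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, run])
    state = start_state.copy()
    olig = start_olig
    # hydration shell is rebuilt only every `hydration_refresh` accepted
    # moves (cost control); the returned best state is re-scored exactly.
    shell = ctx.make_shell(ctx.full_coords(state))
    obj, fit, rp, ev = ctx.evaluate(state, olig, shell)
    best = (obj, state.copy(), olig, fit, rp, ev)
    temp = cfg.t_start
    accepted = 0
    n_bodies = state.n_bodies
    for it in range(cfg.n_iterations):
        # proposal widths shrink with temperature (floored) so late-stage
        # moves refine rather than re-randomize
        step = max(cfg.step_floor, np.sqrt(temp / cfg.t_start))
        cand = state.copy()
        cand_olig = olig
        if cfg.refine_oligomer and rng.random() < cfg.p_olig_move:
            width = cfg.olig_step * step
            n_new = _reflect(olig.N * np.exp(width * rng.standard_normal()),
                             *cfg.n_bounds)
            d_new = _reflect(olig.D * np.exp(width * rng.standard_normal()),
                             *cfg.d_bounds)
            cand_olig = OligomerModel(N=n_new, D=d_new)
        elif rng.random() < cfg.p_large_move:
            # basin hop: large rotation about the body's restraint-anchor
            # pivot, which approximately preserves the restraint distances
            k = int(rng.integers(n_bodies))
            lab = ctx.labels[k]
            c = ctx.centroids[lab]
            p0 = ctx.anchor_pivots[k]
            q_rot = Rotation.from_rotvec(cand.rotvecs[k])
            dr = (np.deg2rad(cfg.rot_step_deg) * cfg.large_factor
                  * rng.standard_normal(3))
            big = Rotation.from_rotvec(dr)
            pivot_now = q_rot.apply(p0 - c) + c + cand.translations[k]
            cand.rotvecs[k] = (big * q_rot).as_rotvec()
            cand.translations[k] = (big.apply(c + cand.translations[k] - pivot_now)
                                    + pivot_now - c)
        else:
            k = int(rng.integers(n_bodies))
            dr = np.deg2rad(cfg.rot_step_deg) * step * rng.standard_normal(3)
            new_rot = Rotation.from_rotvec(dr) * Rotation.from_rotvec(cand.rotvecs[k])
            cand.rotvecs[k] = new_rot.as_rotvec()
            cand.translations[k] = (cand.translations[k]
                                    + cfg.trans_step * step * rng.standard_normal(3))
        cand_obj, cand_fit, cand_rp, cand_ev = ctx.evaluate(cand, cand_olig, shell)
        delta = cand_obj - obj
        if delta <= 0 or rng.random() < np.exp(-delta / max(temp, 1e-12)):
            state, olig, obj, fit, rp, ev = cand, cand_olig, cand_obj, cand_fit, cand_rp, cand_ev
            accepted += 1
            if shell is not None and accepted % cfg.hydration_refresh == 0:
                shell = ctx.make_shell(ctx.full_coords(state))
            if cand_obj < best[0]:
                best = (cand_obj, cand.copy(), cand_olig, cand_fit, cand_rp, cand_ev)
        if (it + 1) % cfg.cool_interval == 0:
            temp *= cfg.cooling
    if shell is not None:
        # exact re-score of the best state with a freshly generated shell
        b_state, b_olig = best[1], best[2]
        obj, fit, rp, ev = ctx.evaluate(b_state, b_olig)
        best = (obj, b_state, b_olig, fit, rp, ev)
    return best, accepted


def _polish(ctx: RefinementContext, state: BodyState, olig: OligomerModel,
            maxfev: int, n_sweeps: int = 2):
    """Deterministic local descent from the annealing winner.

    A joint Powell pass over all body transforms (plus N, D) is followed by
    block-coordinate sweeps, one 6-parameter Powell sub-problem per body.
    The block phase matters because each restrained body retains a
    low-dimensional near-isometric motion (distance restraints fix at most
    five independent anchor distances per body); the joint search crawls
    along these curved valleys, while per-body descent traverses them
    directly.
    """
    from scipy.optimize import minimize

    cfg = ctx.config
    nb = state.n_bodies

    def unpack(x):
        st = BodyState(x[:3 * nb].reshape(nb, 3).copy(),
                       x[3 * nb:6 * nb].reshape(nb, 3).copy())
        if cfg.refine_oligomer:
            ol = OligomerModel(
                N=float(np.clip(x[-2], *cfg.n_bounds)),
                D=float(np.clip(x[-1], *cfg.d_bounds)))
        else:
            ol = olig
        return st, ol

    x0 = np.concatenate([state.rotvecs.ravel(), state.translations.ravel(),
                         [olig.N, olig.D] if cfg.refine_oligomer else []])
    res = minimize(lambda x: ctx.evaluate(*unpack(x))[0], x0, method="Powell",
                   options=dict(maxfev=maxfev, xtol=1e-3, ftol=1e-5))
    state, olig = unpack(res.x)

    def body_coords_fn(k):
        def fn(x):
            st = state.copy()
            st.rotvecs[k] = x[:3]
            st.translations[k] = x[3:]
            return ctx.full_coords(st)
        return fn

    def orbit_candidates(k, xk):
        """Points along body k's restraint-preserving valley.

        The distance restraints fix at most rank(J) of the body's six rigid
        degrees of freedom; the remaining null directions of the restraint
        Jacobian form a low-dimensional valley along which only the data
        term varies, typically with several shallow minima.  Steps along
        each null direction (re-projected onto the valley by minimizing the
        restraint penalty alone, which is cheap) provide global candidates
        that a local descent cannot reach.
        """
        if ctx.restraints is None:
            return []
        coords_fn = body_coords_fn(k)
        rs = ctx.restraints

        def distances(x):
            c = coords_fn(x)
            return np.linalg.norm(c[rs.idx_a] - c[rs.idx_b], axis=1)

        r_k = max(np.linalg.norm(
            ctx.half.coords[ctx.bodies[ctx.labels[k]]]
            - ctx.centroids[ctx.labels[k]], axis=1).mean(), 1.0)
        d0 = distances(xk)
        jac = np.empty((len(d0), 6))
        for j in range(6):
            eps = 1e-4 if j < 3 else 1e-3
            dx = np.zeros(6)
            dx[j] = eps
            scale = r_k if j < 3 else 1.0   # per-Angstrom twist units
            jac[:, j] = (distances(xk + dx) - d0) / eps / scale
        _, sv, vt = np.linalg.svd(jac)
        null = [vt[i] for i in range(6)
                if i >= len(sv) or sv[i] < 0.05 * max(sv[0], 1e-9)]

        def project(x):
            res = minimize(lambda y: rs.penalty(coords_fn(y)), x,
                           method="Powell",
                           options=dict(maxfev=90, xtol=1e-3, ftol=1e-4))
            return res.x

        cands = []
        for u in null[:2]:
            step6 = np.concatenate([u[:3] / r_k, u[3:]])
            for s in (-12.0, -8.0, -5.0, -2.5, 2.5, 5.0, 8.0, 12.0):
                cands.append(project(xk + s * step6))
        return cands

    for _ in range(n_sweeps):
        for k in range(nb):
            def body_obj(x, k=k):
                st = state.copy()
                st.rotvecs[k] = x[:3]
                st.translations[k] = x[3:]
                return ctx.evaluate(st, olig)[0]

            xk = np.concatenate([state.rotvecs[k], state.translations[k]])
            best_x, best_f = xk, body_obj(xk)
            for xc in orbit_candidates(k, xk):
                fc = body_obj(xc)
                if fc < best_f:
                    best_x, best_f = xc, fc
            rk = minimize(body_obj, best_x, method="Powell",
                          options=dict(maxfev=250, xtol=1e-4, ftol=1e-6))
            if rk.fun <= best_f:
                best_x, best_f = rk.x, rk.fun
            state.rotvecs[k] = best_x[:3]
            state.translations[k] = best_x[3:]
        if cfg.refine_oligomer:
            def olig_obj(x):
                ol = OligomerModel(N=float(np.clip(x[0], *cfg.n_bounds)),
                                   D=float(np.clip(x[1], *cfg.d_bounds)))
                return ctx.evaluate(state, ol)[0]

            ro = minimize(olig_obj, [olig.N, olig.D], method="Powell",
                          options=dict(maxfev=80, xtol=1e-4, ftol=1e-6))
            olig = OligomerModel(N=float(np.clip(ro.x[0], *cfg.n_bounds)),
                                 D=float(np.clip(ro.x[1], *cfg.d_bounds)))
    return state, olig


def gauge_align(coords: np.ndarray, reference: np.ndarray,
                axis_point=(0.0, 0.0, 0.0), axis_direction=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Remove the refinement gauge freedom before comparing models.

    Rotations about the C2 axis and translations along it change neither
    the rotation-averaged scattering nor any internal distance, so refined
    models are defined only up to this subgroup.  Returns ``coords`` mapped
    by the least-squares optimal axis rotation + axial shift onto
    ``reference`` (closed form).
    """
    p0 = np.asarray(axis_point, dtype=float)
    n = np.asarray(axis_direction, dtype=float)
    n = n / np.linalg.norm(n)
    # orthonormal frame (e1, e2, n)
    e1 = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(n, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    frame = np.column_stack([e1, e2, n])
    a = (coords - p0) @ frame
    b = (np.asarray(reference, dtype=float) - p0) @ frame
    phi = np.arctan2(np.sum(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]),
                     np.sum(a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]))
    c, s = np.cos(phi), np.sin(phi)
    rot = np.column_stack([c * a[:, 0] - s * a[:, 1],
                           s * a[:, 0] + c * a[:, 1],
                           a[:, 2] + np.mean(b[:, 2] - a[:, 2])])
    return rot @ frame.T + p0


def refine_rigid_body(
    structure_half: CoarseStructure,
    scheme: BodyScheme,
    curve: SAXSCurve,
    config: FitConfig | None = None,
    axis_point=(0.0, 0.0, 0.0),
    axis_direction=(0.0, 0.0, 1.0),
    start_state: BodyState | None = None,
    start_oligomer: OligomerModel | None = None,
    chain_map: dict[str, str] | None = None,
) -> FitResult:
    """Multi-start restrained rigid-body refinement.

    ``structure_half`` is the asymmetric half of a C2 assembly; its mate is
    regenerated from the transformed half at every step.  ``config.n_runs``
    independent annealing runs are started from ``start_state`` (identity by
    default), each with its own stream derived deterministically from
    ``config.seed``; the run with the lowest reduced chi^2 wins.
    """
    config = config or FitConfig()
    ctx = RefinementContext(structure_half, scheme, curve, config,
                   axis_point, axis_direction, chain_map)
    state0 = start_state or BodyState.identity(len(ctx.bodies))
    if state0.n_bodies != len(ctx.bodies):
        raise RefineError("start state has the wrong number of bodies")
    olig0 = start_oligomer or OligomerModel(N=1.0, D=80.0)
    runs: list[RunSummary] = []
    run_bests = []
    for run in range(config.n_runs):
        best, accepted = _anneal_run(ctx, run, state0, olig0)
        runs.append(RunSummary(run=run, chi2_reduced=best[3].value,
                               objective=best[0], accepted=accepted))
        run_bests.append(best)
    # polish the k best annealing runs; different runs may sit in different
    # basins and the annealing chi2 ordering does not always survive descent
    if config.polish_maxfev > 0 and config.polish_top_k > 0:
        order = sorted(range(config.n_runs),
                       key=lambda r: run_bests[r][3].value)
        for r in order[:config.polish_top_k]:
            obj_r, state_r, olig_r, fit_r, rp_r, ev_r = run_bests[r]
            p_state, p_olig = _polish(ctx, state_r, olig_r,
                                      config.polish_maxfev,
                                      config.polish_sweeps)
            p_obj, p_fit, p_rp, p_ev = ctx.evaluate(p_state, p_olig)
            if p_fit.value <= fit_r.value:  # keep the annealing result otherwise
                run_bests[r] = (p_obj, p_state, p_olig, p_fit, p_rp, p_ev)
                runs[r].chi2_reduced = p_fit.value
                runs[r].objective = p_obj
    overall = min(run_bests, key=lambda b: b[3].value)
    obj, state, olig, fit, rp, ev = overall
    final_coords = ctx.full_coords(state)
    final = ctx.reference_full.with_coords(final_coords)
    assert fit.value == min(r.chi2_reduced for r in runs)
    return FitResult(
        best_state=state, oligomer=olig, scale=fit.scale,
        chi2_reduced=fit.value, restraint_penalty=rp,
        excluded_volume_penalty=ev, objective=obj, runs=runs,
        structure=final, converged=fit.value <= config.converge_chi2,
        meta={"n_free_params": ctx.n_free, "n_bodies": len(ctx.bodies)},
    )
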