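"""Explicit elastodynamics on linear tetrahedra with element deletion.

Small-strain central-difference (velocity-Verlet) time integration with
a lumped mass matrix, constant-strain tetrahedra, a fixed-face boundary,
and a rigid frictionless spherical impactor coupled through penalty
contact against the implant-top node patch.  The impactor is removed
permanently at the first full separation after first touch, mirroring a
single-hit impact.

The time step obeys the CFL limit (minimum tet altitude over the
material dilatational wave speed) and, when an impactor is present, the
penalty-spring stability limit 2 sqrt(m_node/k) on the contact patch.

Energy bookkeeping (kinetic + strain + penalty + impactor kinetic +
damage dissipation) is carried along the run as a correctness ledger:
before the first element deletion the total is conserved to the
integration-scheme error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from . import damage as damage_mod
from .geometry import IMPLANT, Mesh, tet_volumes
from .materials import MaterialLibrary, dilatational_wave_speed, lame_parameters

__all__ = [
    "Impactor",
    "FEModel",
    "SimState",
    "TimeIntegrationParams",
    "RunHistory",
    "SolverError",
    "build_model",
    "lumped_mass",
    "element_stress",
    "internal_forces",
    "stable_dt",
    "contact_force",
    "step",
    "run",
]

_I3 = np.eye(3)


class SolverError(RuntimeError):
    pass


@dataclass
class Impactor:
    """Rigid frictionless sphere with penalty contact.

    ``center`` and ``velocity`` are its initial kinematics; the default
    radius matches a Ø1.5 cm ball and the default mass a 15 g steel ball.
    ``penalty_stiffness`` None means auto: 100x the stiffest nodal
    stiffness estimate (implant modulus x grid spacing) of the mesh it is
    paired with.
    """

    center: np.ndarray
    velocity: np.ndarray
    radius: float = 0.0075
    mass: float = 0.015
    penalty_stiffness: float | None = None
    active: bool = True
    # gap must stay open this long before the sphere counts as departed;
    # filters sub-microsecond contact chatter from nodal ringing
    removal_dwell: float = 2e-6

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        speed = float(np.linalg.norm(self.velocity))
        # approach direction: removal also requires the sphere to have
        # stopped advancing along it, so a target briefly outrunning the
        # sphere (apex support collapse) does not end the impact early
        self.approach_dir = self.velocity / speed if speed > 0 else np.zeros(3)
        if self.radius <= 0 or self.mass <= 0:
            raise ValueError("impactor radius and mass must be positive")
        if self.penalty_stiffness is not None and self.penalty_stiffness <= 0:
            raise ValueError("penalty stiffness must be positive")


@dataclass
class TimeIntegrationParams:
    """Explicit-integration controls.

    ``t_end`` budgets the *stepped* portion of the run: an impactor's
    analytically advanced free flight does not consume it.
    """

    cfl_factor: float = 0.5
    t_end: float = 2e-3
    output_every: int = 50
    # run-on after the impactor leaves: the larger of post_window_factor
    # contact durations and post_window_min seconds.  The floor keeps the
    # observation window comparable across conditions (contact duration
    # shrinks with impact speed) and long enough for the delayed
    # stress-wave damage phase, which outlasts the ~20 us contact
    post_window_factor: float = 5.0
    post_window_min: float = 1.0e-3
    approach_margin: float = 1e-4     # m left to step through after free flight

    def __post_init__(self):
        if not (0.0 < self.cfl_factor <= 1.0):
            raise ValueError("cfl_factor must lie in (0, 1]")


def _element_data(mesh: Mesh, materials: MaterialLibrary):
    """Per-element shape gradients, volumes, Lame constants, wave speeds,
    minimum altitudes.  Shape-function gradients come from inverting the
    4x4 linear interpolation matrix per tet."""
    coords = mesh.node_coords
    tets = mesh.tets
    V = tet_volumes(coords, tets)
    if np.any(V <= 0):
        bad = int(np.argmax(V <= 0))
        raise SolverError(f"element {bad} has non-positive volume")

    p = coords[tets]                       # (E,4,3)
    A = np.concatenate([np.ones((tets.shape[0], 4, 1)), p], axis=2)  # (E,4,4)
    C = np.linalg.inv(A)
    G = C[:, 1:4, :].transpose(0, 2, 1)    # (E,4,3): grad N_a = C[1:4, a]

    lam = np.empty(tets.shape[0])
    mu = np.empty(tets.shape[0])
    cd = np.empty(tets.shape[0])
    for region in np.unique(mesh.region):
        m = materials.elastic[region]
        l_, m_ = lame_parameters(m)
        sel = mesh.region == region
        lam[sel], mu[sel] = l_, m_
        cd[sel] = dilatational_wave_speed(m)
    soft = mesh.element_sets.get("SOFT")
    if soft is not None and soft.size:
        lam[soft] *= 1e-6
        mu[soft] *= 1e-6

    # minimum altitude = 3V / largest face area
    faces = p[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], :]   # (E,4,3,3)
    e1 = faces[:, :, 1] - faces[:, :, 0]
    e2 = faces[:, :, 2] - faces[:, :, 0]
    areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=2)          # (E,4)
    h_min = 3.0 * V / areas.max(axis=1)

    return G, V, lam, mu, cd, h_min


@dataclass
class FEModel:
    """Assembled model: mesh + materials + boundary + impactor + caches."""

    mesh: Mesh
    materials: MaterialLibrary
    fixed_nodes: np.ndarray
    impactor: Impactor | None = None
    # derived caches
    G: np.ndarray = None
    V: np.ndarray = None
    lam: np.ndarray = None
    mu: np.ndarray = None
    cd: np.ndarray = None
    h_min: np.ndarray = None
    visc: np.ndarray = None   # per-element bulk-viscosity coefficient
    mass: np.ndarray = None
    thresholds: np.ndarray = None
    top_nodes: np.ndarray = None
    fixed_mask: np.ndarray = None


def build_model(
    mesh: Mesh,
    materials: MaterialLibrary,
    impactor: Impactor | None = None,
    fixed_set: str | None = "FIXED",
    bulk_viscosity: float = 0.06,
) -> FEModel:
    """Assemble mesh, materials, boundary and impactor into a model.

    ``fixed_set`` names the node set to clamp; pass None for a fully
    free (unconstrained) mesh, as used in momentum-conservation checks.

    ``bulk_viscosity`` is the linear bulk-viscosity coefficient b1 of
    standard explicit dynamics (damping pressure b1 rho c_d L_e tr(deps/dt)
    per element); 0.06 is the conventional default, 0 disables damping.
    """
    if fixed_set is None:
        fixed = np.empty(0, dtype=np.int64)
    else:
        fixed = mesh.node_sets.get(fixed_set)
        if fixed is None or fixed.size == 0:
            raise SolverError(f"node set {fixed_set!r} is empty or missing")
    G, V, lam, mu, cd, h_min = _element_data(mesh, materials)

    rho = np.empty(mesh.n_elements)
    for region in np.unique(mesh.region):
        rho[mesh.region == region] = materials.elastic[region].rho
    mass = _lump(mesh, rho * V)

    if impactor is not None and impactor.penalty_stiffness is None:
        # a few times the stiffest adjacent nodal stiffness (implant
        # modulus x grid spacing): contact penetration stays micrometres
        # while the penalty-spring stability limit stays at the CFL level
        k_node = materials.elastic[IMPLANT].E * max(mesh.grid_spacing, 1e-6)
        impactor = replace(impactor, penalty_stiffness=5.0 * k_node)

    fixed_mask = np.zeros(mesh.n_nodes, dtype=bool)
    fixed_mask[fixed] = True
    return FEModel(
        mesh=mesh,
        materials=materials,
        fixed_nodes=fixed,
        impactor=impactor,
        G=G,
        V=V,
        lam=lam,
        mu=mu,
        cd=cd,
        h_min=h_min,
        visc=bulk_viscosity * rho * cd * h_min,
        mass=mass,
        thresholds=damage_mod.failure_thresholds(mesh, materials),
        top_nodes=mesh.node_sets.get("IMPLANT_TOP", np.empty(0, np.int64)),
        fixed_mask=fixed_mask,
    )


def _lump(mesh: Mesh, elem_mass: np.ndarray) -> np.ndarray:
    m = np.zeros(mesh.n_nodes)
    share = np.repeat(elem_mass / 4.0, 4)
    np.add.at(m, mesh.tets.ravel(), share)
    return m


def lumped_mass(mesh: Mesh, materials: MaterialLibrary) -> np.ndarray:
    """Row-sum lumped mass: each element's rho V split equally to its 4 nodes."""
    V = tet_volumes(mesh.node_coords, mesh.tets)
    if np.any(V <= 0):
        raise SolverError("zero or negative element volume in mass lumping")
    rho = np.empty(mesh.n_elements)
    for region in np.unique(mesh.region):
        rho[mesh.region == region] = materials.elastic[region].rho
    return _lump(mesh, rho * V)


def _compute(model: FEModel, disp: np.ndarray, vel: np.ndarray, active: np.ndarray):
    """Fused element pass: forces, stress, strain, vm, energy, viscous power."""
    return _kernel.compute(
        model.mesh.tets, model.G, model.V, model.lam, model.mu, model.visc,
        disp, vel, active,
    )


def _stresses(model: FEModel, disp: np.ndarray, active: np.ndarray):
    """Per-element small-strain tensor and Hooke stress (inactive zeroed)."""
    _, sig, eps, _, _, _ = _compute(model, disp, np.zeros_like(disp), active)
    return eps, sig


def element_stress(mesh: Mesh, element: int, disp: np.ndarray, materials: MaterialLibrary):
    """Constant stress tensor of one element under a displacement field."""
    model = build_model_nocontact(mesh, materials)
    _, sig = _stresses(model, disp, np.ones(mesh.n_elements, dtype=bool))
    return sig[element]


def build_model_nocontact(mesh: Mesh, materials: MaterialLibrary) -> FEModel:
    """Unconstrained model without impactor (standalone operation wrappers)."""
    return build_model(mesh, materials, impactor=None, fixed_set=None)


def internal_forces(
    mesh: Mesh, disp: np.ndarray, materials: MaterialLibrary, active: np.ndarray | None = None
) -> np.ndarray:
    """Assembled nodal internal forces -int B^T sigma over active elements
    (the negative gradient of total strain energy)."""
    model = build_model_nocontact(mesh, materials)
    if active is None:
        active = np.ones(mesh.n_elements, dtype=bool)
    f, _, _, _, _, _ = _compute(model, disp, np.zeros_like(disp), active)
    return f


def strain_energy(model: FEModel, eps: np.ndarray, sig: np.ndarray) -> float:
    return 0.5 * float(np.einsum("e,eij,eij->", model.V, sig, eps))


def total_strain_energy(
    mesh: Mesh, disp: np.ndarray, materials: MaterialLibrary, active: np.ndarray | None = None
) -> float:
    """Total elastic strain energy 1/2 sum_e V_e sigma_e : eps_e, J."""
    model = build_model_nocontact(mesh, materials)
    if active is None:
        active = np.ones(mesh.n_elements, dtype=bool)
    _, _, _, _, se, _ = _compute(model, disp, np.zeros_like(disp), active)
    return se


def stable_dt(
    mesh: Mesh,
    materials: MaterialLibrary,
    active: np.ndarray | None = None,
    cfl_factor: float = 0.5,
) -> float:
    """CFL-stable step: cfl * min over active elements of h_min/c_d."""
    _, _, _, _, cd, h_min = _element_data(mesh, materials)
    if active is None:
        active = np.ones(mesh.n_elements, dtype=bool)
    if not active.any():
        raise SolverError("no active elements")
    return cfl_factor * float(np.min(h_min[active] / cd[active]))


def contact_force(
    impactor: Impactor,
    center: np.ndarray,
    node_positions: np.ndarray,
):
    """Penalty contact of a rigid sphere against a node patch.

    For each node penetrating the sphere by g > 0, a normal force k g
    along the outward sphere-surface normal (frictionless, no tangential
    component).  Returns (per-node forces, impactor reaction, penetration
    depths); the reaction is the exact negative of the nodal resultant.
    """
    w = node_positions - center                     # (n,3)
    dist = np.linalg.norm(w, axis=1)
    pen = impactor.radius - dist
    forces = np.zeros_like(node_positions)
    touching = pen > 0
    if touching.any():
        n_hat = w[touching] / np.maximum(dist[touching, None], 1e-300)
        forces[touching] = impactor.penalty_stiffness * pen[touching, None] * n_hat
    reaction = -forces.sum(axis=0)
    return forces, reaction, pen


@dataclass
class SimState:
    """Instantaneous state of the coupled mesh + impactor system."""

    time: float
    disp: np.ndarray
    vel: np.ndarray
    acc: np.ndarray
    stress: np.ndarray
    active: np.ndarray
    impactor_center: np.ndarray | None = None
    impactor_velocity: np.ndarray | None = None
    impactor_active: bool = False
    impactor_touched: bool = False
    impactor_separated_since: float | None = None
    impactor_reaction: np.ndarray = None   # contact reaction at this state
    strain: np.ndarray = None              # per-element strain tensors
    vm: np.ndarray = None                  # per-element von Mises stress
    strain_energy: float = 0.0
    viscous_power: float = 0.0             # bulk-viscosity dissipation rate, W


def initial_state(model: FEModel) -> SimState:
    n, e = model.mesh.n_nodes, model.mesh.n_elements
    active = np.ones(e, dtype=bool)
    imp = model.impactor
    return SimState(
        time=0.0,
        disp=np.zeros((n, 3)),
        vel=np.zeros((n, 3)),
        acc=np.zeros((n, 3)),
        stress=np.zeros((e, 3, 3)),
        active=active,
        impactor_center=None if imp is None else imp.center.copy(),
        impactor_velocity=None if imp is None else imp.velocity.copy(),
        impactor_active=imp is not None and imp.active,
        impactor_reaction=np.zeros(3),
        strain=np.zeros((e, 3, 3)),
        vm=np.zeros(e),
    )


def _forces(model: FEModel, state_disp, state_vel, active, imp_center, imp_active):
    """Total nodal force and impactor reaction at given positions."""
    f, sig, eps, vm, se, p_visc = _compute(model, state_disp, state_vel, active)
    reaction = np.zeros(3)
    pen = None
    if model.impactor is not None and imp_active:
        pos = (
            model.mesh.node_coords[model.top_nodes]
            + state_disp[model.top_nodes]
        )
        fc, reaction, pen = contact_force(model.impactor, imp_center, pos)
        f[model.top_nodes] += fc
    return f, reaction, pen, eps, sig, vm, se, p_visc


def step(model: FEModel, state: SimState, dt: float) -> SimState:
    """One central-difference step of the coupled system.

    Half-kick / drift / half-kick; fixed nodes clamped to zero
    displacement and velocity throughout; the impactor advances under its
    contact reaction and is deactivated permanently at the first full
    separation after first touch.
    """
    fixed = model.fixed_mask
    minv = 1.0 / model.mass[:, None]
    imp = model.impactor

    acc = state.acc
    reaction_prev = state.impactor_reaction
    if acc is None or (imp is not None and reaction_prev is None):
        f0, reaction_prev, _, _, _, _, _, _ = _forces(
            model, state.disp, state.vel, state.active,
            state.impactor_center, state.impactor_active,
        )
        acc = f0 * minv
        acc[fixed] = 0.0
    if reaction_prev is None:
        reaction_prev = np.zeros(3)

    v_half = state.vel + 0.5 * dt * acc
    v_half[fixed] = 0.0
    disp = state.disp + dt * v_half
    disp[fixed] = 0.0

    imp_center = state.impactor_center
    imp_vel = state.impactor_velocity
    imp_active = state.impactor_active
    touched = state.impactor_touched
    if imp is not None and imp_active:
        imp_vel = imp_vel + 0.5 * dt * reaction_prev / imp.mass
        imp_center = imp_center + dt * imp_vel

    f, reaction, pen, eps, sig, vm, se, p_visc = _forces(
        model, disp, v_half, state.active, imp_center, imp_active
    )
    if not np.all(np.isfinite(f)):
        bad = int(np.argmax(~np.isfinite(f).all(axis=1)))
        raise SolverError(f"non-finite nodal force at node {bad}, t={state.time + dt:.3e}s")

    acc_new = f * minv
    acc_new[fixed] = 0.0
    vel = v_half + 0.5 * dt * acc_new
    vel[fixed] = 0.0

    separated_since = state.impactor_separated_since
    if imp is not None and imp_active:
        imp_vel = imp_vel + 0.5 * dt * reaction / imp.mass
        in_contact = pen is not None and bool(np.any(pen > 0))
        t_new = state.time + dt
        if in_contact:
            touched = True
            separated_since = None
        elif touched:
            if separated_since is None:
                separated_since = t_new
            advancing = float(imp_vel @ imp.approach_dir) > 0.0
            if t_new - separated_since >= imp.removal_dwell and not advancing:
                imp_active = False   # removed after contact, permanently

    return SimState(
        time=state.time + dt,
        disp=disp,
        vel=vel,
        acc=acc_new,
        stress=sig,
        active=state.active.copy(),
        impactor_center=imp_center,
        impactor_velocity=imp_vel,
        impactor_active=imp_active,
        impactor_touched=touched,
        impactor_separated_since=separated_since,
        impactor_reaction=reaction,
        strain=eps,
        vm=vm,
        strain_energy=se,
        viscous_power=p_visc,
    )


@dataclass
class RunHistory:
    """Snapshots, damage events, and the energy ledger of one run."""

    times: list = field(default_factory=list)
    vm: list = field(default_factory=list)          # (E,) float32 per snapshot
    active: list = field(default_factory=list)      # (E,) bool per snapshot
    disp: list = field(default_factory=list)        # (N,3) float32 per snapshot
    energy: list = field(default_factory=list)      # dict rows
    events: list = field(default_factory=list)
    contact: list = field(default_factory=list)     # (t, |resultant|)
    t_touch: float | None = None
    t_release: float | None = None
    final_state: SimState | None = None

    def energy_frame(self):
        import pandas as pd

        return pd.DataFrame(self.energy)


def run(
    model: FEModel,
    params: TimeIntegrationParams,
    state: SimState | None = None,
) -> RunHistory:
    """Explicit time loop with per-step failure checks.

    The step size is fixed at the initial CFL limit (deletion only raises
    the limit) intersected with the penalty-contact stability bound.  An
    impactor's free flight toward the mesh is advanced analytically; the
    loop stops at ``t_end`` or, after a completed impact, at
    ``post_window_factor`` contact durations past release.
    """
    if state is None:
        state = initial_state(model)
    hist = RunHistory()

    dt = stable_dt(model.mesh, model.materials, state.active, params.cfl_factor)
    imp = model.impactor
    if imp is not None:
        m_top = model.mass[model.top_nodes]
        dt_contact = params.cfl_factor * 2.0 * np.sqrt(
            m_top.min() / imp.penalty_stiffness
        )
        dt = min(dt, float(dt_contact))

        # analytic free flight up to approach_margin from first touch
        speed = float(np.linalg.norm(imp.velocity))
        if speed > 0:
            pos = model.mesh.node_coords[model.top_nodes]
            gap = np.linalg.norm(pos - imp.center, axis=1) - imp.radius
            t_ff = (gap.min() - params.approach_margin) / speed
            if t_ff > 0:
                state.impactor_center = state.impactor_center + t_ff * imp.velocity
                state.time = t_ff

    ledger = {"deleted": 0.0, "viscous": 0.0}
    thresholds = model.thresholds

    def record(state: SimState, pen_energy: float):
        ke = 0.5 * float(np.sum(model.mass[:, None] * state.vel**2))
        se = state.strain_energy
        ke_imp = (
            0.5 * imp.mass * float(np.sum(state.impactor_velocity**2))
            if imp is not None
            else 0.0
        )
        hist.times.append(state.time)
        hist.vm.append(state.vm.astype(np.float32))
        hist.active.append(state.active.copy())
        hist.disp.append(state.disp.astype(np.float32))
        hist.energy.append(
            {
                "time_s": state.time,
                "kinetic_J": ke,
                "strain_J": se,
                "penalty_J": pen_energy,
                "impactor_kinetic_J": ke_imp,
                "dissipated_J": ledger["deleted"],
                "viscous_J": ledger["viscous"],
                "total_J": ke + se + pen_energy + ke_imp
                + ledger["deleted"] + ledger["viscous"],
            }
        )

    record(state, 0.0)
    n_step = 0
    t_stop = state.time + params.t_end
    while state.time < t_stop:
        state = step(model, state, dt)
        n_step += 1
        ledger["viscous"] += state.viscous_power * dt

        # failure check on the fresh stresses
        hit = damage_mod.apply_failure(
            state.vm, state.active, thresholds, model.mesh.region, state.time,
            hist.events,
        )
        if hit.size:
            released = 0.5 * float(
                np.einsum(
                    "e,eij,eij->", model.V[hit], state.stress[hit], state.strain[hit]
                )
            )
            ledger["deleted"] += released
            state.strain_energy -= released
            state.stress[hit] = 0.0
            state.strain[hit] = 0.0
            state.vm[hit] = 0.0

        pen_energy = 0.0
        if imp is not None:
            reaction = state.impactor_reaction
            hist.contact.append((state.time, float(np.linalg.norm(reaction))))
            if state.impactor_active:
                pos = (
                    model.mesh.node_coords[model.top_nodes]
                    + state.disp[model.top_nodes]
                )
                pen = imp.radius - np.linalg.norm(pos - state.impactor_center, axis=1)
                pen = np.maximum(pen, 0.0)
                pen_energy = 0.5 * imp.penalty_stiffness * float(np.sum(pen**2))
                if state.impactor_touched and hist.t_touch is None:
                    hist.t_touch = state.time
            elif state.impactor_touched and hist.t_release is None:
                hist.t_release = state.time

        if n_step % params.output_every == 0:
            record(state, pen_energy)

        if (
            imp is not None
            and hist.t_release is not None
            and state.time
            >= hist.t_release
            + max(
                params.post_window_factor
                * (hist.t_release - (hist.t_touch or 0.0)),
                params.post_window_min,
            )
        ):
            break

    if hist.times[-1] != state.time:
        record(state, 0.0)
    hist.final_state = state
    return hist
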