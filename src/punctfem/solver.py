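"""Axisymmetric elastoplastic finite-element solver for rigid flat-punch puncture.

Small-strain axisymmetric 4-node quadrilateral elements (2x2 Gauss, B-bar mean
dilatation to avoid volumetric locking at nu ~ 0.44), J2 bilinear plasticity
integrated with a radial-return map, frictionless rigid flat-punch contact by
nodal penalties on the exposed surface, and element erosion at an equivalent
plastic-strain threshold so the probe can penetrate the skin.  Two drivers are
provided: a displacement-controlled quasi-static Newton solver and an explicit
central-difference dynamic solver.

Unit system: mm, N, MPa, s; densities in tonne/mm^3 (1 kg/m^3 = 1e-12 t/mm^3).
The solver is fully deterministic: identical inputs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .material import MaterialParams, hardening_modulus
from .mesh import DomainSpec, Mesh
from .metrics import ForceDeformationCurve

__all__ = [
    "ProbeSpec",
    "SolverConfig",
    "FieldState",
    "SimulationResult",
    "IPState",
    "radial_return",
    "contact_update",
    "erode_elements",
    "solve_quasi_static",
    "solve_explicit",
    "stable_time_step",
]

_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_SQ23 = np.sqrt(2.0 / 3.0)


class SolverError(RuntimeError):
    pass


class NumericalStateError(SolverError):
    """Non-finite quantities entered the constitutive update."""


@dataclass(frozen=True)
class ProbeSpec:
    """Rigid flat-end probe: radius (mm), insertion velocity (mm/s), max insertion (mm)."""

    radius: float = 1.0
    velocity: float = 1.5
    max_insertion: float = 10.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.velocity < 0 or self.max_insertion <= 0:
            raise ValueError("probe radius and max_insertion must be positive, velocity >= 0")


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls for both solution modes.

    penalty_scale scales the contact penalty relative to the stiffest layer's
    nodal stiffness; eps_p_max is the equivalent-plastic-strain erosion
    threshold (elements at or above it are deleted permanently);
    stop_after_drop, if set, ends a quasi-static run once the force has
    fallen below (1 - stop_after_drop) of its running peak -- enough to
    capture the bioyield point without simulating the full plateau.
    """

    mode: str = "quasi_static"
    penalty_scale: float = 100.0
    eps_p_max: float = 0.5
    increment: float = 0.02  # quasi-static punch-depth increment (mm)
    newton_tol: float = 1e-9  # relative force residual
    newton_maxit: int = 40
    max_bisections: int = 6
    safety: float = 0.9  # explicit CFL safety factor
    time_scale: float = 1.0  # explicit-mode velocity scaling for runtime control
    damping: float = 0.0  # mass-proportional damping coefficient (1/s)
    filter_window: int = 1  # moving-average window for explicit force reporting
    bottom_fixed: bool = True  # clamp both dofs on the bottom face (else roller)
    outer_radial_fixed: bool = True  # u_r = 0 on the outer radius (else free)
    snapshot_depths: tuple = ()
    stop_after_drop: float | None = None
    record_every: int = 1  # explicit-mode sample thinning

    def __post_init__(self) -> None:
        if self.mode not in ("quasi_static", "explicit"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.eps_p_max <= 0 or self.newton_tol <= 0 or not (0 < self.safety <= 1):
            raise ValueError("invalid solver tolerances")


@dataclass
class FieldState:
    """Solution state: nodal displacements plus per-Gauss-point history.

    ``stress`` and ``eps_p`` are (n_elems, 4 gp, 4) Voigt arrays
    [rr, zz, tt, rz] (engineering shear for strain); ``ebar_p`` is the
    equivalent plastic strain, non-decreasing over the history; ``active``
    mirrors the mesh's element flags (eroded elements carry zero stress).
    """

    u: np.ndarray
    stress: np.ndarray
    eps_p: np.ndarray
    ebar_p: np.ndarray
    active: np.ndarray
    punch_depth: float = 0.0
    time: float = 0.0

    @classmethod
    def zero(cls, mesh: Mesh) -> "FieldState":
        ne = mesh.n_elems
        return cls(
            u=np.zeros((mesh.n_nodes, 2)),
            stress=np.zeros((ne, 4, 4)),
            eps_p=np.zeros((ne, 4, 4)),
            ebar_p=np.zeros((ne, 4)),
            active=mesh.active.copy(),
        )

    def von_mises(self) -> np.ndarray:
        """Per-element mean von Mises stress (MPa) over the Gauss points."""
        s = self.stress
        p = s[..., :3].mean(axis=-1)
        dev = s[..., :3] - p[..., None]
        j2 = 0.5 * (dev**2).sum(axis=-1) + s[..., 3] ** 2
        return np.sqrt(3.0 * j2).mean(axis=-1)


@dataclass
class SimulationResult:
    """Force--insertion curve, field snapshots, erosion history and run diagnostics."""

    curve: ForceDeformationCurve
    snapshots: list
    erosion_history: list  # (punch_depth, element_indices) tuples
    external_work: np.ndarray
    strain_energy: np.ndarray
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def dissipated_energy(self) -> np.ndarray:
        return self.external_work - self.strain_energy


# ---------------------------------------------------------------------------
# constitutive update
# ---------------------------------------------------------------------------

def _elastic_matrix(p: MaterialParams) -> np.ndarray:
    G = p.E / (2 * (1 + p.nu))
    lam = p.E * p.nu / ((1 + p.nu) * (1 - 2 * p.nu))
    D = np.zeros((4, 4))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * G
    D[3, 3] = G
    return D


def _dev_matrix(G: float) -> np.ndarray:
    """Voigt operator mapping engineering strain to 2G * deviatoric stress."""
    D = np.full((3, 3), -2 * G / 3.0)
    np.fill_diagonal(D, 4 * G / 3.0)
    out = np.zeros((4, 4))
    out[:3, :3] = D
    out[3, 3] = G
    return out


def _return_map_batch(eps: np.ndarray, eps_p: np.ndarray, ebar: np.ndarray,
                      p: MaterialParams, need_tangent: bool):
    """Vectorised strain-driven radial return for a batch of Gauss points.

    eps, eps_p: (n, 4) Voigt with engineering shear strain.  Returns
    (stress, eps_p_new, ebar_new, D_alg or None).
    """
    if not (np.all(np.isfinite(eps)) and np.all(np.isfinite(eps_p))):
        raise NumericalStateError("non-finite strain state")
    De = _elastic_matrix(p)
    G = p.E / (2 * (1 + p.nu))
    sig_tr = (eps - eps_p) @ De.T
    pm = sig_tr[:, :3].mean(axis=1)
    s_tr = sig_tr.copy()
    s_tr[:, :3] -= pm[:, None]
    norm2 = (s_tr[:, :3] ** 2).sum(axis=1) + 2 * s_tr[:, 3] ** 2
    q_tr = np.sqrt(1.5 * norm2)
    # only evaluate the hardening modulus once plastic flow has occurred,
    # so the degenerate elastic limit (Et == E, non-yielding sigma_y) works
    y = p.sigma_y + (_safe_hardening(p) * ebar if np.any(ebar > 0) else 0.0)
    f = q_tr - y
    plastic = f > 1e-12 * max(p.sigma_y if np.isfinite(p.sigma_y) else p.E, p.E)

    stress = sig_tr.copy()
    eps_p_new = eps_p.copy()
    ebar_new = ebar.copy()
    D_alg = None
    if need_tangent:
        D_alg = np.broadcast_to(De, (eps.shape[0], 4, 4)).copy()

    if np.any(plastic):
        H = _safe_hardening(p)
        idx = np.flatnonzero(plastic)
        qi = q_tr[idx]
        dl = f[idx] / (3 * G + H)
        fac = 1.0 - 3 * G * dl / qi
        s_new = s_tr[idx] * fac[:, None]
        stress[idx, :3] = s_new[:, :3] + pm[idx, None]
        stress[idx, 3] = s_new[:, 3]
        # plastic flow: normal components 1.5*dl*s/q, engineering shear 3*dl*s_rz/q
        flow = s_tr[idx] * (1.5 * dl / qi)[:, None]
        flow[:, 3] *= 2.0
        eps_p_new[idx] += flow
        ebar_new[idx] += dl
        if need_tangent:
            Ddev = _dev_matrix(G)
            coef_dev = 3 * G * dl / qi
            coef_dyad = 6 * G**2 * (dl / qi - 1.0 / (3 * G + H))
            nrm = np.sqrt(norm2[idx])
            Nv = s_tr[idx] / nrm[:, None]
            D_alg[idx] = (
                De
                - coef_dev[:, None, None] * Ddev
                + coef_dyad[:, None, None] * np.einsum("ni,nj->nij", Nv, Nv)
            )
    return stress, eps_p_new, ebar_new, D_alg


def _safe_hardening(p: MaterialParams) -> float:
    # Et == E is only reachable with a non-yielding sigma_y; guard anyway.
    if p.Et >= p.E:
        raise ValueError("hardening modulus undefined for Et >= E at a yielding point")
    return hardening_modulus(p.E, p.Et)


@dataclass(frozen=True)
class IPState:
    """Single integration-point state for the scalar radial-return interface."""

    eps: np.ndarray  # total strain, Voigt engineering shear
    eps_p: np.ndarray
    ebar_p: float
    stress: np.ndarray


def radial_return(strain_increment, state: IPState, p: MaterialParams) -> IPState:
    """Apply one strain increment to an integration point (J2, bilinear hardening).

    The trial stress is elastic; if its von Mises stress exceeds the current
    yield stress sigma_y + H*ebar_p, the stress returns radially to the yield
    surface with H = E*Et/(E - Et), and the plastic strain increment is >= 0.
    """
    deps = np.asarray(strain_increment, dtype=float)
    if not np.all(np.isfinite(deps)):
        raise NumericalStateError("non-finite strain increment")
    eps_new = state.eps + deps
    stress, eps_p, ebar, _ = _return_map_batch(
        eps_new[None, :], state.eps_p[None, :].copy(), np.array([state.ebar_p]), p, False
    )
    return IPState(eps=eps_new, eps_p=eps_p[0], ebar_p=float(ebar[0]), stress=stress[0])


# ---------------------------------------------------------------------------
# discretisation precompute
# ---------------------------------------------------------------------------

class _Discretisation:
    """Precomputed B-bar matrices, quadrature weights and dof maps for a mesh."""

    def __init__(self, mesh: Mesh, materials: dict):
        self.mesh = mesh
        self.materials = materials
        ne = mesh.n_elems
        xy = mesh.nodes[mesh.elems]  # (ne, 4, 2)
        Bb = np.zeros((ne, 4, 4, 8))
        w = np.zeros((ne, 4))
        B_all = np.zeros((ne, 4, 4, 8))
        vol_rows = np.zeros((ne, 4, 8))
        g = 0
        for xi in _GP:
            for eta in _GP:
                N = 0.25 * np.array(
                    [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                     (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
                )
                dN = 0.25 * np.array(
                    [[-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)],
                     [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)]]
                )  # (2, 4) d/dxi, d/deta
                J = np.einsum("an,eni->eai", dN, xy)  # (ne, 2, 2)
                detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
                Jinv = np.empty_like(J)
                Jinv[:, 0, 0] = J[:, 1, 1]
                Jinv[:, 1, 1] = J[:, 0, 0]
                Jinv[:, 0, 1] = -J[:, 0, 1]
                Jinv[:, 1, 0] = -J[:, 1, 0]
                Jinv /= detJ[:, None, None]
                grad = np.einsum("eia,an->ein", Jinv, dN)  # (ne, 2, 4): d/dr, d/dz
                r = xy[:, :, 0] @ N  # (ne,)
                B = np.zeros((ne, 4, 8))
                B[:, 0, 0::2] = grad[:, 0, :]            # eps_rr
                B[:, 1, 1::2] = grad[:, 1, :]            # eps_zz
                B[:, 2, 0::2] = N[None, :] / r[:, None]  # eps_tt
                B[:, 3, 0::2] = grad[:, 1, :]            # gamma_rz
                B[:, 3, 1::2] = grad[:, 0, :]
                B_all[:, g] = B
                vol_rows[:, g] = B[:, 0] + B[:, 1] + B[:, 2]
                w[:, g] = detJ * 2 * np.pi * r  # unit gauss weights (1 each)
                g += 1
        # B-bar: replace the volumetric part with its element (volume) average
        vol_mean = np.einsum("egj,eg->ej", vol_rows, w) / w.sum(axis=1)[:, None]
        for g in range(4):
            corr = (vol_mean - vol_rows[:, g]) / 3.0  # (ne, 8)
            Bb[:, g] = B_all[:, g]
            Bb[:, g, :3, :] += corr[:, None, :]
        self.Bb = Bb
        self.w = w
        if np.any(w <= 0):
            raise SolverError("non-positive integration weight (inverted element?)")

        dofs = np.empty((ne, 8), dtype=np.int64)
        dofs[:, 0::2] = 2 * mesh.elems
        dofs[:, 1::2] = 2 * mesh.elems + 1
        self.dofs = dofs
        self.rows = np.repeat(dofs, 8, axis=1).ravel()
        self.cols = np.tile(dofs, (1, 8)).ravel()
        self.ndof = 2 * mesh.n_nodes
        self.mat_groups = {
            name: np.flatnonzero(mesh.material == name) for name in ("skin", "flesh")
        }
        self.mat_groups = {k: v for k, v in self.mat_groups.items() if v.size}

    def strains(self, u: np.ndarray) -> np.ndarray:
        ue = u.reshape(-1)[self.dofs]  # (ne, 8)
        return np.einsum("egij,ej->egi", self.Bb, ue)

    def update_stress(self, u, eps_p, ebar, need_tangent, active=None):
        """Strain-driven constitutive update; eroded elements stay zero-stress and frozen."""
        eps = self.strains(u)
        stress = np.zeros_like(eps)
        eps_p_new = eps_p.copy()
        ebar_new = ebar.copy()
        D = np.zeros((self.mesh.n_elems, 4, 4, 4)) if need_tangent else None
        for name, els in self.mat_groups.items():
            if active is not None:
                els = els[active[els]]
                if els.size == 0:
                    continue
            p = self.materials[name]
            sh = eps[els].reshape(-1, 4)
            st, ep, eb, Da = _return_map_batch(
                sh, eps_p[els].reshape(-1, 4), ebar[els].ravel(), p, need_tangent
            )
            stress[els] = st.reshape(-1, 4, 4)
            eps_p_new[els] = ep.reshape(-1, 4, 4)
            ebar_new[els] = eb.reshape(-1, 4)
            if need_tangent:
                D[els] = Da.reshape(-1, 4, 4, 4)
        return eps, stress, eps_p_new, ebar_new, D

    def internal_force(self, stress, active) -> np.ndarray:
        wa = self.w * active[:, None]
        fe = np.einsum("egij,egi,eg->ej", self.Bb, stress, wa)
        f = np.zeros(self.ndof)
        np.add.at(f, self.dofs.ravel(), fe.ravel())
        return f

    def stiffness(self, D, active) -> sp.csr_matrix:
        wa = self.w * active[:, None]
        Ke = np.einsum("egip,egij,egjq,eg->epq", self.Bb, D, self.Bb, wa)
        K = sp.coo_matrix((Ke.ravel(), (self.rows, self.cols)), shape=(self.ndof, self.ndof))
        return K.tocsr()

    def lumped_mass(self) -> np.ndarray:
        """Nodal lumped mass (tonne) including the 2*pi*r axisymmetric weight."""
        m = np.zeros(self.mesh.n_nodes)
        xy = self.mesh.nodes[self.mesh.elems]
        rho = np.array([self.materials[t].rho_solver for t in self.mesh.material])
        g = 0
        for xi in _GP:
            for eta in _GP:
                N = 0.25 * np.array(
                    [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                     (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
                )
                contrib = rho[:, None] * self.w[:, g][:, None] * N[None, :]
                np.add.at(m, self.mesh.elems.ravel(), contrib.ravel())
                g += 1
        return m

    def elastic_energy(self, eps, stress, eps_p, active) -> float:
        ee = eps - eps_p
        dens = 0.5 * np.einsum("egi,egi->eg", stress, ee)
        return float((dens * self.w * active[:, None]).sum())


# ---------------------------------------------------------------------------
# contact and erosion
# ---------------------------------------------------------------------------

def _surface_candidates(mesh: Mesh, active: np.ndarray, probe_radius: float):
    """Exposed-surface contact-candidate nodes under the punch footprint.

    Works on the structured grid: for each node column the topmost node that
    still touches an active element is the exposed one; eroded columns expose
    the nodes beneath (eroding contact).  Fully eroded columns drop out.
    """
    nr, nz = mesh.nr, mesh.nz
    grid = active.reshape(nz, nr)
    # topmost active element row per element column, -1 if none
    any_active = grid.any(axis=0)
    top_row = np.where(any_active, nz - 1 - np.argmax(grid[::-1], axis=0), -1)
    nodes = []
    r_coords = mesh.nodes[: nr + 1, 0]
    for i in range(nr + 1):
        if r_coords[i] > probe_radius + 1e-9:
            break
        adj = [c for c in (i - 1, i) if 0 <= c < nr]
        rows = [top_row[c] for c in adj if top_row[c] >= 0]
        if not rows:
            continue  # column fully eroded: hole
        j = max(rows) + 1
        nodes.append(mesh.node_index(i, j))
    return np.array(nodes, dtype=np.int64)


def _penalty_stiffnesses(mesh: Mesh, nodes: np.ndarray, materials: dict,
                         config: SolverConfig) -> np.ndarray:
    """Per-node contact penalty: scale x stiffest-layer modulus x tributary area / h."""
    E_ref = max(m.E for m in materials.values())
    r_all = mesh.nodes[: mesh.nr + 1, 0]
    r = mesh.nodes[nodes, 0]
    dr = np.diff(r_all)
    h_ref = dr.min()
    idx = np.searchsorted(r_all, r)
    w_lo = np.where(idx > 0, dr[np.maximum(idx - 1, 0)], 0.0) / 2
    w_hi = np.where(idx < len(dr), dr[np.minimum(idx, len(dr) - 1)], 0.0) / 2
    width = w_lo + w_hi
    area = np.where(r > 0, 2 * np.pi * r * width, np.pi * (w_hi**2))
    return config.penalty_scale * E_ref * area / h_ref


def contact_update(punch_depth: float, mesh: Mesh, state: FieldState,
                   probe: ProbeSpec, penalty: float):
    """Frictionless penalty contact with the rigid flat punch face.

    ``penalty`` is the nodal penalty stiffness (N/mm) applied uniformly to
    every candidate node.  Returns (contact force vector over all dofs,
    candidate node indices, penetrations, total punch reaction in N).  Nodes
    exposed by erosion enter the candidate set automatically (eroding
    contact); zero force when nothing penetrates.
    """
    if punch_depth < 0:
        raise ValueError("punch_depth must be >= 0")
    nodes = _surface_candidates(mesh, state.active, probe.radius)
    f = np.zeros(2 * mesh.n_nodes)
    if nodes.size == 0:
        return f, nodes, np.zeros(0), 0.0
    z_face = mesh.spec.depth - punch_depth
    z_now = mesh.nodes[nodes, 1] + state.u[nodes, 1]
    pen = np.maximum(z_now - z_face, 0.0)
    f[2 * nodes + 1] = -penalty * pen
    return f, nodes, pen, float((penalty * pen).sum())


def _contact_forces(punch_depth: float, mesh: Mesh, u: np.ndarray, active: np.ndarray,
                    probe: ProbeSpec, materials: dict, config: SolverConfig):
    """Penalty contact force vector, candidate nodes, penetrations, stiffnesses, reaction."""
    nodes = _surface_candidates(mesh, active, probe.radius)
    ndof = 2 * mesh.n_nodes
    f = np.zeros(ndof)
    if nodes.size == 0:
        return f, nodes, np.zeros(0), np.zeros(0), 0.0
    k = _penalty_stiffnesses(mesh, nodes, materials, config)
    z_face = mesh.spec.depth - punch_depth
    z_now = mesh.nodes[nodes, 1] + u.reshape(-1, 2)[nodes, 1]
    pen = z_now - z_face
    pen = np.where(pen > 0, pen, 0.0)
    f[2 * nodes + 1] = -k * pen  # punch pushes the tissue down
    reaction = float((k * pen).sum())
    return f, nodes, pen, k, reaction


def erode_elements(state: FieldState, config: SolverConfig) -> np.ndarray:
    """Deactivate active elements whose max Gauss-point plastic strain >= eps_p_max.

    The threshold is closed (an element exactly at eps_p_max erodes), erosion
    is permanent, and eroded elements' stresses are zeroed in place.  Returns
    the indices of the newly eroded elements.
    """
    over = state.ebar_p.max(axis=1) >= config.eps_p_max
    newly = np.flatnonzero(over & state.active)
    if newly.size:
        state.active[newly] = False
        state.stress[newly] = 0.0
    return newly


# ---------------------------------------------------------------------------
# quasi-static driver
# ---------------------------------------------------------------------------

def solve_quasi_static(mesh: Mesh, materials: dict, probe: ProbeSpec,
                       config: SolverConfig) -> SimulationResult:
    """Displacement-controlled quasi-static puncture with Newton iteration.

    The punch depth advances in increments; at each increment the nodal
    displacements are solved to equilibrium (relative force residual below
    ``newton_tol``), elements at the plastic-strain limit are eroded and the
    configuration is re-equilibrated so the recorded force reflects the
    post-rupture state.  Boundary conditions: bottom face fixed (or roller),
    axis u_r = 0, outer radius u_r = 0 (or free).
    """
    disc = _Discretisation(mesh, materials)
    state = FieldState.zero(mesh)
    fixed = _fixed_dofs(mesh, config)
    free = np.setdiff1d(np.arange(disc.ndof), fixed)

    depths = [0.0]
    forces = [0.0]
    work = [0.0]
    energy = [0.0]
    snapshots = []
    erosion_history = []
    snap_left = sorted(config.snapshot_depths)
    converged_all = True
    n_inc = int(np.ceil(probe.max_insertion / config.increment - 1e-12))
    peak = 0.0
    diag = {"newton_iters": [], "bisections": 0}

    depth = 0.0
    inc = 0
    while depth < probe.max_insertion - 1e-12 and inc < 20 * n_inc + 200:
        target = min(depth + config.increment, probe.max_insertion)
        ok, state, F = _newton_solve(disc, state, target, probe, materials, config, free)
        sub = 0
        while not ok and sub < config.max_bisections:
            # bisect the increment from the last converged depth
            sub += 1
            diag["bisections"] += 1
            target = depth + (target - depth) / 2.0
            ok, state, F = _newton_solve(disc, state, target, probe, materials, config, free)
        if not ok:
            converged_all = False
            break
        # erosion + re-equilibration at the same depth
        cycles = 0
        while True:
            newly = erode_elements(state, config)
            if newly.size == 0:
                break
            erosion_history.append((target, newly))
            cycles += 1
            ok, state, F = _newton_solve(disc, state, target, probe, materials, config, free)
            if not ok or cycles > 20:
                converged_all = converged_all and ok
                break

        w_inc = 0.5 * (forces[-1] + F) * (target - depth)
        work.append(work[-1] + w_inc)
        eps = disc.strains(state.u)
        energy.append(disc.elastic_energy(eps, state.stress, state.eps_p, state.active))
        depth = target
        state.punch_depth = depth
        state.time = depth / probe.velocity if probe.velocity > 0 else 0.0
        depths.append(depth)
        forces.append(F)
        peak = max(peak, F)
        while snap_left and depth >= snap_left[0] - 1e-12:
            snap_left.pop(0)
            snapshots.append(_copy_state(state))
        if config.stop_after_drop is not None and peak > 0 and F < (1 - config.stop_after_drop) * peak:
            break
        inc += 1

    v = probe.velocity if probe.velocity > 0 else 1.0
    curve = ForceDeformationCurve(
        times=np.asarray(depths) / v,
        depths=np.asarray(depths),
        forces=np.maximum(np.asarray(forces), 0.0),
        source="simulated",
    )
    return SimulationResult(
        curve=curve,
        snapshots=snapshots,
        erosion_history=erosion_history,
        external_work=np.asarray(work),
        strain_energy=np.asarray(energy),
        converged=converged_all,
        diagnostics=diag,
    )


def _fixed_dofs(mesh: Mesh, config: SolverConfig) -> np.ndarray:
    fixed = [2 * mesh.axis_nodes()]  # u_r = 0 on the symmetry axis
    bottom = mesh.bottom_nodes()
    fixed.append(2 * bottom + 1)
    if config.bottom_fixed:
        fixed.append(2 * bottom)
    if config.outer_radial_fixed:
        fixed.append(2 * mesh.outer_nodes())
    return np.unique(np.concatenate(fixed))


def _newton_solve(disc, state: FieldState, punch_depth, probe, materials, config, free):
    """Newton iteration at fixed punch depth; returns (converged, state, reaction)."""
    mesh = disc.mesh
    u = state.u.copy()
    reaction = 0.0
    ref = None
    prev_rnorm = np.inf
    stalls = 0
    # dofs of fully eroded neighbourhoods have no stiffness; freeze them
    attached = np.unique(disc.dofs[state.active].ravel())
    free = np.intersect1d(free, attached, assume_unique=False)
    for it in range(config.newton_maxit):
        eps, stress, eps_p, ebar, D = disc.update_stress(
            u, state.eps_p, state.ebar_p, True, active=state.active
        )
        f_int = disc.internal_force(stress, state.active)
        f_c, nodes, pen, kpen, reaction = _contact_forces(
            punch_depth, mesh, u, state.active, probe, materials, config
        )
        R = f_c - f_int
        rnorm = np.linalg.norm(R[free])
        scale = max(np.linalg.norm(f_int[free]), reaction, 1e-12)
        if ref is None:
            ref = max(scale, 1.0)
        # accept at the roundoff floor: quadratic convergence has stalled but
        # the residual is already far below any physically meaningful force
        if rnorm >= 0.5 * prev_rnorm:
            stalls += 1
        else:
            stalls = 0
        prev_rnorm = rnorm
        at_floor = stalls >= 2 and rnorm <= 1e-6 * max(scale, 1e-6 * ref)
        if rnorm <= config.newton_tol * max(scale, 1e-6 * ref) or at_floor:
            new = FieldState(
                u=u, stress=stress, eps_p=eps_p, ebar_p=ebar,
                active=state.active, punch_depth=punch_depth, time=state.time,
            )
            return True, new, reaction
        K = disc.stiffness(D, state.active)
        # contact penalty stiffness on the penetrating nodes' z dofs
        if nodes.size:
            act = pen > 0
            zdofs = 2 * nodes[act] + 1
            K = K + sp.coo_matrix(
                (kpen[act], (zdofs, zdofs)), shape=K.shape
            ).tocsr()
        du = np.zeros(disc.ndof)
        Kff = K[free][:, free]
        du[free] = spla.spsolve(Kff.tocsc(), R[free])
        if not np.all(np.isfinite(du)):
            return False, state, reaction
        # backtracking line search on the residual norm
        step = 1.0
        base = rnorm
        for _ in range(5):
            u_try = (u.reshape(-1) + step * du).reshape(-1, 2)
            _, stress_t, _, _, _ = disc.update_stress(
                u_try, state.eps_p, state.ebar_p, False, active=state.active
            )
            f_int_t = disc.internal_force(stress_t, state.active)
            f_c_t, *_rest, _reac = _contact_forces(
                punch_depth, mesh, u_try, state.active, probe, materials, config
            )
            rn = np.linalg.norm((f_c_t - f_int_t)[free])
            if rn < base * (1 - 1e-4 * step) or step < 0.2:
                break
            step *= 0.5
        u = (u.reshape(-1) + step * du).reshape(-1, 2)
    return False, state, reaction


def _copy_state(state: FieldState) -> FieldState:
    return FieldState(
        u=state.u.copy(), stress=state.stress.copy(), eps_p=state.eps_p.copy(),
        ebar_p=state.ebar_p.copy(), active=state.active.copy(),
        punch_depth=state.punch_depth, time=state.time,
    )


# ---------------------------------------------------------------------------
# explicit driver
# ---------------------------------------------------------------------------

def stable_time_step(h: float, E: float, rho_solver: float, safety: float = 0.9) -> float:
    """CFL-stable explicit time step: safety * h / c with c = sqrt(E/rho).

    ``h`` in mm, ``E`` in MPa, ``rho_solver`` in tonne/mm^3; result in s.
    """
    c = np.sqrt(E / rho_solver)
    return safety * h / c


def _min_edge_lengths(mesh: Mesh) -> np.ndarray:
    xy = mesh.nodes[mesh.elems]
    edges = xy[:, [1, 2, 3, 0], :] - xy
    return np.linalg.norm(edges, axis=2).min(axis=1)


def solve_explicit(mesh: Mesh, materials: dict, probe: ProbeSpec,
                   config: SolverConfig) -> SimulationResult:
    """Explicit central-difference puncture dynamics with lumped mass.

    The punch advances at ``probe.velocity * config.time_scale``; the time
    step obeys the CFL bound per material with ``config.safety``.  Contact and
    erosion use the same operators as the quasi-static driver.  The reported
    force history is low-pass filtered with a moving average of
    ``config.filter_window`` samples (1 = unfiltered).  An energy-growth
    instability detector aborts with a diagnostic.
    """
    disc = _Discretisation(mesh, materials)
    state = FieldState.zero(mesh)
    fixed = _fixed_dofs(mesh, config)
    free_mask = np.ones(disc.ndof, dtype=bool)
    free_mask[fixed] = False

    m_node = disc.lumped_mass()
    m_dof = np.repeat(m_node, 2)
    h_min = _min_edge_lengths(mesh).min()
    dt = min(
        stable_time_step(h_min, m_.E, m_.rho_solver, config.safety)
        for m_ in materials.values()
    )
    # contact penalty springs also bound the stable step: dt < 2*sqrt(m/k)
    nodes0 = _surface_candidates(mesh, state.active, probe.radius)
    if nodes0.size:
        k0 = _penalty_stiffnesses(mesh, nodes0, materials, config)
        dt_contact = config.safety * np.sqrt(m_node[nodes0] / k0).min()
        dt = min(dt, dt_contact)
    v_punch = probe.velocity * config.time_scale
    t_end = probe.max_insertion / v_punch if v_punch > 0 else 200 * dt
    n_steps = int(np.ceil(t_end / dt))

    u = np.zeros(disc.ndof)
    v = np.zeros(disc.ndof)
    times, depths, forces = [0.0], [0.0], [0.0]
    work = [0.0]
    energy = [0.0]
    erosion_history = []
    snapshots = []
    snap_left = sorted(config.snapshot_depths)
    prev_reaction = 0.0
    prev_depth = 0.0
    W = 0.0

    for step in range(1, n_steps + 1):
        t = step * dt
        punch_depth = min(v_punch * t, probe.max_insertion)
        eps, stress, eps_p, ebar, _ = disc.update_stress(
            u.reshape(-1, 2), state.eps_p, state.ebar_p, False, active=state.active
        )
        state.stress, state.eps_p, state.ebar_p = stress, eps_p, ebar
        f_int = disc.internal_force(stress, state.active)
        f_c, nodes, pen, kpen, reaction = _contact_forces(
            punch_depth, mesh, u.reshape(-1, 2), state.active, probe, materials, config
        )
        a = (f_c - f_int - config.damping * m_dof * v) / m_dof
        a[~free_mask] = 0.0
        v = v + dt * a
        u = u + dt * v
        if not np.all(np.isfinite(u)) or np.abs(u).max() > 10 * mesh.spec.depth:
            return _explicit_result(
                times, depths, forces, work, energy, snapshots, erosion_history,
                config, converged=False,
                diag={"aborted_at_step": step, "reason": "instability detected"},
            )
        newly = erode_elements(state, config)
        if newly.size:
            erosion_history.append((punch_depth, newly))
        W += 0.5 * (prev_reaction + reaction) * (punch_depth - prev_depth)
        prev_reaction, prev_depth = reaction, punch_depth
        if step % config.record_every == 0 or step == n_steps:
            times.append(t)
            depths.append(punch_depth)
            forces.append(max(reaction, 0.0))
            work.append(W)
            energy.append(disc.elastic_energy(eps, stress, eps_p, state.active))
            while snap_left and punch_depth >= snap_left[0] - 1e-12:
                snap_left.pop(0)
                state.u = u.reshape(-1, 2).copy()
                state.punch_depth, state.time = punch_depth, t
                snapshots.append(_copy_state(state))
    state.u = u.reshape(-1, 2)
    return _explicit_result(
        times, depths, forces, work, energy, snapshots, erosion_history, config,
        converged=True, diag={"dt": dt, "n_steps": n_steps},
    )


def _explicit_result(times, depths, forces, work, energy, snapshots,
                     erosion_history, config, converged, diag):
    f = np.asarray(forces)
    if config.filter_window > 1:
        from .metrics import _moving_average

        f = _moving_average(f, config.filter_window)
    curve = ForceDeformationCurve(
        times=np.asarray(times), depths=np.asarray(depths),
        forces=np.maximum(f, 0.0), source="simulated",
    )
    return SimulationResult(
        curve=curve, snapshots=snapshots, erosion_history=erosion_history,
        external_work=np.asarray(work), strain_energy=np.asarray(energy),
        converged=converged, diagnostics=diag,
    )
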