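"""Transient Biot poroelasticity on axisymmetric sections.

Small-strain linear Biot consolidation with Biot coefficient 1 and
incompressible constituents (all volume change is fluid exchange):

    div(sigma') - grad p = 0,         sigma' = 2 mu eps + lam tr(eps) I
    d/dt div(u) + div(q) = 0,         q = -k grad p          (Darcy)

``p`` is the pore pressure above the ambient reference; the initial state
(uniform pressure ``p0``, zero displacement) is treated as a pre-stressed
equilibrium, so the solver computes deviations from it and reports the
total pressure ``p0 + p_dev``.  The effective-stress sign convention is
sigma' = sigma_total + p I on the drained skeleton.

Discretisation: Taylor-Hood Q9/Q4 quadrilaterals (quadratic displacement,
bilinear pressure — inf-sup stable), implicit (backward Euler) time
stepping with per-step-size LU factorisation reuse.  Units: um, s, Pa, nN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._fem import GAUSS_PTS, GAUSS_WTS, shape_q4, shape_q9
from .materials import MaterialRegion
from .mesh import Mesh

__all__ = [
    "MechanicalBC",
    "HydraulicBC",
    "BoundarySpec",
    "TransientSolution",
    "SolverError",
    "solve_transient",
    "terzaghi_reference",
    "terzaghi_consolidation_degree",
    "darcy_flux",
    "ramp_hold_times",
]

_TWO_PI = 2.0 * np.pi
_FORCE_TO_NN = 1.0e-3  # Pa * um^2 = pN; 1 nN = 1000 pN


class SolverError(RuntimeError):
    """Raised when the coupled system cannot be solved; carries step index."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


@dataclass
class MechanicalBC:
    """Mechanical condition on (part of) a boundary segment.

    kind:
        ``fixed`` (u = 0), ``free``, ``prescribed_uz`` (vertical displacement
        ``value`` [um] ramped over ``ramp_time``), or ``traction`` (normal
        pressure load ``value`` [Pa] pressing against the surface, ramped).
    r_min / r_max:
        Restrict the condition to nodes with r in [r_min, r_max] (patches
        on the top surface, e.g. the indenter contact).
    """

    kind: str
    value: float = 0.0
    ramp_time: float = 0.0
    r_min: float | None = None
    r_max: float | None = None
    #: optional radial shape of a prescribed displacement: node value =
    #: value * profile(r) (e.g. a spherical-indenter penetration profile)
    profile: object = None

    def ramp(self, t: float) -> float:
        if self.ramp_time <= 0.0:
            return 1.0 if t > 0 else 0.0
        return min(t / self.ramp_time, 1.0)


@dataclass
class HydraulicBC:
    """Hydraulic condition: ``impermeable`` (natural) or ``fixed_pore_pressure``
    with total pressure ``value`` [Pa] ramped over ``ramp_time``; patch
    restriction as in :class:`MechanicalBC`."""

    kind: str
    value: float = 0.0
    ramp_time: float = 0.0
    r_min: float | None = None
    r_max: float | None = None

    def ramp(self, t: float) -> float:
        if self.ramp_time <= 0.0:
            return 1.0 if t > 0 else 0.0
        return min(t / self.ramp_time, 1.0)


@dataclass
class BoundarySpec:
    """Per-segment mechanical and hydraulic conditions.

    Each exterior segment name (``axis``, ``rim``, ``bottom``, ``top``) maps
    to one condition or a list of patch conditions.  The symmetry axis
    always carries u_r = 0 in addition to whatever is specified; segments
    not mentioned are free and impermeable.
    """

    mech: dict[str, MechanicalBC | list[MechanicalBC]] = field(default_factory=dict)
    hyd: dict[str, HydraulicBC | list[HydraulicBC]] = field(default_factory=dict)

    def mech_list(self, seg: str) -> list[MechanicalBC]:
        v = self.mech.get(seg, MechanicalBC("free"))
        return v if isinstance(v, list) else [v]

    def hyd_list(self, seg: str) -> list[HydraulicBC]:
        v = self.hyd.get(seg, HydraulicBC("impermeable"))
        return v if isinstance(v, list) else [v]


@dataclass
class TransientSolution:
    """Node-wise displacement and pore-pressure history plus reaction force.

    ``p`` holds the total pore pressure (initial pressure plus deviation)
    at the corner-node pressure dofs; ``force`` is the vertical reaction on
    the prescribed-displacement patch [nN], positive when the indenter
    pushes down on the material.
    """

    times: np.ndarray
    u: np.ndarray  # (nt, n_nodes, 2) [um]
    p: np.ndarray  # (nt, n_pnodes) [Pa], total
    force: np.ndarray  # (nt,) [nN]
    mesh: Mesh
    initial_pressure: float
    balance_residual: np.ndarray = None  # (nt,) per-step global fluid balance
    max_dp_per_step: np.ndarray = None
    _ctx: dict = field(default_factory=dict, repr=False)

    def pressure_at_nodes(self, node_ids: np.ndarray, t_index: int = -1) -> np.ndarray:
        pdofs = self.mesh.pmap[node_ids]
        if np.any(pdofs < 0):
            raise ValueError("pressure is carried on corner nodes only")
        return self.p[t_index, pdofs]

    def surface_uz(self, t_index: int | slice = slice(None)) -> tuple[np.ndarray, np.ndarray]:
        """Top-surface radii and vertical displacement at the given time(s)."""
        ids, r = self.mesh.top_surface()
        return r, self.u[t_index, ids, 1]

    def boundary_inflow(self, node_ids: np.ndarray, t_index: int = -1) -> float:
        """Discrete fluid inflow [um^3/s] through the given fixed-pressure nodes.

        Evaluated from the continuity-equation residual at the Dirichlet
        pressure dofs (positive = fluid entering the domain).
        """
        QT, H = self._ctx["QT"], self._ctx["H"]
        i = t_index % len(self.times)
        if i == 0:
            raise ValueError("no inflow defined at the initial instant")
        dt = self.times[i] - self.times[i - 1]
        du = (self.u[i] - self.u[i - 1]).ravel() / dt
        pdev = self.p[i] - self.initial_pressure
        resid = QT @ du + H @ pdev
        pdofs = self.mesh.pmap[node_ids]
        pdofs = pdofs[pdofs >= 0]
        return float(resid[pdofs].sum()) * _TWO_PI


def _elastic_c(mat: MaterialRegion) -> np.ndarray:
    """Drained stiffness in (e_rr, e_zz, g_rz, e_tt) order."""
    lam, mu = mat.lam, mat.mu
    c = np.array(
        [
            [lam + 2 * mu, lam, 0.0, lam],
            [lam, lam + 2 * mu, 0.0, lam],
            [0.0, 0.0, mu, 0.0],
            [lam, lam, 0.0, lam + 2 * mu],
        ]
    )
    return c


def _materials_by_region(mesh: Mesh, materials: list[MaterialRegion]) -> list[MaterialRegion]:
    by_label = {m.label: m for m in materials}
    regions = np.unique(mesh.region)
    out = {}
    for rid in regions:
        label = "cytoplasm" if rid == 0 else "cortex"
        if label not in by_label:
            raise ValueError(f"no material given for region {label!r}")
        out[rid] = by_label[label]
    return out


def assemble(mesh: Mesh, materials: list[MaterialRegion]):
    """Assemble global stiffness K, coupling Q and permeability H matrices.

    K: (2n x 2n), Q: (2n x np) with Q_ij = int div(N_i) M_j r dA,
    H: (np x np) with H_ij = int k grad(M_i).grad(M_j) r dA
    (the common 2*pi factor is dropped consistently).
    """
    mats = _materials_by_region(mesh, materials)
    cmats = {rid: _elastic_c(m) for rid, m in mats.items()}
    kvals = {rid: m.k for rid, m in mats.items()}
    Ce = np.stack([cmats[rid] for rid in mesh.region])
    ke = np.array([kvals[rid] for rid in mesh.region])

    xe = mesh.coords[mesh.elems]  # (ne, 9, 2)
    ne = mesh.n_elems
    Kel = np.zeros((ne, 18, 18))
    Qel = np.zeros((ne, 18, 4))
    Hel = np.zeros((ne, 4, 4))

    for (xi, eta), w in zip(GAUSS_PTS, GAUSS_WTS):
        N9, dN9 = shape_q9(xi, eta)
        N4, dN4 = shape_q4(xi, eta)
        J = np.einsum("ai,eaj->eij", dN9, xe)  # J[i,j] = dx_j/dxi_i
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        Jinv = np.empty_like(J)
        Jinv[:, 0, 0] = J[:, 1, 1] / detJ
        Jinv[:, 1, 1] = J[:, 0, 0] / detJ
        Jinv[:, 0, 1] = -J[:, 0, 1] / detJ
        Jinv[:, 1, 0] = -J[:, 1, 0] / detJ
        # dN/dx_j = sum_i dN/dxi_i * (J^-1)[j, i]
        dN9x = np.einsum("ai,eji->eaj", dN9, Jinv)
        dN4x = np.einsum("ai,eji->eaj", dN4, Jinv)
        rg = xe[:, :, 0] @ N9
        wg = w * np.abs(detJ) * rg

        br, bz = dN9x[:, :, 0], dN9x[:, :, 1]
        bt = N9[None, :] / rg[:, None]
        B = np.zeros((ne, 4, 18))
        B[:, 0, 0::2] = br
        B[:, 1, 1::2] = bz
        B[:, 2, 0::2] = bz
        B[:, 2, 1::2] = br
        B[:, 3, 0::2] = bt
        CB = np.einsum("ecd,edj->ecj", Ce, B)
        Kel += wg[:, None, None] * np.einsum("eci,ecj->eij", B, CB)

        div = np.zeros((ne, 18))
        div[:, 0::2] = br + bt
        div[:, 1::2] = bz
        Qel += wg[:, None, None] * div[:, :, None] * N4[None, None, :]
        Hel += (wg * ke)[:, None, None] * np.einsum("eai,ebi->eab", dN4x, dN4x)

    n = mesh.n_nodes
    udof = np.empty((ne, 18), dtype=np.int64)
    udof[:, 0::2] = 2 * mesh.elems
    udof[:, 1::2] = 2 * mesh.elems + 1
    pdof = mesh.pmap[mesh.elems[:, :4]]

    def scatter(el, rows, cols, shape):
        return sp.coo_matrix(
            (
                el.ravel(),
                (
                    np.broadcast_to(rows[:, :, None], el.shape).ravel(),
                    np.broadcast_to(cols[:, None, :], el.shape).ravel(),
                ),
            ),
            shape=shape,
        ).tocsr()

    K = scatter(Kel, udof, udof, (2 * n, 2 * n))
    Q = scatter(Qel, udof, pdof, (2 * n, mesh.n_pnodes))
    H = scatter(Hel, pdof, pdof, (mesh.n_pnodes, mesh.n_pnodes))
    return K, Q, H


def _segment_edges(mesh: Mesh, seg: str) -> np.ndarray:
    """Quadratic edge connectivity (n_edges, 3) of a boundary segment."""
    ids = mesh.boundary[seg]
    if seg in ("top", "bottom"):
        order = np.argsort(mesh.coords[ids, 0])
    else:
        order = np.argsort(mesh.coords[ids, 1])
    ids = ids[order]
    n_ed = (len(ids) - 1) // 2
    return np.stack([ids[0:-2:2], ids[1:-1:2], ids[2::2]], axis=1)


def _edge_load_vector(mesh: Mesh, seg: str, bc: MechanicalBC) -> np.ndarray:
    """Unit nodal force vector of a normal pressure load on a segment patch."""
    f = np.zeros(2 * mesh.n_nodes)
    gx, gw = np.polynomial.legendre.leggauss(3)
    for edge in _segment_edges(mesh, seg):
        xe = mesh.coords[edge]
        rmid = xe[1, 0]
        if bc.r_max is not None and rmid > bc.r_max:
            continue
        if bc.r_min is not None and rmid < bc.r_min:
            continue
        for s, w in zip(gx, gw):
            L = np.array([0.5 * s * (s - 1), 1 - s * s, 0.5 * s * (s + 1)])
            dL = np.array([s - 0.5, -2 * s, s + 0.5])
            x = L @ xe
            tvec = dL @ xe
            nvec = np.array([tvec[1], -tvec[0]])
            # outward normal: +z-ish on top, -z on bottom, +r on rim
            ref = {"top": (0, 1), "bottom": (0, -1), "rim": (1, 0), "axis": (-1, 0)}[seg]
            if nvec @ ref < 0:
                nvec = -nvec
            nrm = np.linalg.norm(nvec)
            unit_n = nvec / nrm
            # pressure load of unit magnitude presses against the surface
            fvec = -unit_n
            for a in range(3):
                f[2 * edge[a]] += w * L[a] * fvec[0] * x[0] * nrm
                f[2 * edge[a] + 1] += w * L[a] * fvec[1] * x[0] * nrm
    return f


def _patch_nodes(mesh: Mesh, seg: str, r_min: float | None, r_max: float | None) -> np.ndarray:
    ids = mesh.boundary[seg]
    r = mesh.coords[ids, 0]
    keep = np.ones(len(ids), dtype=bool)
    tol = 1e-9 * max(1.0, mesh.geometry.radius)
    if r_min is not None:
        keep &= r >= r_min - tol
    if r_max is not None:
        keep &= r <= r_max + tol
    return ids[keep]


def solve_transient(
    mesh: Mesh,
    materials: list[MaterialRegion],
    bcs: BoundarySpec,
    time_grid: np.ndarray,
    initial_pressure: float = 0.0,
) -> TransientSolution:
    """Run the implicit coupled Biot solve over the given time grid.

    The time grid must start at 0 (the pre-stressed reference state).  LU
    factorisations are reused across steps of equal size.  Raises
    :class:`SolverError` for singular systems (e.g. no mechanical
    constraint beyond the symmetry axis) or failed steps.
    """
    times = np.asarray(time_grid, dtype=float)
    if times[0] != 0.0:
        raise ValueError("time grid must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")

    K, Q, H = assemble(mesh, materials)
    n = mesh.n_nodes
    npn = mesh.n_pnodes
    ndof = 2 * n + npn

    # --- Dirichlet constraints: (dof index, base value, ramp fn) ------------
    con_dofs: list[np.ndarray] = []
    con_vals: list[np.ndarray] = []
    con_bcs: list = []
    force_dofs: list[np.ndarray] = []

    axis_ids = mesh.boundary["axis"]
    con_dofs.append(2 * axis_ids)
    con_vals.append(np.zeros(len(axis_ids)))
    con_bcs.append(None)

    tractions: list[tuple[np.ndarray, MechanicalBC]] = []
    any_mech_fix = False
    for seg in mesh.boundary:
        for bc in bcs.mech_list(seg):
            if bc.kind == "free":
                continue
            if bc.kind == "traction":
                tractions.append((_edge_load_vector(mesh, seg, bc), bc))
                continue
            ids = _patch_nodes(mesh, seg, bc.r_min, bc.r_max)
            if bc.kind == "fixed":
                any_mech_fix = True
                dofs = np.concatenate([2 * ids, 2 * ids + 1])
                con_dofs.append(dofs)
                con_vals.append(np.zeros(len(dofs)))
                con_bcs.append(None)
            elif bc.kind in ("fixed_ur", "fixed_uz"):
                any_mech_fix = any_mech_fix or bc.kind == "fixed_uz"
                dofs = 2 * ids if bc.kind == "fixed_ur" else 2 * ids + 1
                con_dofs.append(dofs)
                con_vals.append(np.zeros(len(dofs)))
                con_bcs.append(None)
            elif bc.kind == "prescribed_uz":
                any_mech_fix = True
                con_dofs.append(2 * ids + 1)
                shape = (
                    np.ones(len(ids))
                    if bc.profile is None
                    else np.asarray([bc.profile(r) for r in mesh.coords[ids, 0]])
                )
                con_vals.append(bc.value * shape)
                con_bcs.append(bc)
                force_dofs.append(2 * ids + 1)
            else:
                raise ValueError(f"unknown mechanical condition {bc.kind!r}")
    if not any_mech_fix:
        raise SolverError("singular system: no mechanical constraint beyond the axis")

    for seg in mesh.boundary:
        for bc in bcs.hyd_list(seg):
            if bc.kind == "impermeable":
                continue
            if bc.kind != "fixed_pore_pressure":
                raise ValueError(f"unknown hydraulic condition {bc.kind!r}")
            ids = _patch_nodes(mesh, seg, bc.r_min, bc.r_max)
            pd = mesh.pmap[ids]
            pd = pd[pd >= 0]
            con_dofs.append(2 * n + pd)
            # solver works in pressure deviation from the reference state
            con_vals.append(np.full(len(pd), bc.value - initial_pressure))
            con_bcs.append(bc)

    # later entries win on duplicates
    order = {}
    for group, dofs in enumerate(con_dofs):
        for j, d in enumerate(dofs):
            order[int(d)] = (group, j)
    con_idx = np.array(sorted(order), dtype=np.int64)
    free_idx = np.setdiff1d(np.arange(ndof), con_idx)

    def constrained_values(t: float) -> np.ndarray:
        vals = np.zeros(len(con_idx))
        for i, d in enumerate(con_idx):
            group, j = order[d]
            bc = con_bcs[group]
            ramp = 1.0 if bc is None else bc.ramp(t)
            vals[i] = con_vals[group][j] * ramp
        return vals

    A = sp.bmat([[K, -Q], [Q.T, None]], format="csr")
    QT = Q.T.tocsr()
    Hpad = sp.bmat(
        [[sp.csr_matrix((2 * n, 2 * n)), None], [None, H]], format="csr"
    )

    nt = len(times)
    u = np.zeros((nt, n, 2))
    pdev = np.zeros((nt, npn))
    force = np.zeros(nt)
    balance = np.zeros(nt)
    max_dp = np.zeros(nt)

    factor_cache: dict[float, tuple] = {}
    x_prev = np.zeros(ndof)

    for step in range(1, nt):
        t1 = times[step]
        dt = t1 - times[step - 1]
        key = round(float(dt), 14)
        if key not in factor_cache:
            Adt = (A + dt * Hpad).tocsc()
            Aff = Adt[free_idx][:, free_idx]
            Afc = Adt[free_idx][:, con_idx]
            try:
                lu = spla.splu(Aff.tocsc())
            except RuntimeError as exc:  # pragma: no cover - singular systems
                raise SolverError(f"factorisation failed: {exc}", step=step)
            factor_cache[key] = (lu, Afc)
        lu, Afc = factor_cache[key]

        fvec = np.zeros(2 * n)
        for fv, bc in tractions:
            fvec += bc.value * bc.ramp(t1) * fv
        rhs_full = np.concatenate([fvec, QT @ x_prev[: 2 * n]])
        xc = constrained_values(t1)
        x = np.empty(ndof)
        x[con_idx] = xc
        xf = lu.solve(rhs_full[free_idx] - Afc @ xc)
        if not np.all(np.isfinite(xf)):
            raise SolverError("non-finite solution", step=step)
        x[free_idx] = xf

        u[step] = x[: 2 * n].reshape(n, 2)
        pdev[step] = x[2 * n :]
        max_dp[step] = np.max(np.abs(pdev[step] - pdev[step - 1])) if npn else 0.0
        # global fluid balance: continuity residual summed over free p dofs
        resid = QT @ ((x[: 2 * n] - x_prev[: 2 * n]) / dt) + H @ x[2 * n :]
        free_p = free_idx[free_idx >= 2 * n] - 2 * n
        balance[step] = np.abs(resid[free_p]).max() if len(free_p) else 0.0

        if force_dofs:
            react = K @ x[: 2 * n] - Q @ x[2 * n :] - fvec
            fd = np.unique(np.concatenate(force_dofs))
            force[step] = -react[fd].sum() * _TWO_PI * _FORCE_TO_NN
        x_prev = x

    sol = TransientSolution(
        times=times,
        u=u,
        p=pdev + initial_pressure,
        force=force,
        mesh=mesh,
        initial_pressure=initial_pressure,
        balance_residual=balance,
        max_dp_per_step=max_dp,
        _ctx={"K": K, "Q": Q, "H": H, "QT": QT},
    )
    return sol


def darcy_flux(solution: TransientSolution, materials: list[MaterialRegion], t_index: int = -1):
    """Element-centroid Darcy flux q = -k grad p [um/s], shape (n_elems, 2)."""
    mesh = solution.mesh
    mats = _materials_by_region(mesh, materials)
    ke = np.array([mats[rid].k for rid in mesh.region])
    xe = mesh.coords[mesh.elems]
    N9, dN9 = shape_q9(0.0, 0.0)
    _, dN4 = shape_q4(0.0, 0.0)
    J = np.einsum("ai,eaj->eij", dN9, xe)
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    Jinv = np.empty_like(J)
    Jinv[:, 0, 0] = J[:, 1, 1] / detJ
    Jinv[:, 1, 1] = J[:, 0, 0] / detJ
    Jinv[:, 0, 1] = -J[:, 0, 1] / detJ
    Jinv[:, 1, 0] = -J[:, 1, 0] / detJ
    dN4x = np.einsum("ai,eji->eaj", dN4, Jinv)
    pel = solution.p[t_index][mesh.pmap[mesh.elems[:, :4]]]
    gradp = np.einsum("eaj,ea->ej", dN4x, pel)
    return -ke[:, None] * gradp


def terzaghi_reference(
    q: float, column_height: float, D: float, z: float | np.ndarray, t: float, tol: float = 1e-12
):
    """Closed-form 1D consolidation (Terzaghi) pore pressure [Pa].

    Column of height H drained at the top (z = H), impermeable at the base
    (z = 0), loaded by a step normal stress ``q`` at t = 0.  Returns the
    classical series solution; ``q`` at t -> 0+ (undrained) and 0 at
    t -> infinity.  The series is truncated once terms fall below ``tol * q``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > column_height):
        raise ValueError("z outside the column")
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0.0:
        return np.where(z < column_height, q, 0.0)
    Tv = D * t / column_height**2
    p = np.zeros_like(z)
    m = 1
    while True:
        amp = 4.0 * q / (np.pi * m) * np.exp(-(m**2) * np.pi**2 * Tv / 4.0)
        p = p + amp * np.sin(m * np.pi * (column_height - z) / (2.0 * column_height))
        if abs(amp) < tol * abs(q) or m > 20001:
            break
        m += 2
    return p


def terzaghi_consolidation_degree(Tv: float, tol: float = 1e-14) -> float:
    """Average degree of consolidation U(Tv) of the Terzaghi column."""
    s = 0.0
    m = 1
    while True:
        term = 8.0 / (np.pi**2 * m**2) * np.exp(-(m**2) * np.pi**2 * Tv / 4.0)
        s += term
        if term < tol or m > 20001:
            break
        m += 2
    return 1.0 - s


def ramp_hold_times(
    ramp_time: float,
    t_end: float,
    n_ramp: int = 5,
    dt0: float | None = None,
    growth: float = 1.3,
    dt_max: float | None = None,
) -> np.ndarray:
    """Time grid: uniform steps through the ramp, geometric growth after.

    ``dt0`` is the first hold-phase step (default: the ramp step); the
    step size grows by ``growth`` per step up to the optional cap
    ``dt_max``, which bounds the backward-Euler error at late times.
    """
    if ramp_time <= 0:
        ramp_times = np.array([0.0])
        dt = dt0 if dt0 is not None else t_end / 200.0
    else:
        ramp_times = np.linspace(0.0, ramp_time, n_ramp + 1)
        dt = dt0 if dt0 is not None else ramp_time / n_ramp
    times = list(ramp_times)
    t = times[-1]
    while t < t_end:
        t = min(t + dt, t_end)
        times.append(t)
        dt *= growth
        if dt_max is not None:
            dt = min(dt, dt_max)
    return np.array(times)
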