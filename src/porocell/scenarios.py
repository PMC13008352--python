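"""The three in-silico cell experiments built on the Biot solver.

* **Indentation**: a rigid spherical indenter (radius R) pushed ~2 um into a
  20 x 20 um cylindrical disk with a no-slip base; drained free surface,
  frictionless impermeable contact.  Observables: hold-phase force
  relaxation and the steady-state surface displacement vs distance from
  the tip.
* **Microinjection**: fluid driven into an axisymmetric elliptical-cap cell
  (40 um diameter, 4.5 um thick) through a pipette patch held at
  P_app > P_in; observables: bead displacement vs distance at a given time
  and time lags of movement onset (10%-of-steady-state rule).
* **Depressurisation**: the same cap wrapped in a thin low-permeability
  membrane-cortex layer, with a small sink patch held at P_app < P_in and
  the remaining outer boundary held at the reservoir pressure P_in
  (trans-membrane influx); observable: the steady-state intracellular
  pressure profile vs distance from the sink, for a sweep of cortex
  diffusion constants D1.

The contact problem is simplified to a prescribed rigid-sphere penetration
profile u_z(r) = -(delta - r^2/(2R)) over the geometric contact patch
a = sqrt(2 R delta) — edge-continuous, so no contact solver is needed;
probe displacements are interpolated at the undeformed surface radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .biot import (
    BoundarySpec,
    HydraulicBC,
    MechanicalBC,
    TransientSolution,
    ramp_hold_times,
    solve_transient,
)
from .estimators import BeadTrace, time_lag
from .materials import MaterialRegion
from .mesh import ScenarioGeometry, build_mesh

__all__ = [
    "IndentationProtocol",
    "PressureProtocol",
    "SurfaceResponse",
    "simulate_indentation",
    "simulate_injection",
    "simulate_depressurisation",
    "graded_breaks",
]


@dataclass
class IndentationProtocol:
    """Ramp-and-hold indentation: depth [um], ramp and hold durations [s]."""

    depth: float
    ramp_time: float = 0.01
    hold_time: float = 30.0
    indenter_radius: float = 2.0

    def __post_init__(self) -> None:
        if not self.depth >= 0:
            raise ValueError("depth must be >= 0")
        if not self.ramp_time > 0:
            raise ValueError("ramp_time must be positive")

    @property
    def contact_radius(self) -> float:
        """Geometric contact patch radius a = sqrt(2 R delta) [um]: the
        radius at which the penetrating rigid sphere meets the undeformed
        surface."""
        return float(np.sqrt(2.0 * self.indenter_radius * self.depth))


@dataclass
class PressureProtocol:
    """Pressure step at the pipette: internal and applied pressure [Pa]."""

    P_in: float
    P_app: float
    ramp_time: float = 2.0
    duration: float = 40.0
    mode: str = "injection"

    def __post_init__(self) -> None:
        if self.mode not in ("injection", "release"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "injection" and not self.P_app > self.P_in:
            raise ValueError("injection requires P_app > P_in")
        if self.mode == "release" and not self.P_app < self.P_in:
            raise ValueError("release requires P_app < P_in")

    @property
    def P_eff(self) -> float:
        return self.P_app - self.P_in


@dataclass
class SurfaceResponse:
    """Observables of one scenario run.

    ``displacement`` holds the probe z-displacement [um] over time (nt x
    n_probes); ``steady_profile`` the final surface displacement vs radius;
    ``time_lags`` the 10%-of-steady-state onset lags per probe (injection);
    ``pressure_profile`` a (distance, pressure) steady profile
    (depressurisation); ``force`` the indenter reaction [nN] (indentation).
    """

    probe_distances: np.ndarray
    times: np.ndarray
    displacement: np.ndarray
    steady_profile: tuple[np.ndarray, np.ndarray]
    force: np.ndarray | None = None
    time_lags: np.ndarray | None = None
    pressure_profile: tuple[np.ndarray, np.ndarray] | None = None
    steady_reached: bool = True
    params: dict = field(default_factory=dict)
    solution: TransientSolution | None = None

    def probe_traces(self) -> list[BeadTrace]:
        return [
            BeadTrace(self.times[1:], self.displacement[1:, j], float(x))
            for j, x in enumerate(self.probe_distances)
        ]


def graded_breaks(a: float, R: float, n_in: int = 2, growth: float = 1.35) -> np.ndarray:
    """Radial element boundaries: uniform inside the patch [0, a], widths
    growing geometrically outside up to R (rescaled to fit exactly)."""
    inner = np.linspace(0.0, a, n_in + 1)
    w = a / n_in
    widths = []
    pos = a
    while pos < R:
        w *= growth
        widths.append(w)
        pos += w
    widths = np.asarray(widths)
    widths *= (R - a) / widths.sum()
    return np.concatenate([inner, a + np.cumsum(widths)])


def _is_steady(times: np.ndarray, series: np.ndarray, rel_tol: float = 0.01) -> bool:
    """Relative change of the series over the final 5% of the window < tol."""
    t_lo = times[-1] - 0.05 * (times[-1] - times[0])
    sel = times >= t_lo
    window = np.atleast_2d(series[sel].T)
    scale = np.max(np.abs(series)) or 1.0
    change = np.max(np.abs(window[:, -1] - window[:, 0]))
    return bool(change <= rel_tol * scale)


def _probe_series(sol: TransientSolution, probes: np.ndarray) -> np.ndarray:
    ids, r = sol.mesh.top_surface()
    out = np.empty((len(sol.times), len(probes)))
    for i in range(len(sol.times)):
        out[i] = np.interp(probes, r, sol.u[i, ids, 1])
    return out


def simulate_indentation(
    geometry: ScenarioGeometry,
    materials: list[MaterialRegion],
    protocol: IndentationProtocol,
    probes: np.ndarray | None = None,
    resolution: float = 2.0,
    n_z: int = 8,
    z_bias: float = 4.0,
    n_ramp: int = 4,
    dt0: float = 0.01,
    growth: float = 1.25,
    dt_max: float | None = None,
) -> SurfaceResponse:
    """AFM indentation of the disk: ramp-hold force relaxation and the
    steady-state surface displacement profile.

    The contact is a prescribed spherical penetration profile over the
    geometric patch a = sqrt(2 R delta) (frictionless, impermeable); the
    free top surface is drained (p = 0), the no-slip base and the rim are
    impermeable.  Auto-extends the hold once if no steady state is reached.
    """
    if geometry.shape != "disk":
        raise ValueError("indentation runs on the disk geometry")
    if protocol.depth > geometry.thickness / 2.0:
        raise ValueError("indentation depth exceeds half the thickness (small-strain validity)")
    a = protocol.contact_radius
    if probes is None:
        probes = np.linspace(a, 0.8 * geometry.radius, 12)
    probes = np.asarray(probes, dtype=float)

    if protocol.depth == 0.0:
        times = ramp_hold_times(protocol.ramp_time, protocol.hold_time, n_ramp, dt0, growth)
        zero = np.zeros((len(times), len(probes)))
        ids_r = np.linspace(0, geometry.radius, 16)
        return SurfaceResponse(probes, times, zero, (ids_r, np.zeros_like(ids_r)),
                               force=np.zeros(len(times)))

    n_in = max(2, int(np.ceil(2.0 * a / resolution)))
    mesh = build_mesh(
        geometry, resolution,
        r_breaks=graded_breaks(a, geometry.radius, n_in=n_in), n_z=n_z,
        z_bias=z_bias,
    )
    mat = [m for m in materials if m.label == "cytoplasm"][0]
    bcs = BoundarySpec(
        mech={
            "bottom": MechanicalBC("fixed"),
            "top": MechanicalBC(
                "prescribed_uz", value=-protocol.depth,
                ramp_time=protocol.ramp_time, r_max=a,
                # rigid-sphere penetration shape: delta - r^2 / (2 R)
                profile=lambda r, a2=a**2: 1.0 - r**2 / a2,
            ),
        },
        hyd={"top": HydraulicBC("fixed_pore_pressure", value=0.0, r_min=a * (1 + 1e-9))},
    )
    t_relax = a**2 / mat.D

    def run(t_end):
        times = ramp_hold_times(
            protocol.ramp_time, t_end, n_ramp,
            dt0=min(dt0, 0.2 * t_relax), growth=growth,
            dt_max=dt_max if dt_max is not None else 0.05 * t_end,
        )
        return solve_transient(mesh, materials, bcs, times)

    sol = run(protocol.hold_time)
    ids, r_surf = mesh.top_surface()
    steady = _is_steady(sol.times, sol.u[:, ids, 1])
    if not steady:
        sol = run(2.0 * protocol.hold_time)
        steady = _is_steady(sol.times, sol.u[:, ids, 1])

    disp = _probe_series(sol, probes)
    return SurfaceResponse(
        probe_distances=probes,
        times=sol.times,
        displacement=disp,
        steady_profile=(r_surf, sol.u[-1, ids, 1]),
        force=sol.force,
        steady_reached=steady,
        params={"contact_radius": a, "E": mat.E, "D": mat.D},
        solution=sol,
    )


def _pressure_cap_run(
    geometry: ScenarioGeometry,
    materials: list[MaterialRegion],
    protocol: PressureProtocol,
    membrane_reservoir: bool,
    resolution: float,
    n_z: int,
    dt0: float,
    growth: float,
    dt_max: float | None,
    t_end: float | None = None,
) -> TransientSolution:
    r_pat = geometry.contact_or_sink_radius
    n_in = max(2, int(np.ceil(2.0 * r_pat / resolution)))
    mesh = build_mesh(
        geometry, resolution,
        r_breaks=graded_breaks(r_pat, geometry.radius, n_in=n_in), n_z=n_z,
    )
    if membrane_reservoir and geometry.cortex_thickness > 0:
        # the pipette establishes a whole-cell fluidic connection: the
        # membrane-cortex layer is breached under the sink patch
        cent_r = mesh.coords[mesh.elems[:, 8], 0]
        mesh.region[(mesh.region == 1) & (cent_r <= r_pat)] = 0
    hyd_top: list[HydraulicBC] = [
        HydraulicBC(
            "fixed_pore_pressure", value=protocol.P_app,
            ramp_time=protocol.ramp_time, r_max=r_pat,
        )
    ]
    if membrane_reservoir:
        # reservoir at P_in on the outer surface away from the sink: one
        # element-row gap keeps the two Dirichlet patches apart
        ids, r_surf = mesh.top_surface()
        gap = r_surf[r_surf > r_pat * (1 + 1e-9)]
        r_start = gap[2] if len(gap) > 2 else r_pat * 1.5
        hyd_top.append(
            HydraulicBC("fixed_pore_pressure", value=protocol.P_in, r_min=r_start)
        )
        mesh_rim_hyd = HydraulicBC("fixed_pore_pressure", value=protocol.P_in)
    else:
        mesh_rim_hyd = HydraulicBC("impermeable")
    bcs = BoundarySpec(
        mech={"bottom": MechanicalBC("fixed")},
        hyd={"top": hyd_top, "rim": mesh_rim_hyd},
    )
    cyto = [m for m in materials if m.label == "cytoplasm"][0]
    t_char = geometry.radius**2 / cyto.D
    t_final = t_end if t_end is not None else max(protocol.duration, 1.5 * t_char)
    times = ramp_hold_times(
        protocol.ramp_time, t_final,
        n_ramp=max(4, int(round(protocol.ramp_time / dt0))),
        dt0=dt0, growth=growth,
        dt_max=dt_max if dt_max is not None else 0.04 * t_final,
    )
    return solve_transient(mesh, materials, bcs, times, initial_pressure=protocol.P_in)


def simulate_injection(
    geometry: ScenarioGeometry,
    materials: list[MaterialRegion],
    protocol: PressureProtocol,
    probes: np.ndarray,
    resolution: float = 1.5,
    n_z: int = 4,
    dt0: float = 0.05,
    growth: float = 1.2,
    dt_max: float | None = None,
    t_end: float | None = None,
    auto_extend: bool = True,
) -> SurfaceResponse:
    """Fluid microinjection into the elliptical-cap cell.

    The pipette patch (radius ``geometry.contact_or_sink_radius``) is held
    at P_app ramped over ``protocol.ramp_time``; the rest of the surface is
    impermeable (membrane water exchange is slow compared to the injection).
    Returns per-probe upward displacement and onset time lags computed with
    the 10%-of-steady-state rule.
    """
    if geometry.shape != "elliptical_cap":
        raise ValueError("injection runs on the elliptical_cap geometry")
    if protocol.mode != "injection":
        raise ValueError("protocol.mode must be 'injection'")
    probes = np.asarray(probes, dtype=float)
    r_foot = geometry.radius * np.sqrt(
        max(1.0 - (geometry.rim_thickness / geometry.thickness) ** 2, 0.0)
    )
    if np.any(probes >= r_foot):
        raise ValueError("probes must lie inside the cell footprint")

    if protocol.P_eff == 0.0:
        times = ramp_hold_times(protocol.ramp_time, protocol.duration, 4, dt0, growth)
        zero = np.zeros((len(times), len(probes)))
        rr = np.linspace(0, r_foot, 16)
        return SurfaceResponse(probes, times, zero, (rr, np.zeros_like(rr)))

    sol = _pressure_cap_run(
        geometry, materials, protocol, membrane_reservoir=False,
        resolution=resolution, n_z=n_z, dt0=dt0, growth=growth,
        dt_max=dt_max, t_end=t_end,
    )
    ids, r_surf = sol.mesh.top_surface()
    steady = _is_steady(sol.times, sol.u[:, ids, 1])
    if not steady and auto_extend:
        sol = _pressure_cap_run(
            geometry, materials, protocol, membrane_reservoir=False,
            resolution=resolution, n_z=n_z, dt0=dt0, growth=growth,
            dt_max=dt_max, t_end=2.0 * sol.times[-1],
        )
        ids, r_surf = sol.mesh.top_surface()
        steady = _is_steady(sol.times, sol.u[:, ids, 1])
    disp = _probe_series(sol, probes)
    lags = np.array(
        [
            np.nan if (lag := time_lag(
                BeadTrace(sol.times[1:], disp[1:, j], probes[j]), rule="fraction"
            )) is None else lag
            for j in range(len(probes))
        ]
    )
    return SurfaceResponse(
        probe_distances=probes,
        times=sol.times,
        displacement=disp,
        steady_profile=(r_surf, sol.u[-1, ids, 1]),
        time_lags=lags,
        steady_reached=steady,
        params={"P_eff": protocol.P_eff},
        solution=sol,
    )


def simulate_depressurisation(
    geometry: ScenarioGeometry,
    materials_two_layer: list[MaterialRegion],
    protocol: PressureProtocol,
    D1_sweep: np.ndarray | None = None,
    resolution: float = 1.5,
    n_z: int = 4,
    dt0: float = 0.05,
    growth: float = 1.3,
    dt_max: float | None = None,
    t_end: float | None = None,
) -> list[SurfaceResponse]:
    """Localised pressure release through a sink in the two-layer cell.

    Requires a cortex layer (geometry.cortex_thickness > 0 and a cortex
    material).  The sink patch is held at P_app < P_in; the outer surface
    away from the sink is held at the reservoir pressure P_in, modelling
    trans-membrane influx that keeps cell volume constant.  For each cortex
    diffusion constant in ``D1_sweep`` (default: the given cortex D) the
    steady-state intracellular pressure profile vs distance from the sink
    is returned, sampled along the cell base.
    """
    labels = {m.label for m in materials_two_layer}
    if geometry.cortex_thickness <= 0 or "cortex" not in labels:
        raise ValueError("depressurisation requires a two-layer (cortex) model")
    if protocol.mode != "release":
        raise ValueError("protocol.mode must be 'release'")
    cortex = [m for m in materials_two_layer if m.label == "cortex"][0]
    cyto = [m for m in materials_two_layer if m.label == "cytoplasm"][0]
    if D1_sweep is None:
        D1_sweep = np.array([cortex.D])

    responses = []
    for D1 in np.asarray(D1_sweep, dtype=float):
        mats = [cyto, replace(cortex, D=float(D1), k=None)]
        if protocol.P_eff == 0.0:
            rr = np.linspace(0, geometry.radius, 16)
            responses.append(
                SurfaceResponse(
                    probe_distances=rr, times=np.array([0.0]),
                    displacement=np.zeros((1, len(rr))),
                    steady_profile=(rr, np.zeros_like(rr)),
                    pressure_profile=(rr, np.full_like(rr, protocol.P_in)),
                    params={"D1": float(D1)},
                )
            )
            continue
        sol = _pressure_cap_run(
            geometry, mats, protocol, membrane_reservoir=True,
            resolution=resolution, n_z=n_z, dt0=dt0, growth=growth,
            dt_max=dt_max, t_end=t_end,
        )
        if not _is_steady(sol.times, sol.p):
            sol = _pressure_cap_run(
                geometry, mats, protocol, membrane_reservoir=True,
                resolution=resolution, n_z=n_z, dt0=dt0, growth=growth,
                dt_max=dt_max, t_end=2.0 * sol.times[-1],
            )
        base = sol.mesh.boundary["bottom"]
        base = base[sol.mesh.pmap[base] >= 0]
        order = np.argsort(sol.mesh.coords[base, 0])
        base = base[order]
        xb = sol.mesh.coords[base, 0]
        pb = sol.p[-1, sol.mesh.pmap[base]]
        ids, r_surf = sol.mesh.top_surface()
        steady = _is_steady(sol.times, sol.p)
        responses.append(
            SurfaceResponse(
                probe_distances=xb,
                times=sol.times,
                displacement=_probe_series(sol, np.clip(xb, 0, r_surf[-1])),
                steady_profile=(r_surf, sol.u[-1, ids, 1]),
                pressure_profile=(xb, pb),
                steady_reached=steady,
                params={"D1": float(D1), "P_in": protocol.P_in, "P_eff": protocol.P_eff},
                solution=sol,
            )
        )
    return responses
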