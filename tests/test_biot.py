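"""Solver validation against closed-form consolidation results."""

import numpy as np
import pytest

from porocell.biot import (
    BoundarySpec,
    HydraulicBC,
    MechanicalBC,
    SolverError,
    darcy_flux,
    ramp_hold_times,
    solve_transient,
    terzaghi_consolidation_degree,
    terzaghi_reference,
)
from porocell.materials import MaterialRegion
from porocell.mesh import ScenarioGeometry, build_mesh

H, D, Q_LOAD = 10.0, 5.0, 100.0


def column_mesh(n_z=40):
    return build_mesh(ScenarioGeometry("column", 2.0, H), 1.0, n_z=n_z)


def confined_bcs(load=None, p_bottom=None):
    mech = {"bottom": MechanicalBC("fixed"), "rim": MechanicalBC("fixed_ur")}
    hyd = {"top": HydraulicBC("fixed_pore_pressure", 0.0)}
    if load is not None:
        mech["top"] = MechanicalBC("traction", value=load)
    if p_bottom is not None:
        hyd["bottom"] = HydraulicBC("fixed_pore_pressure", p_bottom)
    return BoundarySpec(mech=mech, hyd=hyd)


@pytest.fixture(scope="module")
def terzaghi_solution():
    mesh = column_mesh()
    mat = MaterialRegion("cytoplasm", E=1000.0, nu=0.3, D=D)
    t_char = H**2 / D
    times = ramp_hold_times(
        0.0, 1.2 * t_char, dt0=2e-5 * t_char, growth=1.08, dt_max=3e-3 * t_char
    )
    sol = solve_transient(mesh, [mat], confined_bcs(load=Q_LOAD), times)
    return mesh, sol


class TestTerzaghiReference:
    def test_undrained_and_drained_limits(self):
        z = np.array([0.0, 3.0, 7.0])
        assert np.allclose(terzaghi_reference(Q_LOAD, H, D, z, 0.0), Q_LOAD)
        assert np.all(terzaghi_reference(Q_LOAD, H, D, z, 1e4) < 1e-6 * Q_LOAD)
        # drained boundary is always at ambient pressure
        assert terzaghi_reference(Q_LOAD, H, D, H, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_half_consolidation_time_factor(self):
        """Average degree of consolidation reaches 50% at Tv ~ 0.197."""
        assert terzaghi_consolidation_degree(0.197) == pytest.approx(0.5, abs=1e-3)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            terzaghi_reference(Q_LOAD, H, D, H + 1.0, 1.0)
        with pytest.raises(ValueError):
            terzaghi_reference(Q_LOAD, H, D, 1.0, -1.0)


class TestTransientSolve:
    def test_matches_terzaghi_series_within_1pc(self, terzaghi_solution):
        """FE pore pressure tracks the consolidation series to <1% rel. L2."""
        mesh, sol = terzaghi_solution
        ids = np.where((np.abs(mesh.coords[:, 0]) < 1e-12) & (mesh.pmap >= 0))[0]
        ids = ids[np.argsort(mesh.coords[ids, 1])]
        z = mesh.coords[ids, 1]
        t_char = H**2 / D
        for Tv in (0.05, 0.197, 0.5, 1.0):
            i = int(np.argmin(np.abs(sol.times - Tv * t_char)))
            p_fe = sol.p[i, mesh.pmap[ids]]
            p_ref = terzaghi_reference(Q_LOAD, H, D, z, sol.times[i])
            err = np.linalg.norm(p_fe - p_ref) / np.linalg.norm(p_ref)
            assert err < 0.01, f"Tv={Tv}: {err:.3%}"

    def test_undrained_first_step_carries_full_load(self, terzaghi_solution):
        """Away from the drained boundary the instantaneous response is p = q."""
        mesh, sol = terzaghi_solution
        base = np.where((mesh.coords[:, 1] == 0.0) & (mesh.pmap >= 0))[0]
        assert sol.p[1, mesh.pmap[base]].mean() == pytest.approx(Q_LOAD, rel=1e-3)

    def test_per_step_fluid_balance_residual_small(self, terzaghi_solution):
        _, sol = terzaghi_solution
        assert sol.balance_residual.max() < 1e-8

    def test_steady_two_pressure_column_is_linear(self):
        """Fixed 100 Pa at the base and 0 at the top: linear steady profile."""
        mesh = column_mesh(n_z=10)
        mat = MaterialRegion("cytoplasm", E=1000.0, nu=0.3, D=D)
        times = ramp_hold_times(0.1, 200.0, 4, dt0=0.5, growth=1.4)
        sol = solve_transient(mesh, [mat], confined_bcs(p_bottom=100.0), times)
        ids = np.where(mesh.pmap >= 0)[0]
        z = mesh.coords[ids, 1]
        expected = 100.0 * (1.0 - z / H)
        dev = np.abs(sol.p[-1, mesh.pmap[ids]] - expected).max()
        assert dev < 0.005 * 100.0

    def test_zero_load_uniform_pressure_stays_constant(self):
        """Uniform initial pressure with impermeable walls is an equilibrium."""
        mesh = column_mesh(n_z=4)
        mat = MaterialRegion("cytoplasm", E=1000.0, nu=0.3, D=D)
        bcs = BoundarySpec(mech={"bottom": MechanicalBC("fixed")}, hyd={})
        sol = solve_transient(mesh, [mat], bcs, np.linspace(0, 5, 6), initial_pressure=200.0)
        assert np.abs(sol.u).max() == 0.0
        assert np.all(sol.p == 200.0)

    def test_unconstrained_system_rejected(self):
        mesh = column_mesh(n_z=4)
        mat = MaterialRegion("cytoplasm", E=1000.0, nu=0.3, D=D)
        with pytest.raises(SolverError, match="singular"):
            solve_transient(mesh, [mat], BoundarySpec(), np.linspace(0, 1, 3))

    def test_time_grid_validation(self):
        mesh = column_mesh(n_z=4)
        mat = MaterialRegion("cytoplasm", E=1000.0, nu=0.3, D=D)
        with pytest.raises(ValueError):
            solve_transient(mesh, [mat], confined_bcs(load=1.0), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            solve_transient(mesh, [mat], confined_bcs(load=1.0), np.array([0.0, 2.0, 1.0]))

    def test_spatial_halving_changes_pressure_below_2pc(self):
        """Halving the column element size barely moves the pressure field."""
        mat = MaterialRegion("cytoplasm", E=1000.0, nu=0.3, D=D)
        t_char = H**2 / D
        times = ramp_hold_times(0.0, 0.25 * t_char, dt0=1e-4 * t_char,
                                growth=1.1, dt_max=5e-3 * t_char)
        z_eval = np.linspace(0.0, H, 9)
        vals = []
        for n_z in (10, 20):
            mesh = column_mesh(n_z=n_z)
            sol = solve_transient(mesh, [mat], confined_bcs(load=Q_LOAD), times)
            ids = np.where((np.abs(mesh.coords[:, 0]) < 1e-12) & (mesh.pmap >= 0))[0]
            ids = ids[np.argsort(mesh.coords[ids, 1])]
            vals.append(np.interp(z_eval, mesh.coords[ids, 1], sol.p[-1, mesh.pmap[ids]]))
        assert np.abs(vals[0] - vals[1]).max() < 0.02 * Q_LOAD

    def test_permeability_time_rescaling_invariance(self):
        """k -> c k with t -> t/c leaves the trajectory unchanged."""
        c = 7.0
        geo = ScenarioGeometry("disk", 10.0, 10.0, indenter_radius=2.0)
        mesh = build_mesh(geo, 2.0)
        times = ramp_hold_times(0.5, 20.0, 4, dt0=0.2, growth=1.3)

        def run(k, ramp, tgrid):
            mat = MaterialRegion("cytoplasm", E=500.0, nu=0.3, k=k)
            bcs = BoundarySpec(
                mech={
                    "bottom": MechanicalBC("fixed"),
                    "top": MechanicalBC("prescribed_uz", value=-1.0, ramp_time=ramp, r_max=3.0),
                },
                hyd={"top": HydraulicBC("fixed_pore_pressure", 0.0, r_min=3.0001)},
            )
            return solve_transient(mesh, [mat], bcs, tgrid)

        a = run(0.01, 0.5, times)
        b = run(0.01 * c, 0.5 / c, times / c)
        assert np.abs(a.u - b.u).max() < 1e-9 * np.abs(a.u).max()
        assert np.abs(a.p - b.p).max() < 1e-6 * np.abs(a.p).max()


class TestDarcyFlux:
    def test_uniform_pressure_gives_zero_flux(self):
        mesh = column_mesh(n_z=4)
        mat = MaterialRegion("cytoplasm", E=1000.0, nu=0.3, D=D)
        bcs = BoundarySpec(mech={"bottom": MechanicalBC("fixed")}, hyd={})
        sol = solve_transient(mesh, [mat], bcs, np.linspace(0, 5, 6), initial_pressure=50.0)
        assert np.abs(darcy_flux(sol, [mat])).max() == 0.0

    def test_linear_drop_hand_value(self):
        """100 Pa over 10 um with k = 0.125 um^2/(Pa s) gives |q| = 1.25 um/s."""
        mesh = column_mesh(n_z=10)
        mat = MaterialRegion("cytoplasm", E=1000.0, nu=0.3, k=0.125)
        times = ramp_hold_times(0.1, 500.0, 4, dt0=0.5, growth=1.4)
        sol = solve_transient(mesh, [mat], confined_bcs(p_bottom=100.0), times)
        q = darcy_flux(sol, [mat])
        assert np.abs(q[:, 1]).mean() == pytest.approx(1.25, rel=1e-3)
        assert np.abs(q[:, 0]).max() < 1e-9
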