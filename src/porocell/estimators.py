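"""Estimators turning bead traces and pressure-step data into physical quantities.

The experimental observables are vertical bead displacements z(t) at known
distances from a stimulus (AFM tip or micropipette) and pressure-step
records (length scale, time lag, pressure step).  From these we derive:

* time lags of front arrival (threshold crossing of z(t)),
* hydraulic permeability k via Darcy's law, regressing the front velocity
  v ~ length / delta_t on the pressure-gradient estimate dP / length,
* the hyperbolic dependence delta_t = c / dP of metaphase onset lags,
* the slow-phase poroelastic relaxation time tau_p (single-exponential fit),
* pore-size / relaxation-time scaling ratios under osmotic volume change,
* the closed-form order-of-magnitude scales L = sqrt(d delta), t_p = L^2/D,
  l = gamma/E and tau_z = l delta_z / (k E).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BeadTrace",
    "PressureStepDataset",
    "PoreScalingParams",
    "DarcyFit",
    "HyperbolicFit",
    "ScalingEstimates",
    "EstimatorError",
    "time_lag",
    "darcy_fit",
    "hyperbolic_lag_fit",
    "tau_p_fit",
    "pore_scaling",
    "scaling_estimates",
]


class EstimatorError(RuntimeError):
    """Raised when an estimator cannot produce a result."""


@dataclass
class BeadTrace:
    """Vertical displacement time series of one bead.

    t [s] strictly increasing; z [um] displacement from baseline (z(0) = 0
    after baseline subtraction); ``distance`` [um] from the stimulus.
    """

    t: np.ndarray
    z: np.ndarray
    distance: float = np.nan
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.t.shape != self.z.shape or self.t.ndim != 1:
            raise ValueError("t and z must be 1D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def baseline_subtracted(self) -> "BeadTrace":
        return BeadTrace(self.t, self.z - self.z[0], self.distance, self.label)


@dataclass
class PressureStepDataset:
    """Records (length_scale [um], delta_t [s], dP [Pa]) per cell.

    ``length_scale`` is the bead-pipette distance for interphase beads or
    the cell diameter for metaphase cells.
    """

    length_scale: np.ndarray
    dt: np.ndarray
    dP: np.ndarray
    cell_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.length_scale = np.atleast_1d(np.asarray(self.length_scale, dtype=float))
        self.dt = np.atleast_1d(np.asarray(self.dt, dtype=float))
        self.dP = np.atleast_1d(np.asarray(self.dP, dtype=float))
        n = len(self.length_scale)
        if len(self.dt) != n or len(self.dP) != n:
            raise ValueError("length_scale, dt and dP must have equal length")
        if np.any(self.length_scale <= 0) or np.any(self.dP <= 0):
            raise ValueError("length scales and pressure steps must be positive")

    def __len__(self) -> int:
        return len(self.length_scale)


def time_lag(
    trace: BeadTrace,
    rule: str = "absolute",
    threshold: float = 0.1,
    fraction: float = 0.10,
    steady_value: float | None = None,
) -> float | None:
    """First threshold-crossing time of |z(t)| by linear interpolation [s].

    rule ``"absolute"``: the threshold is ``threshold`` um (default 0.1 um,
    the experimental criterion).  rule ``"fraction"``: the threshold is
    ``fraction`` of the steady-state displacement magnitude (default 10%,
    the criterion used for the simulations); ``steady_value`` defaults to
    the final sample of the trace.

    Returns ``None`` (a no-lag result distinct from 0) if the trace never
    crosses the threshold.
    """
    if rule == "absolute":
        thr = threshold
    elif rule == "fraction":
        steady = trace.z[-1] if steady_value is None else steady_value
        thr = fraction * abs(steady)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if thr <= 0:
        raise ValueError("threshold must be positive")
    mag = np.abs(trace.z)
    above = mag >= thr
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(trace.t[0])
    # linear interpolation between samples i-1 and i
    t0, t1 = trace.t[i - 1], trace.t[i]
    m0, m1 = mag[i - 1], mag[i]
    return float(t0 + (thr - m0) / (m1 - m0) * (t1 - t0))


@dataclass
class DarcyFit:
    """Through-origin Darcy regression result: v = k * (dP / length)."""

    k: float  # um^2/(Pa s)
    r2: float  # coefficient of determination of the free-intercept fit
    intercept: float  # um/s, of the free-intercept fit
    n_used: int
    n_rejected: int

    @property
    def k_si(self) -> float:
        """Permeability in m^2/(Pa s) (k [um^2/(Pa s)] * 1e-12)."""
        return self.k * 1e-12


def darcy_fit(data: PressureStepDataset) -> DarcyFit:
    """Estimate hydraulic permeability from pressure-step records.

    Computes per record the front velocity v_i = length_i / dt_i and the
    pressure-gradient estimate g_i = dP_i / length_i, then fits Darcy's law
    v = k g through the origin (the law has no offset).  The r^2 and
    intercept of the ordinary free-intercept regression are reported
    alongside for comparability.  Records with non-positive dt are rejected
    (counted in ``n_rejected``).
    """
    keep = data.dt > 0
    n_rej = int((~keep).sum())
    if keep.sum() < 3:
        raise EstimatorError("need at least 3 usable records")
    L, dt, dP = data.length_scale[keep], data.dt[keep], data.dP[keep]
    v = L / dt
    g = dP / L
    k = float(np.dot(v, g) / np.dot(g, g))
    lin = stats.linregress(g, v)
    return DarcyFit(k=k, r2=float(lin.rvalue**2), intercept=float(lin.intercept),
                    n_used=int(keep.sum()), n_rejected=n_rej)


@dataclass
class HyperbolicFit:
    """Fit of delta_t = c / dP."""

    c: float  # Pa s
    rms_residual: float  # s
    relative_residual: float  # rms residual / rms delta_t


def hyperbolic_lag_fit(data: PressureStepDataset) -> HyperbolicFit:
    """Least-squares fit of the hyperbolic lag law delta_t = c / dP.

    Requires at least 3 distinct pressure steps.  The residual is reported
    so a structureless (e.g. constant-lag) dataset shows up as a misfit
    rather than a silent success.
    """
    if len(np.unique(data.dP)) < 3:
        raise EstimatorError("need at least 3 distinct pressure steps")
    x = 1.0 / data.dP
    c = float(np.dot(data.dt, x) / np.dot(x, x))
    resid = data.dt - c * x
    rms = float(np.sqrt(np.mean(resid**2)))
    return HyperbolicFit(c=c, rms_residual=rms,
                         relative_residual=rms / float(np.sqrt(np.mean(data.dt**2))))


def tau_p_fit(trace: BeadTrace, phase_split_time: float = 0.3) -> float:
    """Slow-phase relaxation time tau_p [s] by single-exponential fit.

    The biphasic bead response is split at ``phase_split_time`` (default
    0.3 s, the upper bound of the fast phase); on the post-split segment
    z(t) = z_inf + (z_split - z_inf) exp(-(t - t_split)/tau_p) is fitted
    with free (z_inf, tau_p), z_split being the measured value at the split.
    """
    ts = phase_split_time
    sel = trace.t >= ts
    if sel.sum() < 4:
        raise EstimatorError("too few samples after the phase split")
    t, z = trace.t[sel], trace.z[sel]
    z_split = float(np.interp(ts, trace.t, trace.z))

    def model(tt, z_inf, tau):
        return z_inf + (z_split - z_inf) * np.exp(-(tt - ts) / tau)

    span = t[-1] - ts
    p0 = (float(z[-1]), max(span / 3.0, 1e-3))
    try:
        popt, _ = optimize.curve_fit(
            model, t, z, p0=p0, bounds=([-np.inf, 1e-6], [np.inf, np.inf]), maxfev=10000
        )
    except RuntimeError as exc:
        raise EstimatorError(f"exponential fit did not converge: {exc}")
    return float(popt[1])


@dataclass
class PoreScalingParams:
    """Inputs of the pore-size scaling under osmotic volume change.

    alpha = V/V0 (volume ratio after the shock), phi = solid-to-fluid
    volume ratio; alternatively give the pore sizes xi and xi0 [nm]
    directly.  eta is the interstitial fluid viscosity [Pa s] (carried for
    reference; the ratios are viscosity-independent).
    """

    alpha: float | None = None
    phi: float | None = None
    xi: float | None = None
    xi0: float | None = None
    V_f: float | None = None
    eta: float = 1e-3

    def __post_init__(self) -> None:
        if self.alpha is not None and not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.phi is not None and not self.phi > 0:
            raise ValueError("phi must be positive")


def pore_scaling(params: PoreScalingParams) -> tuple[float, float]:
    """Pore-size and relaxation-time ratios (xi/xi0, t_p/t_p0).

    With intracellular water held in N pores of volume xi0^3 and a solid
    fraction that does not change under osmotic shock, a volume change
    V/V0 = alpha rescales the pore size as

        xi/xi0 = (alpha + phi (alpha - 1))^(1/3),

    and since D_p ~ xi^2, the efflux time scales as t_p/t_p0 = (xi/xi0)^-2.
    Pore sizes may also be given directly via ``xi`` and ``xi0``.
    """
    if params.alpha is not None:
        if params.phi is None:
            raise ValueError("phi required with alpha")
        arg = params.alpha + params.phi * (params.alpha - 1.0)
        if arg <= 0:
            raise ValueError("fully collapsed pores: alpha + phi(alpha-1) <= 0")
        xi_ratio = arg ** (1.0 / 3.0)
    elif params.xi is not None and params.xi0 is not None:
        if params.xi <= 0 or params.xi0 <= 0:
            raise ValueError("pore sizes must be positive")
        xi_ratio = params.xi / params.xi0
    else:
        raise ValueError("give either (alpha, phi) or (xi, xi0)")
    return xi_ratio, xi_ratio ** (-2.0)


@dataclass
class ScalingEstimates:
    """Closed-form scale estimates; unavailable ones are None."""

    L: float | None = None  # deformed-region length scale [um]
    t_p: float | None = None  # poroelastic efflux time [s]
    l: float | None = None  # tension/elasticity crossover length [um]
    tau_z: float | None = None  # vertical-displacement relaxation time [s]


def scaling_estimates(
    d: float | None = None,
    delta: float | None = None,
    D: float | None = None,
    gamma: float | None = None,
    E: float | None = None,
    delta_z: float | None = None,
    k: float | None = None,
    require: tuple[str, ...] = (),
) -> ScalingEstimates:
    """Order-of-magnitude scales of the indentation response.

    L = sqrt(d * delta) [um] with d the indentation diameter and delta the
    depth; t_p = d*delta/D [s]; l = gamma/E (gamma [N/m], E [Pa], result in
    um); tau_z = l * delta_z / (k * E) [s] with k [um^2/(Pa s)].  Outputs
    whose inputs are missing are returned as None, unless listed in
    ``require`` in which case a ValueError is raised.
    """
    out = ScalingEstimates()
    if d is not None and delta is not None:
        out.L = float(np.sqrt(d * delta))
        if D is not None:
            out.t_p = d * delta / D
    if gamma is not None and E is not None:
        out.l = gamma / E * 1e6  # m -> um
    l_for_tau = out.l
    if l_for_tau is not None and delta_z is not None and k is not None and E is not None:
        out.tau_z = l_for_tau * delta_z / (k * E)
    for name in require:
        if getattr(out, name) is None:
            raise ValueError(f"missing inputs for requested output {name!r}")
    return out
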