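"""Synthetic datasets with the statistical structure of the experiments.

Every generator is seeded (all randomness flows from one explicit
`numpy.random.Generator`) and its ground truth is recoverable by the
matching estimator exactly at zero noise — the round-trip property the
test suite asserts.

Generators
----------
* biphasic bead traces: fast sub-0.3 s jump plus slow exponential phase
  with distance-dependent relaxation time tau_p(r) and nm-scale noise;
  displacement sign switches from down to up at a configurable radius.
* Darcy pressure-step datasets: records (distance, time lag, pressure
  step) with lags set by Darcy front propagation, delta_t = dx^2/(k dP).
* metaphase diameter time courses: flat until a hyperbolic onset lag
  delta_t = c / dP, then linear diameter increase.
* ring-image stacks for the defocusing tracker (via
  :func:`porocell.beadtrack.synthesize_ring_image`).

Default noise levels: 5 nm additive Gaussian on z (the defocusing
precision scale) and 10-20% multiplicative on time lags.  Experimental
displacement amplitudes vs distance are only published as figures, so the
amplitude defaults here are order-of-magnitude placeholders, not
measured values.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .beadtrack import RingImage, synthesize_ring_image
from .estimators import BeadTrace, PressureStepDataset

__all__ = [
    "gen_biphasic_traces",
    "gen_darcy_dataset",
    "gen_metaphase_diameter",
    "gen_ring_stack",
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_biphasic_traces(
    distances: Sequence[float],
    seed: int | np.random.Generator,
    fast_amplitude: Callable[[float], float] | None = None,
    slow_amplitude: Callable[[float], float] | None = None,
    tau_p: Callable[[float], float] | None = None,
    noise_sigma: float = 0.005,
    sign_switch_radius: float = 6.0,
    fast_time: float = 0.0,
    t_max: float = 10.0,
    dt: float = 0.1,
) -> list[BeadTrace]:
    """Biphasic bead z-traces at the given distances from the AFM tip.

    z(t) = A_fast(r) * step(t; t < 0.3 s) + A_slow(r) * (1 - exp(-t/tau_p(r)))
    plus additive Gaussian noise (sigma in um; default 5 nm).  The overall
    sign is negative (downward) for beads closer than ``sign_switch_radius``
    (default 6 um) and positive further out.  tau_p(r) is non-decreasing in
    r by default (0.5 s + 0.1 s/um), reflecting slower equilibration away
    from the tip.  Amplitude defaults are order-of-magnitude placeholders
    decaying with distance.

    ``fast_time`` = 0 (default) makes the fast phase an instantaneous jump,
    so the slow-phase relaxation time is recoverable exactly at zero noise;
    a positive value gives a smooth rise completing within ``fast_time``.
    """
    rng = _rng(seed)
    if fast_amplitude is None:
        fast_amplitude = lambda r: 0.15 * np.exp(-r / 8.0)
    if slow_amplitude is None:
        slow_amplitude = lambda r: 0.35 * np.exp(-r / 10.0)
    if tau_p is None:
        tau_p = lambda r: 0.5 + 0.1 * r
    t = np.arange(0.0, t_max + dt / 2, dt)
    traces = []
    for r in distances:
        tau = tau_p(r)
        if tau <= 0:
            raise ValueError("tau_p must be positive")
        sign = -1.0 if r < sign_switch_radius else 1.0
        if fast_time > 0:
            fast = fast_amplitude(r) * (1.0 - np.exp(-3.0 * t / fast_time))
        else:
            fast = fast_amplitude(r) * (t > 0)
        slow = slow_amplitude(r) * (1.0 - np.exp(-t / tau))
        z = sign * (fast + slow)
        if noise_sigma > 0:
            z = z + rng.normal(0.0, noise_sigma, t.shape)
        z[0] = 0.0  # baseline-subtracted by construction
        traces.append(BeadTrace(t=t, z=z, distance=float(r)))
    return traces


def gen_darcy_dataset(
    k: float,
    dP: Sequence[float],
    dx: Sequence[float],
    seed: int | np.random.Generator,
    noise_frac: float = 0.0,
    front_model: str = "darcy",
    cell_ids: Sequence | None = None,
) -> PressureStepDataset:
    """Pressure-step records whose time lags follow Darcy front propagation.

    Each (dx_i, dP_i) pair receives a lag.  ``front_model="darcy"``
    (default) sets delta_t = dx^2 / (k dP), the lag consistent with the
    velocity and gradient estimates v = dx/dt, grad P = dP/dx — so
    :func:`porocell.estimators.darcy_fit` recovers ``k`` exactly at zero
    noise.  ``front_model="linear"`` makes the lag linear in distance at
    fixed dP (constant front speed set at the median distance), the shape
    reported for the bead data; k recovery is then only approximate.
    Noise is multiplicative log-normal-free Gaussian: dt *= (1 + eps),
    eps ~ N(0, noise_frac).
    """
    rng = _rng(seed)
    dP = np.asarray(dP, dtype=float)
    dx = np.asarray(dx, dtype=float)
    if dP.shape != dx.shape:
        raise ValueError("dP and dx must have equal length")
    if not k > 0:
        raise ValueError("k must be positive")
    if front_model == "darcy":
        dt = dx**2 / (k * dP)
    elif front_model == "linear":
        x0 = np.median(dx)
        dt = dx * x0 / (k * dP)
    else:
        raise ValueError(f"unknown front_model {front_model!r}")
    if noise_frac > 0:
        dt = dt * np.abs(1.0 + rng.normal(0.0, noise_frac, dt.shape))
    return PressureStepDataset(
        length_scale=dx, dt=dt, dP=dP,
        cell_id=None if cell_ids is None else np.asarray(cell_ids),
    )


def gen_metaphase_diameter(
    dP: Sequence[float],
    seed: int | np.random.Generator,
    baseline_d: float = 20.0,
    c_lag: float = 200.0,
    rate: Callable[[float], float] | None = None,
    noise_frac: float = 0.0,
    n_replicates: int = 3,
    t_max: float = 6.0,
    dt: float = 0.067,
) -> tuple[dict[float, list[BeadTrace]], PressureStepDataset]:
    """Metaphase-cell diameter time courses under pressure steps.

    For each pressure step dP the diameter stays at ``baseline_d`` until
    the hyperbolic onset lag delta_t = c_lag / dP, then grows linearly at
    ``rate(dP)`` (default proportional to dP).  Returns the traces (as
    diameter-change BeadTraces, ``n_replicates`` per pressure, emulating
    the N = 3 cells per pressure of the experiments) and the
    (d, delta_t, dP) dataset with onset lags measured from the noisy
    traces' threshold crossing of 1% of baseline diameter.
    """
    rng = _rng(seed)
    if rate is None:
        rate = lambda p: 0.002 * p  # um/s per Pa step
    t = np.arange(0.0, t_max + dt / 2, dt)
    traces: dict[float, list[BeadTrace]] = {}
    recs_d, recs_dt, recs_dP = [], [], []
    for p in dP:
        if p <= 0:
            raise ValueError("pressure steps must be positive")
        lag = c_lag / p
        group = []
        for rep in range(n_replicates):
            d = np.where(t < lag, 0.0, rate(p) * (t - lag))
            if noise_frac > 0:
                d = d * (1.0 + rng.normal(0.0, noise_frac, t.shape))
            group.append(BeadTrace(t=t, z=d, distance=baseline_d, label=f"dP={p}"))
            # onset measured as crossing of 1% of the baseline diameter
            thr = 0.01 * baseline_d
            above = np.abs(d) >= thr
            if above.any():
                i = int(np.argmax(above))
                t_on = t[i] if i == 0 else float(
                    np.interp(thr, [abs(d[i - 1]), abs(d[i])], [t[i - 1], t[i]])
                )
                # subtract the threshold-rise time so the record reflects the lag
                t_on = max(t_on - thr / rate(p), dt / 10.0)
                recs_d.append(baseline_d)
                recs_dt.append(t_on)
                recs_dP.append(p)
        traces[float(p)] = group
    data = PressureStepDataset(
        length_scale=np.array(recs_d), dt=np.array(recs_dt), dP=np.array(recs_dP)
    )
    return traces, data


def gen_ring_stack(
    z_of_t: np.ndarray,
    calibration_slope: float = 0.05,
    base_radius: float = 20.0,
    noise_sigma: float = 5.0,
    seed: int | np.random.Generator = 0,
    **ring_kwargs,
) -> list[RingImage]:
    """Defocused-bead frame stack for a known height time course.

    Frame i carries outer ring radius base_radius + z_i / slope, so the
    tracker plus a calibration of the given slope should recover z(t).
    """
    rng = _rng(seed)
    frames = []
    for z in np.asarray(z_of_t, dtype=float):
        frames.append(
            synthesize_ring_image(
                base_radius + z / calibration_slope,
                noise_sigma=noise_sigma, seed=rng, **ring_kwargs,
            )
        )
    return frames
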