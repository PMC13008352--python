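#!/usr/bin/env python
"""Simulated fluid microinjection into an elliptical-cap cell.

Pressure P_eff = 500 Pa at a 1-um pipette patch drives fluid into the
poroelastic cap (E = 1.2 kPa, D = 13 um^2/s); the surface rises with an
onset lag growing with distance.  A Darcy regression on the simulated
lags recovers a permeability of the order the solver was given.  Writes
CSVs under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from porocell import (
    MaterialRegion,
    PressureProtocol,
    PressureStepDataset,
    ScenarioGeometry,
    darcy_fit,
    simulate_injection,
)
from porocell.io import write_result

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

geometry = ScenarioGeometry("elliptical_cap", 20.0, 4.5, contact_or_sink_radius=1.0)
mat = MaterialRegion("cytoplasm", E=1200.0, nu=0.3, D=13.0)
protocol = PressureProtocol(P_in=0.0, P_app=500.0, ramp_time=2.0, mode="injection")
probes = np.linspace(3.0, 15.0, 7)

resp = simulate_injection(geometry, [mat], protocol, probes, resolution=1.0, n_z=6)
write_result(resp, OUT, name="injection", force=True)

i2 = int(np.argmin(np.abs(resp.times - 2.0)))
pd.DataFrame(
    {"dx_um": probes, "uz_at_2s_um": resp.displacement[i2], "dt_s": resp.time_lags}
).to_csv(OUT / "injection_lags.csv", index=False)

lin = stats.linregress(probes, resp.time_lags)
data = PressureStepDataset(probes, resp.time_lags, np.full(len(probes), 500.0))
fit = darcy_fit(data)
print(f"onset lags grow with distance (r^2 = {lin.rvalue**2:.3f}), "
      f"slope {lin.slope:.2f} s/um")
print(f"coarse Darcy estimate from the simulated lags: "
      f"k ~ {fit.k:.3f} um^2/(Pa s) = {fit.k_si:.2e} m^2/(Pa s) "
      f"(solver value {mat.k:.3f} um^2/(Pa s))")
print(f"ratio estimator/solver: {fit.k/mat.k:.2f} - the v ~ dx/dt front "
      "approximation is order-of-magnitude accurate.")
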