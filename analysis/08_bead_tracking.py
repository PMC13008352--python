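#!/usr/bin/env python
"""Defocused-bead ring tracking: sub-pixel radii and nanometre z-traces.

Synthesises concentric-ring bead images, measures the outer ring radius
by Gaussian peak fitting on a diametric profile, calibrates radius -> z
with simulated piezo steps, and tracks a known height ramp through a
noisy stack.  Writes results/bead_tracking.json.
"""

import json
from pathlib import Path

import numpy as np

from porocell.beadtrack import calibrate, outer_ring_radius, synthesize_ring_image, track_stack
from porocell.synthetic import gen_ring_stack

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rng = np.random.default_rng(2024)
errs = []
for _ in range(100):
    im = synthesize_ring_image(20.0, noise_sigma=10.0, seed=rng)
    est, _ = outer_ring_radius(im)
    errs.append(est - 20.0)
radius_rmse = float(np.sqrt(np.mean(np.square(errs))))

# piezo calibration: known 50 nm z-steps
z_steps = np.arange(0.0, 0.55, 0.05)
radii = []
for i, z in enumerate(z_steps):
    im = synthesize_ring_image(20.0 + z / 0.05, noise_sigma=5.0, seed=500 + i)
    radii.append(outer_ring_radius(im)[0])
cal = calibrate(np.array(radii), z_steps)

z_true = np.linspace(0.0, 0.4, 30)
frames = gen_ring_stack(z_true, calibration_slope=0.05, noise_sigma=5.0, seed=7)
trace = track_stack(frames, cal)
z_rmse = float(np.sqrt(np.nanmean((trace.z - z_true) ** 2)))

payload = {
    "radius_rmse_px_at_10pc_noise": radius_rmse,
    "calibration_slope_um_per_px": cal.slope,
    "calibration_r2": cal.r2,
    "z_trace_rmse_nm": z_rmse * 1e3,
}
(OUT / "bead_tracking.json").write_text(json.dumps(payload, indent=2))

print(f"outer ring radius RMSE at 10% noise: {radius_rmse:.3f} px (100 frames)")
print(f"piezo calibration: {cal.slope:.4f} um/px, r^2 = {cal.r2:.4f}")
print(f"tracked z-ramp RMSE: {z_rmse*1e3:.1f} nm - nanometre-scale height "
      "precision from diffraction-ring radii.")
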