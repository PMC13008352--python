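"""File formats, run configuration and result serialisation.

Fixed CSV dialect: comma-separated, '.' decimal, UTF-8, header mandatory.
Column dictionary for trace files: ``t_s`` (time [s]), ``z_um``
(z-displacement [um]), ``dx_um`` (distance to stimulus [um]), optional
``trace_id`` and ``condition``.  Pressure-step files: ``dx_um``, ``dt_s``,
``dP_Pa``, optional ``cell_id``.  Scalar results are written as JSON with
the hash of the resolved configuration embedded; fields go to legacy-VTK
text so any standard viewer opens them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .beadtrack import Calibration, RingImage
from .estimators import BeadTrace, PressureStepDataset
from .inference import FitResult
from .scenarios import SurfaceResponse

__all__ = [
    "RunConfig",
    "read_trace_csv",
    "write_trace_csv",
    "read_pressure_step_csv",
    "read_ring_stack",
    "write_ring_stack",
    "write_result",
    "write_vtk_fields",
]

TRACE_COLUMNS = ("t_s", "z_um", "dx_um")
PRESSURE_COLUMNS = ("dx_um", "dt_s", "dP_Pa")


@dataclass
class RunConfig:
    """Resolved configuration of one run; round-trips through YAML losslessly."""

    module: str
    params: dict = field(default_factory=dict)
    mesh_resolution: float | None = None
    tolerances: dict = field(default_factory=dict)
    seed: int | None = None
    out_dir: str = "results"
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_trace_csv(path: str | Path) -> list[BeadTrace]:
    """Read bead traces from CSV (columns t_s, z_um, dx_um[, trace_id]).

    Unknown extra columns are accepted with a warning; missing mandatory
    columns or non-monotone time raise descriptive errors naming the
    offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    known = set(TRACE_COLUMNS) | {"trace_id", "condition"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}")
    if "trace_id" in df.columns:
        groups = [g for _, g in df.groupby("trace_id", sort=True)]
    else:
        groups = [df]
    traces = []
    for g in groups:
        t = g["t_s"].to_numpy(dtype=float)
        bad = np.where(np.diff(t) <= 0)[0]
        if len(bad):
            row = g.index[bad[0] + 1]
            raise ValueError(f"{path}: non-monotone time at row {row + 2} (1-based incl. header)")
        label = str(g["condition"].iloc[0]) if "condition" in g.columns else ""
        traces.append(
            BeadTrace(
                t=t,
                z=g["z_um"].to_numpy(dtype=float),
                distance=float(g["dx_um"].iloc[0]),
                label=label,
            )
        )
    return traces


def write_trace_csv(traces: list[BeadTrace], path: str | Path) -> None:
    frames = []
    for i, tr in enumerate(traces):
        frames.append(
            pd.DataFrame(
                {"trace_id": i, "t_s": tr.t, "z_um": tr.z, "dx_um": tr.distance,
                 "condition": tr.label}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_pressure_step_csv(path: str | Path) -> PressureStepDataset:
    df = pd.read_csv(path)
    missing = [c for c in PRESSURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    return PressureStepDataset(
        length_scale=df["dx_um"].to_numpy(dtype=float),
        dt=df["dt_s"].to_numpy(dtype=float),
        dP=df["dP_Pa"].to_numpy(dtype=float),
        cell_id=df["cell_id"].to_numpy() if "cell_id" in df.columns else None,
    )


def read_ring_stack(path: str | Path, pixel_size: float = 0.1) -> list[RingImage]:
    """Read a defocused-bead time-lapse TIFF stack as RingImage frames."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return [RingImage(frame.astype(float), pixel_size=pixel_size) for frame in data]


def write_ring_stack(frames: list[RingImage], path: str | Path) -> None:
    """Write RingImage frames as a float32 multi-page TIFF stack."""
    tifffile.imwrite(
        path,
        np.stack([f.pixels for f in frames]).astype(np.float32),
        photometric="minisblack",
    )


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    return x


def write_result(
    result: FitResult | SurfaceResponse | Calibration,
    out_dir: str | Path,
    name: str = "result",
    config: RunConfig | None = None,
    force: bool = False,
) -> list[Path]:
    """Serialise a result: JSON for scalars, CSV for series.

    FitResult and Calibration go to ``<name>.json``; a SurfaceResponse is
    written as one CSV per probe plus the steady profile (and pressure
    profile when present).  Existing files are only overwritten with
    ``force=True``.  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _check(p: Path) -> Path:
        if p.exists() and not force:
            raise FileExistsError(f"{p} exists (pass force=True to overwrite)")
        written.append(p)
        return p

    meta = {"config_hash": config.content_hash()} if config is not None else {}
    if isinstance(result, FitResult):
        payload = {
            "E_Pa": result.E, "D_um2_per_s": result.D,
            "objective": result.objective, "converged": result.converged,
            "n_evaluations": result.n_evaluations,
            "grid_best": _jsonable(result.grid_best),
            "warnings": list(result.warnings), **meta,
        }
        _check(out / f"{name}.json").write_text(json.dumps(payload, indent=2))
    elif isinstance(result, Calibration):
        payload = {
            "slope_um_per_px": result.slope, "intercept_um": result.intercept,
            "r2": result.r2, **meta,
        }
        _check(out / f"{name}.json").write_text(json.dumps(payload, indent=2))
    elif isinstance(result, SurfaceResponse):
        df = pd.DataFrame({"t_s": result.times})
        for j, x in enumerate(result.probe_distances):
            df[f"probe_{x:g}um"] = result.displacement[:, j]
        if result.force is not None:
            df["force_nN"] = result.force
        df.to_csv(_check(out / f"{name}_timeseries.csv"), index=False)
        r, uz = result.steady_profile
        pd.DataFrame({"r_um": r, "uz_um": uz}).to_csv(
            _check(out / f"{name}_steady_profile.csv"), index=False
        )
        if result.pressure_profile is not None:
            x, p = result.pressure_profile
            pd.DataFrame({"x_um": x, "p_Pa": p}).to_csv(
                _check(out / f"{name}_pressure_profile.csv"), index=False
            )
        if meta:
            _check(out / f"{name}_meta.json").write_text(json.dumps(meta, indent=2))
    else:
        raise TypeError(f"cannot serialise {type(result).__name__}")
    return written


def write_vtk_fields(solution, path: str | Path, t_index: int = -1) -> Path:
    """Write one time slice as legacy-VTK text (bilinear sub-cells of the mesh)."""
    mesh = solution.mesh
    path = Path(path)
    n = mesh.n_nodes
    cells = mesh.elems[:, :4]
    # pressure is defined on corner nodes; interpolate to all for output
    pfull = np.zeros(n)
    has_p = mesh.pmap >= 0
    pfull[has_p] = solution.p[t_index][mesh.pmap[has_p]]
    # midside/centre values from corner means (output convenience only)
    pel = pfull[cells]
    for a, (i, j) in enumerate([(0, 1), (1, 2), (2, 3), (3, 0)]):
        pfull[mesh.elems[:, 4 + a]] = 0.5 * (pel[:, i] + pel[:, j])
    pfull[mesh.elems[:, 8]] = pel.mean(axis=1)

    lines = ["# vtk DataFile Version 3.0", "porocell fields", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {n} double"]
    for r, z in mesh.coords:
        lines.append(f"{r:.9g} {z:.9g} 0")
    lines.append(f"CELLS {len(cells)} {5 * len(cells)}")
    for c in cells:
        lines.append("4 " + " ".join(str(i) for i in c))
    lines.append(f"CELL_TYPES {len(cells)}")
    lines.extend(["9"] * len(cells))
    lines.append(f"POINT_DATA {n}")
    lines.append("VECTORS displacement double")
    for ur, uz in solution.u[t_index]:
        lines.append(f"{ur:.9g} {uz:.9g} 0")
    lines.append("SCALARS pore_pressure double 1")
    lines.append("LOOKUP_TABLE default")
    for p in pfull:
        lines.append(f"{p:.9g}")
    path.write_text("\n".join(lines) + "\n")
    return path
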