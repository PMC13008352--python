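"""Axisymmetric structured meshes for the cell geometries.

All domains are meridian (r, z) sections of axisymmetric bodies, meshed with
structured grids of 9-node quadrilaterals (displacement / geometry) whose
corner nodes carry the bilinear pore-pressure space.  Supported shapes:

``disk`` / ``column``
    Rectangle [0, radius] x [0, thickness]; the disk models a cell slab
    indented on its top face, the column is the 1D consolidation geometry.
``elliptical_cap``
    Half-ellipse profile z = thickness * sqrt(1 - (r/radius)^2), the
    idealised shape of a spread cell; truncated at a small rim height so
    elements stay well-shaped.

A cortex (low-permeability membrane-cortex layer, typically 250 nm) can be
carried as a separate element region occupying the top ``cortex_thickness``
of each node column, resolved by two element rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fem import GAUSS_PTS, GAUSS_WTS, shape_q9

__all__ = ["ScenarioGeometry", "Mesh", "build_mesh"]


@dataclass
class ScenarioGeometry:
    """Axisymmetric cell geometry.

    Parameters
    ----------
    shape:
        ``"disk"``, ``"column"`` or ``"elliptical_cap"``.
    radius:
        Outer radius of the meridian section [um].
    thickness:
        Height of the section on the axis [um].
    cortex_thickness:
        Thickness of the membrane-cortex surface layer [um]; 0 for a
        single-layer model.
    indenter_radius:
        Radius R of the spherical indenter [um] (indentation only).
    contact_or_sink_radius:
        Radius of the pipette contact / sink patch on the top surface [um].
    rim_thickness:
        Height at which the elliptical cap is truncated [um]; ignored for
        rectangular shapes.
    """

    shape: str
    radius: float
    thickness: float
    cortex_thickness: float = 0.0
    indenter_radius: float = 2.0
    contact_or_sink_radius: float = 1.0
    rim_thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "column", "elliptical_cap"):
            raise ValueError(f"unknown shape {self.shape!r}")
        for name in ("radius", "thickness", "indenter_radius", "contact_or_sink_radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.cortex_thickness < 0:
            raise ValueError("cortex_thickness must be >= 0")
        if self.cortex_thickness >= self.thickness:
            raise ValueError(
                f"degenerate geometry: cortex_thickness={self.cortex_thickness} "
                f">= thickness={self.thickness}"
            )
        if self.contact_or_sink_radius >= self.radius:
            raise ValueError("contact_or_sink_radius must be < radius")

    def surface_height(self, r: np.ndarray) -> np.ndarray:
        """Top-surface height z(r) of the undeformed section."""
        r = np.asarray(r, dtype=float)
        if self.shape in ("disk", "column"):
            return np.full_like(r, self.thickness)
        h = self.thickness * np.sqrt(np.clip(1.0 - (r / self.radius) ** 2, 0.0, None))
        return np.maximum(h, self.rim_thickness)


@dataclass
class Mesh:
    """Structured Q9/Q4 mesh of a meridian section.

    Attributes
    ----------
    coords:
        (n_nodes, 2) node coordinates (r, z) [um].
    elems:
        (n_elems, 9) Q9 connectivity (local order of :mod:`porocell._fem`).
    region:
        (n_elems,) region id: 0 = cytoplasm, 1 = cortex.
    pmap:
        (n_nodes,) compact pressure-dof index for corner nodes, -1 elsewhere.
    boundary:
        Node-id arrays for the tagged exterior segments ``axis``, ``rim``,
        ``bottom``, ``top``.
    """

    coords: np.ndarray
    elems: np.ndarray
    region: np.ndarray
    pmap: np.ndarray
    boundary: dict[str, np.ndarray]
    geometry: ScenarioGeometry
    n_pnodes: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_pnodes = int((self.pmap >= 0).sum())

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def top_surface(self) -> tuple[np.ndarray, np.ndarray]:
        """Top-surface node ids and radii, ordered by increasing r."""
        ids = self.boundary["top"]
        order = np.argsort(self.coords[ids, 0])
        ids = ids[order]
        return ids, self.coords[ids, 0]

    def element_areas(self) -> np.ndarray:
        """Meridian-plane element areas by 3x3 Gauss quadrature [um^2]."""
        xe = self.coords[self.elems]  # (ne, 9, 2)
        areas = np.zeros(self.n_elems)
        for (xi, eta), w in zip(GAUSS_PTS, GAUSS_WTS):
            _, dN = shape_q9(xi, eta)
            J = np.einsum("ai,eaj->eij", dN, xe)
            areas += w * np.abs(np.linalg.det(J))
        return areas


def _node_levels(breaks: np.ndarray) -> np.ndarray:
    """Interleave element breakpoints with their midpoints."""
    levels = np.empty(2 * (len(breaks) - 1) + 1)
    levels[0::2] = breaks
    levels[1::2] = 0.5 * (breaks[:-1] + breaks[1:])
    return levels


def build_mesh(
    geometry: ScenarioGeometry,
    resolution: float,
    r_breaks: np.ndarray | None = None,
    n_z: int | None = None,
    z_bias: float = 1.0,
) -> Mesh:
    """Build a conforming structured mesh of the geometry.

    Parameters
    ----------
    geometry:
        The axisymmetric section to mesh.
    resolution:
        Target element size [um]; must be positive and no larger than twice
        the smallest geometric feature.
    r_breaks:
        Optional explicit radial element boundaries (overrides the uniform
        radial subdivision); must start at 0 and end at ``geometry.radius``
        (elliptical caps are truncated at the rim internally).
    n_z:
        Optional explicit number of element rows through the cytoplasm.
    z_bias:
        Ratio of bottom to top element height (> 1 concentrates rows near
        the loaded top surface; default 1 = uniform).

    The cortex layer, when present, is always resolved by two element rows
    through its thickness.
    """
    if not resolution > 0:
        raise ValueError("resolution must be positive")
    min_feature = min(geometry.radius, geometry.thickness)
    if resolution > 2.0 * min_feature:
        raise ValueError("resolution too coarse for the geometry")

    g = geometry
    r_max = g.radius
    if g.shape == "elliptical_cap":
        # truncate where the cap height reaches the rim height
        r_max = g.radius * np.sqrt(max(1.0 - (g.rim_thickness / g.thickness) ** 2, 0.0))

    if r_breaks is None:
        n_r = max(int(np.ceil(r_max / resolution)), 2)
        r_breaks = np.linspace(0.0, r_max, n_r + 1)
    else:
        r_breaks = np.asarray(r_breaks, dtype=float)
        if g.shape == "elliptical_cap":
            r_breaks = r_breaks * (r_max / r_breaks[-1])
    r_lv = _node_levels(r_breaks)
    n_r = len(r_breaks) - 1

    tc = g.cortex_thickness
    eff_thick = g.thickness - tc
    if n_z is None:
        n_z = max(int(np.ceil(eff_thick / resolution)), 2)
    n_cx = 2 if tc > 0 else 0
    if tc > 0 and tc / 2.0 > resolution:
        n_cx = int(np.ceil(tc / resolution))
    n_zt = n_z + n_cx

    # per-column z levels: cytoplasm rows fill [0, h - tc], cortex rows [h - tc, h]
    h_col = g.surface_height(r_lv)
    if z_bias == 1.0 or n_z == 1:
        frac_cyto = np.linspace(0.0, 1.0, n_z + 1)
    else:
        q = (1.0 / z_bias) ** (1.0 / (n_z - 1))  # element heights shrink upward
        w = q ** np.arange(n_z)
        frac_cyto = np.concatenate([[0.0], np.cumsum(w) / w.sum()])
    z_lv = np.empty((len(r_lv), 2 * n_zt + 1))
    for c, h in enumerate(h_col):
        zb = np.concatenate(
            [
                (h - tc) * frac_cyto,
                (h - tc) + tc * np.linspace(0.0, 1.0, n_cx + 1)[1:] if n_cx else [],
            ]
        )
        z_lv[c] = _node_levels(zb)

    n_lr, n_lz = len(r_lv), 2 * n_zt + 1
    coords = np.empty((n_lr * n_lz, 2))
    for i in range(n_lr):
        sl = slice(i * n_lz, (i + 1) * n_lz)
        coords[sl, 0] = r_lv[i]
        coords[sl, 1] = z_lv[i]

    def nid(i: int, j: int) -> int:
        return i * n_lz + j

    elems = np.empty((n_r * n_zt, 9), dtype=np.int64)
    region = np.zeros(n_r * n_zt, dtype=np.int64)
    e = 0
    for er in range(n_r):
        i0 = 2 * er
        for ez in range(n_zt):
            j0 = 2 * ez
            elems[e] = [
                nid(i0, j0), nid(i0 + 2, j0), nid(i0 + 2, j0 + 2), nid(i0, j0 + 2),
                nid(i0 + 1, j0), nid(i0 + 2, j0 + 1), nid(i0 + 1, j0 + 2), nid(i0, j0 + 1),
                nid(i0 + 1, j0 + 1),
            ]
            if ez >= n_z:
                region[e] = 1
            e += 1

    pmap = np.full(n_lr * n_lz, -1, dtype=np.int64)
    corner = [nid(i, j) for i in range(0, n_lr, 2) for j in range(0, n_lz, 2)]
    pmap[np.asarray(corner)] = np.arange(len(corner))

    boundary = {
        "axis": np.array([nid(0, j) for j in range(n_lz)]),
        "rim": np.array([nid(n_lr - 1, j) for j in range(n_lz)]),
        "bottom": np.array([nid(i, 0) for i in range(n_lr)]),
        "top": np.array([nid(i, n_lz - 1) for i in range(n_lr)]),
    }
    return Mesh(coords, elems, region, pmap, boundary, geometry)
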