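"""Radial finite-volume grids for the per-segment conduction operator.

Each segment is discretized on a vertex-centred radial grid: nodes run from
the axis/centre (r = 0) to the outer surface (r = R), control-volume faces
sit midway between nodes, and layer interfaces always coincide with a node
so tissue assignment is unambiguous.  Cell volumes telescope to the exact
segment volume.  The skin shell is always resolved by at least four interior
nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .body import BodySegment
from .tissues import tissue_properties

__all__ = ["RadialGrid", "build_grid"]

MIN_SKIN_NODES = 4


@dataclass(frozen=True)
class RadialGrid:
    """Discretization of one segment.

    All areas/volumes are totals over the segment's ``count`` copies.

    Attributes
    ----------
    r : ndarray
        Node radii, m, strictly increasing, ``r[0] = 0``, ``r[-1] = R``.
    faces : ndarray
        Control-volume face radii, length ``n + 1``.
    vol : ndarray
        Cell volumes, m³ (× count); sums exactly to the segment volume.
    cond : ndarray
        Inter-node conductances, W/°C (× count), length ``n − 1``;
        ``cond[i]`` couples nodes ``i`` and ``i+1`` through the shared face
        with the two half-cell tissue resistances in series.
    surface_area : float
        Exposed outer area, m² (× count).
    tissue_idx : ndarray
        Layer index per node (nodes on an interface belong to the inner
        layer).
    tissue_names : tuple of str
        Layer index → tissue name.
    vol_by_layer : ndarray, shape (n, n_layers)
        Exact volume of each cell lying inside each tissue layer; cells
        straddling an interface are split so that volumetric properties
        (heat capacity, perfusion, metabolism) are second-order accurate.
    """

    segment_name: str
    r: np.ndarray
    faces: np.ndarray
    vol: np.ndarray
    cond: np.ndarray
    surface_area: float
    tissue_idx: np.ndarray
    tissue_names: tuple[str, ...]
    vol_by_layer: np.ndarray

    @property
    def n(self) -> int:
        return self.r.size

    def tissue_of(self, i: int) -> str:
        return self.tissue_names[self.tissue_idx[i]]

    def nodes_in(self, tissue: str) -> np.ndarray:
        """Boolean mask of nodes assigned to ``tissue``."""
        names = np.array(self.tissue_names)[self.tissue_idx]
        return names == tissue


def _face_area(segment: BodySegment, rf: np.ndarray) -> np.ndarray:
    if segment.shape == "sphere":
        return 4.0 * math.pi * rf**2 * segment.count
    return 2.0 * math.pi * rf * segment.length * segment.count


def _cell_volume(segment: BodySegment, r_in: np.ndarray, r_out: np.ndarray) -> np.ndarray:
    if segment.shape == "sphere":
        return 4.0 / 3.0 * math.pi * (r_out**3 - r_in**3) * segment.count
    return math.pi * (r_out**2 - r_in**2) * segment.length * segment.count


def build_grid(segment: BodySegment, nr: int = 40) -> RadialGrid:
    """Build the radial grid for one segment.

    ``nr`` is the approximate total node count; the skin shell always gets
    at least :data:`MIN_SKIN_NODES` + 1 nodes (interface to surface) and the
    interior layers share the remainder proportionally to their thickness.
    """
    if nr < 8:
        raise ValueError("nr must be at least 8")
    if not segment.layers:
        raise ValueError(f"segment {segment.name!r}: no tissue layers defined")
    bounds = [0.0] + [r for _, r in segment.layers]
    names = tuple(t for t, _ in segment.layers)

    thickness = np.diff(bounds)
    if len(names) == 1:
        # uniform single-tissue segment (verification cases)
        r = np.linspace(0.0, segment.outer_radius, nr)
        tissue_idx = np.zeros(nr, dtype=int)
        return _assemble(segment, r, tissue_idx, bounds, names)

    n_skin = max(MIN_SKIN_NODES + 1, max(5, nr // 7))
    interior_total = max(nr - n_skin, 3 * (len(names) - 1))
    interior_thick = thickness[:-1]
    # distribute interior nodes proportionally, at least 3 per layer
    counts = np.maximum(
        3, np.round(interior_total * interior_thick / interior_thick.sum()).astype(int)
    )

    radii: list[np.ndarray] = []
    tidx: list[np.ndarray] = []
    for layer, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        if layer < len(names) - 1:
            # interior layers: grade nodes toward the outer edge, where
            # perfusion boundary layers and the steepest gradients sit
            m = counts[layer]
            u = np.linspace(0.0, 1.0, m + 1)
            pts = a + (b - a) * (1.0 - (1.0 - u) ** 1.7)
        else:
            m = n_skin
            pts = np.linspace(a, b, m + 1)
        if layer > 0:
            pts = pts[1:]  # interface node already emitted by the inner layer
            tidx.append(np.full(pts.size, layer))
        else:
            tidx.append(np.full(pts.size, layer))
        radii.append(pts)
    r = np.concatenate(radii)
    tissue_idx = np.concatenate(tidx)
    # nodes exactly on an interface belong to the inner layer
    for layer, b in enumerate(bounds[1:-1]):
        tissue_idx[np.isclose(r, b)] = layer
    return _assemble(segment, r, tissue_idx, bounds, names)


def _assemble(
    segment: BodySegment,
    r: np.ndarray,
    tissue_idx: np.ndarray,
    bounds: list[float],
    names: tuple[str, ...],
) -> RadialGrid:
    faces = np.empty(r.size + 1)
    faces[0] = 0.0
    faces[-1] = segment.outer_radius
    faces[1:-1] = 0.5 * (r[:-1] + r[1:])

    vol = _cell_volume(segment, faces[:-1], faces[1:])
    area_f = _face_area(segment, faces[1:-1])

    # exact split of every cell volume across the tissue layers
    vol_by_layer = np.zeros((r.size, len(names)))
    for layer, (la, lb) in enumerate(zip(bounds[:-1], bounds[1:])):
        a = np.clip(faces[:-1], la, lb)
        b = np.clip(faces[1:], la, lb)
        keep = b > a
        vol_by_layer[keep, layer] = _cell_volume(segment, a[keep], b[keep])

    k_node = np.array([tissue_properties(names[j]).k for j in tissue_idx])
    # series resistance of the two half-cells either side of each face
    d_in = faces[1:-1] - r[:-1]
    d_out = r[1:] - faces[1:-1]
    resist = d_in / k_node[:-1] + d_out / k_node[1:]
    cond = area_f / resist

    return RadialGrid(
        segment_name=segment.name,
        r=r,
        faces=faces,
        vol=vol,
        cond=cond,
        surface_area=_face_area(segment, np.array([segment.outer_radius]))[0],
        tissue_idx=tissue_idx,
        tissue_names=names,
        vol_by_layer=vol_by_layer,
    )
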