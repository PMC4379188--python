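"""Discrete cell domain on the substrate mesh.

The cell occupies a face-connected set of hexahedral elements.  Migration
happens by swapping one front element in (extension) and one rear element
out (retraction) at a time, keeping the element count — a proxy for cell
volume — constant.  Pseudopodia (the protruding volume beyond the nominal
radius) are capped at 10% of the cell volume.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .fem import HexMesh

__all__ = [
    "CellDomain",
    "init_spherical_cell",
    "membrane_nodes",
    "membrane_area",
    "front_rear_partition",
    "select_extension_retraction",
    "remodel",
    "principal_dimensions",
    "shape_factor",
    "pseudopod_fraction",
    "is_face_connected",
]

PSEUDOPOD_CAP = 0.10


@dataclass
class CellDomain:
    """Evolving set of cell elements with cached membrane geometry."""

    mesh: HexMesh
    elements: set[int]
    r: float                                  # nominal cell radius (um)
    membrane_node_ids: np.ndarray = field(default=None, repr=False)
    S: float = 0.0                            # membrane area (um^2)

    def __post_init__(self) -> None:
        self._refresh()

    @property
    def n_cell(self) -> int:
        return len(self.elements)

    @property
    def centroid(self) -> np.ndarray:
        return self._centroid

    @property
    def faces(self):
        """Cached (node_ids, outward normals, areas, owners) of ∂Ω′."""
        return self._faces

    @property
    def e_i(self) -> np.ndarray:
        """Unit vectors from each membrane node towards the centroid."""
        coords = self.mesh.node_coords[self.membrane_node_ids]
        v = self.centroid[None, :] - coords
        nrm = np.linalg.norm(v, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        return v / nrm

    def _refresh(self) -> None:
        self._centroid = self.mesh.element_centroids[
            sorted(self.elements)].mean(axis=0)
        self._faces = exposed_faces(self.mesh, self.elements)
        f_nodes, _, f_areas, _ = self._faces
        self.membrane_node_ids = np.unique(f_nodes)
        self.S = float(f_areas.sum())

    def copy(self) -> "CellDomain":
        return CellDomain(self.mesh, set(self.elements), self.r)


def _face_neighbors(mesh: HexMesh, eid: int):
    """Face-neighbour ids of one element; -1 marks the outside of the mesh."""
    return mesh.element_neighbors[eid]


def is_face_connected(mesh: HexMesh, elements: set[int]) -> bool:
    if not elements:
        return False
    table = mesh.element_neighbors
    seen = {next(iter(elements))}
    queue = deque(seen)
    while queue:
        e = queue.popleft()
        for nb in table[e]:
            nb = int(nb)
            if nb in elements and nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return len(seen) == len(elements)


def init_spherical_cell(mesh: HexMesh, center, r: float) -> CellDomain:
    """Voxelized ball: elements whose centroid lies within r of center."""
    center = np.asarray(center, dtype=float)
    lo, hi = mesh.origin, mesh.origin + [mesh.Lx, mesh.Ly, mesh.Lz]
    if np.any(center - r < lo) or np.any(center + r > hi):
        raise ValueError("sphere does not fit inside the mesh")
    d = np.linalg.norm(mesh.element_centroids - center, axis=1)
    elems = set(np.flatnonzero(d <= r).tolist())
    if not elems:
        raise ValueError("radius too small: no element centroid inside sphere")
    if not is_face_connected(mesh, elems):  # pragma: no cover - voxel balls connect
        raise ValueError("voxelized sphere is not face-connected")
    return CellDomain(mesh, elems, r)


def membrane_nodes(mesh: HexMesh, elements: set[int]):
    """Membrane node ids and membrane area of an element set.

    A node is on the membrane when it is shared by a cell element and a
    non-cell element (or lies on the mesh boundary).  The membrane area
    is the number of exposed element faces times the face area.
    """
    if not elements:
        raise ValueError("empty cell domain")
    face_areas = (mesh.hy * mesh.hz, mesh.hy * mesh.hz,
                  mesh.hx * mesh.hz, mesh.hx * mesh.hz,
                  mesh.hx * mesh.hy, mesh.hx * mesh.hy)
    nodes: set[int] = set()
    area = 0.0
    conn = mesh.element_nodes
    for e in elements:
        for f, nb in enumerate(_face_neighbors(mesh, e)):
            if nb not in elements:  # exposed (includes nb == -1)
                area += face_areas[f]
        # nodes on any exposed face -> just check node-level exposure below
    # node-level: a node of a cell element is a membrane node unless all
    # its incident elements are cell elements and none is missing (interior)
    for e in elements:
        i, j, k = mesh.elem_ijk(e)
        for nid in conn[e]:
            if nid in nodes:
                continue
            ni, nj, nk = mesh.node_ijk(nid)
            exposed = False
            for dk in (-1, 0):
                for dj in (-1, 0):
                    for di in (-1, 0):
                        ei, ej, ek = ni + di, nj + dj, nk + dk
                        if not (0 <= ei < mesh.nx and 0 <= ej < mesh.ny
                                and 0 <= ek < mesh.nz):
                            exposed = True
                        elif int(mesh.elem_id(ei, ej, ek)) not in elements:
                            exposed = True
                    if exposed:
                        break
                if exposed:
                    break
            if exposed:
                nodes.add(int(nid))
    return np.array(sorted(nodes), dtype=np.int64), area


def membrane_area(mesh: HexMesh, elements: set[int]) -> float:
    return membrane_nodes(mesh, elements)[1]


# local corner indices (a = di + 2 dj + 4 dk) of each element face
_FACE_CORNERS = {
    (0, 1): (1, 3, 5, 7), (0, -1): (0, 2, 4, 6),
    (1, 1): (2, 3, 6, 7), (1, -1): (0, 1, 4, 5),
    (2, 1): (4, 5, 6, 7), (2, -1): (0, 1, 2, 3),
}


def exposed_faces(mesh: HexMesh, elements: set[int]):
    """Exposed (membrane) faces of the cell domain.

    Returns (node_ids (F, 4), outward normals (F, 3), areas (F,),
    owner element ids (F,)).  The union of face node ids is exactly the
    membrane node set, and the areas sum to the membrane area S(t).
    Face-weighted normals of a closed voxel surface sum to zero, which
    makes them the right quadrature for net-traction sums: a uniform
    stress then yields a net force of exactly zero instead of
    voxel-shape noise.
    """
    if not elements:
        raise ValueError("empty cell domain")
    conn = mesh.element_nodes
    areas_by_axis = (mesh.hy * mesh.hz, mesh.hx * mesh.hz, mesh.hx * mesh.hy)
    el = np.fromiter(elements, dtype=np.int64, count=len(elements))
    el.sort()
    nb = mesh.element_neighbors[el]                      # (N, 6)
    exposed = ~np.isin(nb, el)                           # -1 is never a member
    # neighbour-table column order: +x, -x, +y, -y, +z, -z
    col_dirs = [(0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)]
    nodes, normals, areas, owners = [], [], [], []
    for col, (axis, sgn) in enumerate(col_dirs):
        rows = np.flatnonzero(exposed[:, col])
        if rows.size == 0:
            continue
        own = el[rows]
        nodes.append(conn[own][:, list(_FACE_CORNERS[(axis, sgn)])])
        nrm = np.zeros((rows.size, 3))
        nrm[:, axis] = sgn
        normals.append(nrm)
        areas.append(np.full(rows.size, areas_by_axis[axis]))
        owners.append(own)
    return (np.concatenate(nodes), np.concatenate(normals),
            np.concatenate(areas), np.concatenate(owners))


def front_rear_partition(cell: CellDomain, e_pol: np.ndarray):
    """Split membrane nodes by the plane through the centroid normal to e_pol.

    Returns (front node ids, rear node ids, delta values) where delta is
    the signed distance of each membrane node along e_pol.  Nodes exactly
    on the plane count as front.
    """
    n = np.asarray(e_pol, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("e_pol must be a unit vector")
    s = cell.mesh.node_coords[cell.membrane_node_ids] - cell.centroid
    delta = s @ n
    front = cell.membrane_node_ids[delta >= 0.0]
    rear = cell.membrane_node_ids[delta < 0.0]
    return front, rear, delta


def _outside_fraction(d: np.ndarray, r: float, h: float) -> np.ndarray:
    """Approximate per-element volume fraction lying beyond radius r.

    Linear ramp over one element edge centred on the sphere surface —
    binary counting at coarse resolution jams the remodeling because
    every element of the surface shell straddles the radius.
    """
    return np.clip((np.asarray(d) - r) / h, 0.0, 1.0)


def pseudopod_fraction(cell: CellDomain) -> float:
    """Fraction of cell volume protruding beyond the nominal radius."""
    h = (cell.mesh.hx + cell.mesh.hy + cell.mesh.hz) / 3.0
    d = np.linalg.norm(
        cell.mesh.element_centroids[sorted(cell.elements)] - cell.centroid, axis=1
    )
    return float(np.mean(_outside_fraction(d, cell.r, h)))


def _candidate_swap_ok(cell: CellDomain, e_ex: int, e_re: int) -> bool:
    """Feasibility of a swap: connectivity, pseudopod cap, conservation."""
    mesh = cell.mesh
    new_set = set(cell.elements)
    new_set.discard(e_re)
    new_set.add(e_ex)
    if len(new_set) != cell.n_cell:
        return False
    # extension must touch the remaining body by a face
    if not any(nb in new_set for nb in _face_neighbors(mesh, e_ex)):
        return False
    if not is_face_connected(mesh, new_set):
        return False
    cents = mesh.element_centroids[sorted(new_set)]
    centroid = cents.mean(axis=0)
    h = (mesh.hx + mesh.hy + mesh.hz) / 3.0
    d = np.linalg.norm(cents - centroid, axis=1)
    return float(np.mean(_outside_fraction(d, cell.r, h))) <= PSEUDOPOD_CAP + 1e-9


def _elements_incident_to_node(mesh: HexMesh, nid: int):
    row = mesh.node_incident_elements[nid]
    return [int(e) for e in row if e >= 0]


def select_extension_retraction(cell: CellDomain, e_pol: np.ndarray,
                                delta: np.ndarray | None = None,
                                forbidden_ex: set[int] = frozenset(),
                                forbidden_re: set[int] = frozenset()):
    """Pick the (extension, retraction) element pair for one swap.

    Extension: a substrate element incident to the maximum-delta membrane
    node, preferring the one whose centroid projects farthest along
    ``e_pol``.  Retraction: a cell element incident to the minimum-delta
    node, preferring the most rearward centroid.  Candidate pairs failing
    connectivity, the pseudopod cap or mesh bounds are skipped in ranked
    order.  Returns None when the cell is jammed.
    """
    mesh = cell.mesh
    n = np.asarray(e_pol, dtype=float)
    if delta is None:
        _, _, delta = front_rear_partition(cell, n)
    order_front = np.argsort(delta)[::-1]
    order_rear = np.argsort(delta)
    centroid = cell.centroid
    h = (mesh.hx + mesh.hy + mesh.hz) / 3.0
    budget = PSEUDOPOD_CAP * cell.n_cell

    cell_list = sorted(cell.elements)
    cell_dist = np.linalg.norm(mesh.element_centroids[cell_list] - centroid, axis=1)
    out_frac = _outside_fraction(cell_dist, cell.r, h)
    total_out = float(out_frac.sum())

    incident_table = mesh.node_incident_elements
    neighbor_table = mesh.element_neighbors

    def gen_extensions():
        """Substrate elements face-attached to the cell, best delta first."""
        seen: set[int] = set()
        for idx in order_front:
            nid = int(cell.membrane_node_ids[idx])
            incident = [int(e) for e in incident_table[nid]
                        if e >= 0 and int(e) not in cell.elements
                        and int(e) not in seen and int(e) not in forbidden_ex
                        and any(int(nb) in cell.elements
                                for nb in neighbor_table[e])]
            incident.sort(
                key=lambda e: -(mesh.element_centroids[e] - centroid) @ n)
            for e in incident:
                seen.add(e)
                yield e

    def gen_retractions():
        """Rearmost cell elements, then most distant (pseudopod recycling)."""
        seen: set[int] = set()
        for idx in order_rear:
            nid = int(cell.membrane_node_ids[idx])
            incident = [int(e) for e in incident_table[nid]
                        if e >= 0 and int(e) in cell.elements
                        and int(e) not in seen and int(e) not in forbidden_re]
            incident.sort(
                key=lambda e: (mesh.element_centroids[e] - centroid) @ n)
            for e in incident:
                seen.add(e)
                yield e
        for i in np.argsort(cell_dist)[::-1][:8]:
            e = int(cell_list[i])
            if e not in seen and e not in forbidden_re:
                seen.add(e)
                yield e

    frac_of = dict(zip(cell_list, out_frac))
    re_pool: list[int] = []
    re_iter = gen_retractions()
    for n_ex, e_ex in enumerate(gen_extensions()):
        if n_ex >= 80:
            break
        ex_out = float(_outside_fraction(
            np.linalg.norm(mesh.element_centroids[e_ex] - centroid), cell.r, h))
        for slot in range(20):
            while len(re_pool) <= slot:
                nxt = next(re_iter, None)
                if nxt is None:
                    break
                re_pool.append(nxt)
            if len(re_pool) <= slot:
                break
            e_re = re_pool[slot]
            # cheap pseudopod-budget pre-check before any connectivity work
            if total_out + ex_out - frac_of[e_re] > budget + 0.5:
                continue
            if _candidate_swap_ok(cell, e_ex, e_re):
                return e_ex, e_re
    return None


def remodel(cell: CellDomain, e_ex: int, e_re: int) -> np.ndarray:
    """Apply one extension/retraction swap in place.

    Returns the centroid displacement, ``(x_ex - x_re) / N_cell``.
    """
    if e_ex in cell.elements or e_re not in cell.elements:
        raise ValueError("invalid swap pair")
    mesh = cell.mesh
    disp = (mesh.element_centroids[e_ex] - mesh.element_centroids[e_re]) / cell.n_cell
    cell.elements.discard(e_re)
    cell.elements.add(e_ex)
    cell._refresh()
    return disp


def principal_dimensions(cell: CellDomain):
    """Sorted (l_max, l_med, l_min) extents along the inertia eigen-axes.

    Axes are the eigenvectors of the second-moment tensor of the element
    centroids; the extent along each axis is the centroid span plus one
    element edge, making the result rotation-invariant for voxel sets.
    """
    cents = cell.mesh.element_centroids[sorted(cell.elements)]
    h = (cell.mesh.hx + cell.mesh.hy + cell.mesh.hz) / 3.0
    if len(cents) == 1:
        return h, h, h
    rel = cents - cents.mean(axis=0)
    cov = rel.T @ rel / len(rel)
    _, vecs = np.linalg.eigh(cov)
    proj = rel @ vecs
    spans = proj.max(axis=0) - proj.min(axis=0) + h
    spans = np.sort(spans)[::-1]
    return float(spans[0]), float(spans[1]), float(spans[2])


def shape_factor(l_max: float, l_med: float, l_min: float) -> float:
    """Corey shape factor, (l_max * l_med / l_min^2)^0.09; 1 for a sphere."""
    if l_min <= 0:
        raise ValueError("l_min must be positive")
    if not (l_max >= l_med >= l_min):
        raise ValueError("dimensions must be sorted descending")
    return float((l_max * l_med / l_min**2) ** 0.09)
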