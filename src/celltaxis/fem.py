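"""Small-strain linear elasticity on a regular hexahedral grid.

The substrate is a box meshed with 8-node trilinear hexahedra, one Young's
modulus per element (stiffness-gradient substrates, plus a distinct cell
modulus during the sensing solve).  The mechano-sensing step applies
centripetal point loads at the membrane nodes, solves the elastic problem
and returns nodal strain tensors.

For per-step speed the sensing solve can be restricted to a padded window
around the cell: window faces that coincide with real substrate surfaces
stay traction free, cut faces are clamped (the sensing loads are
self-equilibrated and their strain field decays rapidly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "HexMesh",
    "ElasticSolution",
    "hex_element_stiffness",
    "assemble_system",
    "minimal_constraints",
    "apply_sensing_loads",
    "solve_sensing",
    "element_strains",
    "node_strain_tensors",
    "membrane_strain_tensor",
    "directional_strain",
    "SensingSolver",
]

_GAUSS = 1.0 / np.sqrt(3.0)
# local node (di, dj, dk) order: a = di + 2*dj + 4*dk
_LOCAL_CORNERS = np.array(
    [[di, dj, dk] for dk in (0, 1) for dj in (0, 1) for di in (0, 1)], dtype=int
)


class HexMesh:
    """Regular axis-aligned grid of identical hexahedral elements.

    Parameters are the box dimensions (um), element counts per axis and an
    optional origin offset (used for window sub-meshes).
    """

    def __init__(self, Lx, Ly, Lz, nx, ny, nz, origin=(0.0, 0.0, 0.0)):
        if min(nx, ny, nz) < 1:
            raise ValueError("element counts must be >= 1")
        if min(Lx, Ly, Lz) <= 0:
            raise ValueError("box dimensions must be positive")
        self.Lx, self.Ly, self.Lz = float(Lx), float(Ly), float(Lz)
        self.nx, self.ny, self.nz = int(nx), int(ny), int(nz)
        self.origin = np.asarray(origin, dtype=float)
        self.hx = self.Lx / self.nx
        self.hy = self.Ly / self.ny
        self.hz = self.Lz / self.nz
        self.n_elems = self.nx * self.ny * self.nz
        self.n_nodes = (self.nx + 1) * (self.ny + 1) * (self.nz + 1)
        self.n_dofs = 3 * self.n_nodes

    # ---- indexing -----------------------------------------------------
    def node_id(self, i, j, k):
        return i + (self.nx + 1) * (np.asarray(j) + (self.ny + 1) * np.asarray(k))

    def node_ijk(self, nid):
        nid = np.asarray(nid)
        i = nid % (self.nx + 1)
        rest = nid // (self.nx + 1)
        return i, rest % (self.ny + 1), rest // (self.ny + 1)

    def elem_id(self, i, j, k):
        return np.asarray(i) + self.nx * (np.asarray(j) + self.ny * np.asarray(k))

    def elem_ijk(self, eid):
        eid = np.asarray(eid)
        i = eid % self.nx
        rest = eid // self.nx
        return i, rest % self.ny, rest // self.ny

    @property
    def element_nodes(self) -> np.ndarray:
        """(n_elems, 8) node connectivity, cached."""
        cached = getattr(self, "_element_nodes", None)
        if cached is None:
            eids = np.arange(self.n_elems)
            i, j, k = self.elem_ijk(eids)
            conn = np.empty((self.n_elems, 8), dtype=np.int64)
            for a, (di, dj, dk) in enumerate(_LOCAL_CORNERS):
                conn[:, a] = self.node_id(i + di, j + dj, k + dk)
            cached = self._element_nodes = conn
        return cached

    @property
    def node_coords(self) -> np.ndarray:
        cached = getattr(self, "_node_coords", None)
        if cached is None:
            i, j, k = self.node_ijk(np.arange(self.n_nodes))
            cached = self._node_coords = self.origin + np.column_stack(
                [i * self.hx, j * self.hy, k * self.hz]
            ).astype(float)
        return cached

    @property
    def element_neighbors(self) -> np.ndarray:
        """(n_elems, 6) face-neighbour element ids, -1 outside the mesh.

        Order: +x, -x, +y, -y, +z, -z.
        """
        cached = getattr(self, "_element_neighbors", None)
        if cached is None:
            i, j, k = self.elem_ijk(np.arange(self.n_elems))
            out = np.full((self.n_elems, 6), -1, dtype=np.int64)
            for col, (di, dj, dk) in enumerate(
                    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                     (0, 0, 1), (0, 0, -1)]):
                ni, nj, nk = i + di, j + dj, k + dk
                ok = ((0 <= ni) & (ni < self.nx) & (0 <= nj) & (nj < self.ny)
                      & (0 <= nk) & (nk < self.nz))
                out[ok, col] = self.elem_id(ni[ok], nj[ok], nk[ok])
            cached = self._element_neighbors = out
        return cached

    @property
    def node_incident_elements(self) -> np.ndarray:
        """(n_nodes, 8) element ids incident to each node, -1 where absent."""
        cached = getattr(self, "_node_incident_elements", None)
        if cached is None:
            i, j, k = self.node_ijk(np.arange(self.n_nodes))
            out = np.full((self.n_nodes, 8), -1, dtype=np.int64)
            col = 0
            for dk in (-1, 0):
                for dj in (-1, 0):
                    for di in (-1, 0):
                        ei, ej, ek = i + di, j + dj, k + dk
                        ok = ((0 <= ei) & (ei < self.nx) & (0 <= ej)
                              & (ej < self.ny) & (0 <= ek) & (ek < self.nz))
                        out[ok, col] = self.elem_id(ei[ok], ej[ok], ek[ok])
                        col += 1
            cached = self._node_incident_elements = out
        return cached

    @property
    def element_centroids(self) -> np.ndarray:
        cached = getattr(self, "_element_centroids", None)
        if cached is None:
            i, j, k = self.elem_ijk(np.arange(self.n_elems))
            cached = self._element_centroids = self.origin + np.column_stack(
                [(i + 0.5) * self.hx, (j + 0.5) * self.hy, (k + 0.5) * self.hz]
            )
        return cached

    @property
    def element_volume(self) -> float:
        return self.hx * self.hy * self.hz


def _shape_gradients(xi, eta, zeta, hx, hy, hz) -> np.ndarray:
    """(8, 3) physical gradients of the trilinear shape functions."""
    g = np.empty((8, 3))
    for a, (di, dj, dk) in enumerate(_LOCAL_CORNERS):
        sx, sy, sz = 2 * di - 1, 2 * dj - 1, 2 * dk - 1
        g[a, 0] = sx * (1 + sy * eta) * (1 + sz * zeta) / 8.0 * (2.0 / hx)
        g[a, 1] = (1 + sx * xi) * sy * (1 + sz * zeta) / 8.0 * (2.0 / hy)
        g[a, 2] = (1 + sx * xi) * (1 + sy * eta) * sz / 8.0 * (2.0 / hz)
    return g


def _isotropic_D(E: float, nu: float) -> np.ndarray:
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def hex_element_stiffness(hx: float, hy: float, hz: float, nu: float) -> np.ndarray:
    """(24, 24) element stiffness for unit Young's modulus (2x2x2 Gauss)."""
    D = _isotropic_D(1.0, nu)
    detJ = (hx / 2) * (hy / 2) * (hz / 2)
    K = np.zeros((24, 24))
    for gz in (-_GAUSS, _GAUSS):
        for gy in (-_GAUSS, _GAUSS):
            for gx in (-_GAUSS, _GAUSS):
                g = _shape_gradients(gx, gy, gz, hx, hy, hz)
                B = np.zeros((6, 24))
                for a in range(8):
                    dx, dy, dz = g[a]
                    c = 3 * a
                    B[0, c] = dx
                    B[1, c + 1] = dy
                    B[2, c + 2] = dz
                    B[3, c] = dy
                    B[3, c + 1] = dx
                    B[4, c + 1] = dz
                    B[4, c + 2] = dy
                    B[5, c] = dz
                    B[5, c + 2] = dx
                K += B.T @ D @ B * detJ
    return K


def assemble_system(mesh: HexMesh, E_per_elem: np.ndarray, nu: float = 0.3,
                    K_ref: np.ndarray | None = None) -> sp.csr_matrix:
    """Global stiffness matrix (unconstrained, SPSD).

    Each element contributes ``E_e * K_ref``; ``K_ref`` may be passed in
    to avoid recomputing it per call.
    """
    E = np.asarray(E_per_elem, dtype=float)
    if E.shape != (mesh.n_elems,):
        raise ValueError("E_per_elem must have one modulus per element")
    if np.any(E <= 0):
        raise ValueError("all moduli must be positive")
    if K_ref is None:
        K_ref = hex_element_stiffness(mesh.hx, mesh.hy, mesh.hz, nu)
    dofs = (3 * mesh.element_nodes[:, :, None] + np.arange(3)).reshape(mesh.n_elems, 24)
    rows = np.repeat(dofs, 24, axis=1).ravel()
    cols = np.tile(dofs, (1, 24)).ravel()
    data = (E[:, None, None] * K_ref[None, :, :]).ravel()
    K = sp.coo_matrix((data, (rows, cols)), shape=(mesh.n_dofs, mesh.n_dofs))
    return K.tocsr()


def minimal_constraints(mesh: HexMesh) -> np.ndarray:
    """3-2-1 rigid-body constraint dofs (all surfaces stay traction free).

    Corner node: all three translations; its x-neighbour corner: y and z;
    its y-neighbour corner: z.  Removes the six rigid modes only.
    """
    a = mesh.node_id(0, 0, 0)
    b = mesh.node_id(mesh.nx, 0, 0)
    c = mesh.node_id(0, mesh.ny, 0)
    return np.array([3 * a, 3 * a + 1, 3 * a + 2, 3 * b + 1, 3 * b + 2, 3 * c + 2])


def apply_sensing_loads(mesh: HexMesh, membrane_node_ids: np.ndarray,
                        e_i: np.ndarray, F_sens: float) -> np.ndarray:
    """Load vector with ``F_sens * e_i`` (nN) at every membrane node."""
    if len(membrane_node_ids) == 0:
        raise ValueError("cell has no membrane nodes")
    f = np.zeros(mesh.n_dofs)
    idx = (3 * np.asarray(membrane_node_ids)[:, None] + np.arange(3)).ravel()
    f[idx] = (F_sens * np.asarray(e_i)).ravel()
    return f


# local corner indices (a = di + 2 dj + 4 dk) of each element face
_FACE_CORNERS = {
    (0, 1): (1, 3, 5, 7), (0, -1): (0, 2, 4, 6),
    (1, 1): (2, 3, 6, 7), (1, -1): (0, 1, 4, 5),
    (2, 1): (4, 5, 6, 7), (2, -1): (0, 1, 2, 3),
}
_FACE_DIRS = [(0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)]


def apply_contraction_pressure(mesh: HexMesh, elements: set[int],
                               pressure: float) -> np.ndarray:
    """Inward normal tractions on every exposed face of the cell domain.

    Statically equivalent to a uniform contraction eigenstrain of the cell
    elements; each exposed face contributes ``pressure * A_face`` split
    over its four nodes.  Smoother than nodal point loads on a lumpy
    voxel surface, which matters for the fidelity of the sensed
    deformation asymmetry.
    """
    if not elements:
        raise ValueError("empty cell domain")
    loads = np.zeros(mesh.n_dofs)
    conn = mesh.element_nodes
    areas = {0: mesh.hy * mesh.hz, 1: mesh.hx * mesh.hz, 2: mesh.hx * mesh.hy}
    for e in elements:
        i, j, k = mesh.elem_ijk(e)
        for axis, sgn in _FACE_DIRS:
            ni = int(i) + (sgn if axis == 0 else 0)
            nj = int(j) + (sgn if axis == 1 else 0)
            nk = int(k) + (sgn if axis == 2 else 0)
            if (0 <= ni < mesh.nx and 0 <= nj < mesh.ny and 0 <= nk < mesh.nz
                    and int(mesh.elem_id(ni, nj, nk)) in elements):
                continue  # internal face
            f_node = pressure * areas[axis] / 4.0
            for a in _FACE_CORNERS[(axis, sgn)]:
                loads[3 * int(conn[e][a]) + axis] -= sgn * f_node
    return loads


def element_strains(mesh: HexMesh, u: np.ndarray) -> np.ndarray:
    """(n_elems, 3, 3) small-strain tensors at the element centroids."""
    G = _shape_gradients(0.0, 0.0, 0.0, mesh.hx, mesh.hy, mesh.hz)
    U = u.reshape(-1, 3)[mesh.element_nodes]            # (n_elems, 8, 3)
    grad = np.einsum("aj,eai->eij", G, U)               # d u_i / d x_j
    return 0.5 * (grad + grad.transpose(0, 2, 1))


@dataclass
class ElasticSolution:
    """Displacements and per-element strains from one linear solve."""

    mesh: HexMesh
    u: np.ndarray                   # (n_nodes, 3) displacements (um)
    strains: np.ndarray             # (n_elems, 3, 3)


def solve_sensing(mesh: HexMesh, E_per_elem: np.ndarray, loads: np.ndarray,
                  fixed_dofs: np.ndarray | None = None, nu: float = 0.3,
                  K: sp.csr_matrix | None = None) -> ElasticSolution:
    """Direct sparse solve of the constrained elastic system."""
    if K is None:
        K = assemble_system(mesh, E_per_elem, nu)
    if fixed_dofs is None:
        fixed_dofs = minimal_constraints(mesh)
    free = np.ones(mesh.n_dofs, dtype=bool)
    free[fixed_dofs] = False
    Kff = K[free][:, free].tocsc()
    u = np.zeros(mesh.n_dofs)
    try:
        u[free] = spla.spsolve(Kff, loads[free])
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"elastic solve failed on {mesh.nx}x{mesh.ny}x{mesh.nz} mesh: {exc}"
        ) from exc
    if not np.all(np.isfinite(u)):
        raise RuntimeError("elastic solve produced non-finite displacements "
                           "(system singular after constraints?)")
    return ElasticSolution(mesh=mesh, u=u.reshape(-1, 3),
                           strains=element_strains(mesh, u))


def _incident_elements(mesh: HexMesh, node_id: int) -> list[int]:
    i, j, k = mesh.node_ijk(node_id)
    out = []
    for dk in (-1, 0):
        for dj in (-1, 0):
            for di in (-1, 0):
                ei, ej, ek = i + di, j + dj, k + dk
                if 0 <= ei < mesh.nx and 0 <= ej < mesh.ny and 0 <= ek < mesh.nz:
                    out.append(int(mesh.elem_id(ei, ej, ek)))
    return out


def membrane_strain_tensor(solution: ElasticSolution, node_id: int,
                           restrict_to: set[int] | None = None) -> np.ndarray:
    """Nodal strain: volume-weighted mean over incident elements.

    All elements of the regular grid share one volume, so this is a plain
    average of the incident centroid strain tensors.  ``restrict_to``
    limits the average to a subset of elements — the cell-internal strain
    at a membrane node averages the incident *cell* elements only (the
    surrounding substrate is stretched, not contracted, by the sensing
    loads and would corrupt the sign of the sensed deformation).
    """
    elems = _incident_elements(solution.mesh, node_id)
    if restrict_to is not None:
        elems = [e for e in elems if e in restrict_to]
    if not elems:
        raise ValueError(f"node {node_id} has no (admissible) incident elements")
    return solution.strains[elems].mean(axis=0)


def node_strain_tensors(solution: ElasticSolution, node_ids: np.ndarray,
                        restrict_to: set[int] | None = None) -> np.ndarray:
    return np.array([membrane_strain_tensor(solution, n, restrict_to)
                     for n in node_ids])


def directional_strain(eps_tensor: np.ndarray, e_i: np.ndarray) -> float:
    """Normal strain along e_i: e_i^T eps e_i (e_i must be unit)."""
    e = np.asarray(e_i, dtype=float)
    if abs(np.linalg.norm(e) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    return float(e @ np.asarray(eps_tensor) @ e)


class _WindowOperator:
    """Matrix-free constrained stiffness operator of one window.

    ``K @ x`` is evaluated element-wise (gather, small dense multiply,
    scatter-add), never forming the sparse matrix; fixed dofs act as an
    identity block.  SPD whenever the constrained system is.
    """

    def __init__(self, wmesh: HexMesh, E_local: np.ndarray, K_ref: np.ndarray,
                 fixed: np.ndarray):
        self.wmesh = wmesh
        self.E = np.asarray(E_local, dtype=float)
        self.K_ref = K_ref
        self.dofs = (3 * wmesh.element_nodes[:, :, None]
                     + np.arange(3)).reshape(wmesh.n_elems, 24)
        self.fixed = fixed
        diag = np.bincount(
            self.dofs.ravel(),
            weights=(self.E[:, None] * K_ref.diagonal()[None, :]).ravel(),
            minlength=wmesh.n_dofs)
        diag[fixed] = 1.0
        self.diag = diag

    def matvec(self, x: np.ndarray) -> np.ndarray:
        x2 = x.copy()
        x2[self.fixed] = 0.0
        ye = (x2[self.dofs] @ self.K_ref) * self.E[:, None]  # K_ref symmetric
        y = np.bincount(self.dofs.ravel(), weights=ye.ravel(),
                        minlength=self.wmesh.n_dofs)
        y[self.fixed] = x[self.fixed]
        return y

    def solve(self, loads: np.ndarray, rtol: float) -> np.ndarray:
        f = loads.copy()
        f[self.fixed] = 0.0
        n = self.wmesh.n_dofs
        A = spla.LinearOperator((n, n), matvec=self.matvec)
        M = spla.LinearOperator((n, n), matvec=lambda x: x / self.diag)
        u, info = spla.cg(A, f, rtol=rtol, atol=0.0, M=M, maxiter=5000)
        if info != 0:  # pragma: no cover - fallback path
            K = assemble_system(self.wmesh, self.E, K_ref=self.K_ref)
            free = np.ones(n, dtype=bool)
            free[self.fixed] = False
            u = np.zeros(n)
            u[free] = spla.spsolve(K[free][:, free].tocsc(), loads[free])
        return u


class SensingSolver:
    """Per-step mechano-sensing solves, optionally on a padded window.

    Holds the precomputed element stiffness, the substrate modulus field
    and cached window assembly patterns.  ``solve_membrane_strains``
    places the centripetal sensing loads, solves the elastic problem and
    returns the strain tensor at every membrane node of the cell.

    Window dimensions are quantized up to multiples of four elements so
    that only a handful of patterns are ever built per run.
    """

    def __init__(self, mesh: HexMesh, substrate_E: np.ndarray, *, nu: float = 0.3,
                 E_cell: float | None = None, pad: float = 60.0,
                 use_window: bool = True, cg_rtol: float = 1e-8,
                 loading: str = "pressure"):
        if loading not in ("pressure", "nodal"):
            raise ValueError("loading must be 'pressure' or 'nodal'")
        self.mesh = mesh
        self.substrate_E = np.asarray(substrate_E, dtype=float)
        self.nu = nu
        self.loading = loading
        self.E_cell = E_cell  # None: cell elements keep the substrate modulus
        self.pad = pad
        self.use_window = use_window
        self.cg_rtol = cg_rtol
        self.K_ref = hex_element_stiffness(mesh.hx, mesh.hy, mesh.hz, nu)
        self._window_meshes: dict[tuple, HexMesh] = {}

    # -- window construction -------------------------------------------
    def _window_ranges(self, cell_elem_ids: np.ndarray):
        """Quantized window element ranges containing the padded cell bbox."""
        m = self.mesh
        i, j, k = m.elem_ijk(cell_elem_ids)
        out = []
        for lo, hi, n, h in ((i.min(), i.max() + 1, m.nx, m.hx),
                             (j.min(), j.max() + 1, m.ny, m.hy),
                             (k.min(), k.max() + 1, m.nz, m.hz)):
            p = max(1, int(np.ceil(self.pad / h)))
            w = min(n, -(-(hi - lo + 2 * p) // 4) * 4)   # round up to mult of 4
            a = min(max(lo - (w - (hi - lo)) // 2, 0), n - w)
            out.append((a, a + w))
        return tuple(out)

    def _window_mesh(self, wnx: int, wny: int, wnz: int) -> HexMesh:
        key = (wnx, wny, wnz)
        wmesh = self._window_meshes.get(key)
        if wmesh is None:
            m = self.mesh
            wmesh = HexMesh(wnx * m.hx, wny * m.hy, wnz * m.hz, wnx, wny, wnz)
            self._window_meshes[key] = wmesh
        return wmesh

    def solve_membrane_strains(self, cell_elem_ids: np.ndarray,
                               membrane_node_ids: np.ndarray,
                               e_i: np.ndarray, F_sens: float,
                               element_strains_too: bool = False,
                               reference_too: bool = False):
        """(n_membrane, 3, 3) cell-internal strain tensors under the sensing
        contraction (averaged over incident cell elements).

        With ``element_strains_too`` additionally returns the centroid
        strain tensor of every cell element as ``{global_eid: (3, 3)}``.
        With ``reference_too`` (window mode only) a second solve of the
        same loaded shape embedded in a homogeneous, far-field-clamped
        medium is returned as a third value: subtracting it isolates the
        micro-environmental part of the sensed deformation (stiffness
        gradient, free surfaces) from the cell's own shape response.
        """
        m = self.mesh
        cell_elem_ids = np.asarray(cell_elem_ids)
        E = self.substrate_E.copy()
        if self.E_cell is not None:
            E[cell_elem_ids] = self.E_cell

        if not self.use_window:
            if self.loading == "pressure":
                loads = apply_contraction_pressure(m, set(cell_elem_ids.tolist()),
                                                   F_sens)
            else:
                loads = apply_sensing_loads(m, membrane_node_ids, e_i, F_sens)
            sol = solve_sensing(m, E, loads, nu=self.nu,
                                K=assemble_system(m, E, self.nu, K_ref=self.K_ref))
            node_eps = node_strain_tensors(sol, membrane_node_ids,
                                           restrict_to=set(cell_elem_ids.tolist()))
            if element_strains_too:
                return node_eps, {int(e): sol.strains[int(e)]
                                  for e in cell_elem_ids}
            return node_eps

        (i0, i1), (j0, j1), (k0, k1) = self._window_ranges(np.asarray(cell_elem_ids))
        wnx, wny, wnz = i1 - i0, j1 - j0, k1 - k0
        wmesh = self._window_mesh(wnx, wny, wnz)

        # global -> local element modulus map
        wi, wj, wk = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1),
                                 np.arange(k0, k1), indexing="ij")
        geids = m.elem_id(wi.ravel(), wj.ravel(), wk.ravel())
        leids = wmesh.elem_id(wi.ravel() - i0, wj.ravel() - j0, wk.ravel() - k0)
        E_local = np.empty(wmesh.n_elems)
        E_local[leids] = E[geids]

        # loads: map global membrane node ids into the window
        ni, nj, nk = m.node_ijk(np.asarray(membrane_node_ids))
        local_nodes = wmesh.node_id(ni - i0, nj - j0, nk - k0)
        g2l_e = dict(zip(geids.tolist(), leids.tolist()))
        local_cell = {g2l_e[int(e)] for e in cell_elem_ids}
        if self.loading == "pressure":
            loads = apply_contraction_pressure(wmesh, local_cell, F_sens)
        else:
            loads = apply_sensing_loads(wmesh, local_nodes, e_i, F_sens)

        # clamp cut faces (faces interior to the global mesh)
        li, lj, lk = wmesh.node_ijk(np.arange(wmesh.n_nodes))
        cut = np.zeros(wmesh.n_nodes, dtype=bool)
        if i0 > 0:
            cut |= li == 0
        if i1 < m.nx:
            cut |= li == wnx
        if j0 > 0:
            cut |= lj == 0
        if j1 < m.ny:
            cut |= lj == wny
        if k0 > 0:
            cut |= lk == 0
        if k1 < m.nz:
            cut |= lk == wnz
        if cut.any():
            fixed = (3 * np.flatnonzero(cut)[:, None] + np.arange(3)).ravel()
        else:
            fixed = minimal_constraints(wmesh)

        op = _WindowOperator(wmesh, E_local, self.K_ref, fixed)
        u = op.solve(loads, self.cg_rtol)
        sol = ElasticSolution(mesh=wmesh, u=u.reshape(-1, 3),
                              strains=element_strains(wmesh, u))
        node_eps = node_strain_tensors(sol, local_nodes, restrict_to=local_cell)
        if not element_strains_too:
            return node_eps
        eps_el = {int(g): sol.strains[g2l_e[int(g)]] for g in cell_elem_ids}
        if not reference_too:
            return node_eps, eps_el
        # reference: same shape and loads, homogeneous medium at the local
        # stiffness, every window face clamped (no gradient, no free surface)
        E_hom = float(np.median(E[cell_elem_ids]))
        li_b = (li == 0) | (li == wnx) | (lj == 0) | (lj == wny) \
            | (lk == 0) | (lk == wnz)
        fixed_ref = (3 * np.flatnonzero(li_b)[:, None] + np.arange(3)).ravel()
        op_ref = _WindowOperator(wmesh, np.full(wmesh.n_elems, E_hom),
                                 self.K_ref, fixed_ref)
        u_ref = op_ref.solve(loads, self.cg_rtol)
        strains_ref = element_strains(wmesh, u_ref)
        eps_ref = {int(g): strains_ref[g2l_e[int(g)]] for g in cell_elem_ids}
        return node_eps, eps_el, eps_ref
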