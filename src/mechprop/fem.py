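"""Minimal plane-stress finite elements on regular quad meshes.

Shared numerical kernel for monolayer stress microscopy (static elastic
sheet) and the active viscoelastic sheet simulation.  Bilinear
quadrilateral elements on an axis-aligned grid, 2×2 Gauss integration,
sparse assembly.  Displacement DOFs are ordered (ux0, uy0, ux1, uy1, …).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

# local node order: BL, BR, TR, TL (counterclockwise)
_XI = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float) / np.sqrt(3)


@dataclass
class QuadMesh:
    """Regular quad mesh over the True cells of an element mask."""

    nodes: np.ndarray        # (n_nodes, 2) physical coords (µm)
    elems: np.ndarray        # (n_elems, 4) node indices, CCW
    spacing: float           # element side (µm)
    elem_mask: np.ndarray    # the (ney, nex) boolean layout
    elem_index: np.ndarray   # (ney, nex) int map into elems, −1 outside

    @classmethod
    def from_element_mask(cls, elem_mask: np.ndarray, spacing: float,
                          origin: tuple[float, float] = (0.0, 0.0)
                          ) -> "QuadMesh":
        elem_mask = np.asarray(elem_mask, bool)
        ney, nex = elem_mask.shape
        if not elem_mask.any():
            raise ValueError("degenerate mask: no elements")
        node_id = -np.ones((ney + 1, nex + 1), dtype=int)
        nodes = []
        elems = []
        elem_index = -np.ones((ney, nex), dtype=int)
        for j in range(ney):
            for i in range(nex):
                if not elem_mask[j, i]:
                    continue
                ids = []
                for dj, di in ((0, 0), (0, 1), (1, 1), (1, 0)):
                    r, c = j + dj, i + di
                    if node_id[r, c] < 0:
                        node_id[r, c] = len(nodes)
                        nodes.append((origin[0] + c * spacing,
                                      origin[1] + r * spacing))
                    ids.append(node_id[r, c])
                elem_index[j, i] = len(elems)
                # ids collected as BL, BR, TR, TL
                elems.append((ids[0], ids[1], ids[2], ids[3]))
        return cls(np.asarray(nodes, float), np.asarray(elems, int),
                   float(spacing), elem_mask, elem_index)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elems(self) -> int:
        return len(self.elems)

    def elem_centers(self) -> np.ndarray:
        return self.nodes[self.elems].mean(axis=1)


def plane_stress_C(E: float, nu: float) -> np.ndarray:
    """Plane-stress constitutive matrix (σ = C ε, Voigt [εxx, εyy, γxy])."""
    return E / (1 - nu**2) * np.array([[1, nu, 0],
                                       [nu, 1, 0],
                                       [0, 0, (1 - nu) / 2]])


def _B_matrix(xi: float, eta: float, h: float) -> np.ndarray:
    """Strain-displacement matrix (3×8) at local coords for side length h."""
    dN = np.empty((4, 2))
    for i, (xin, etan) in enumerate(_XI):
        dN[i, 0] = 0.25 * xin * (1 + etan * eta) * (2.0 / h)
        dN[i, 1] = 0.25 * etan * (1 + xin * xi) * (2.0 / h)
    B = np.zeros((3, 8))
    B[0, 0::2] = dN[:, 0]
    B[1, 1::2] = dN[:, 1]
    B[2, 0::2] = dN[:, 1]
    B[2, 1::2] = dN[:, 0]
    return B


def element_stiffness(C: np.ndarray, h: float) -> np.ndarray:
    """8×8 stiffness of one square element."""
    detJ = (h / 2.0) ** 2
    Ke = np.zeros((8, 8))
    for xi, eta in _GP:
        B = _B_matrix(xi, eta, h)
        Ke += B.T @ C @ B * detJ
    return Ke


def assemble_stiffness(mesh: QuadMesh, C: np.ndarray) -> sp.csr_matrix:
    Ke = element_stiffness(C, mesh.spacing)
    ndof = 2 * mesh.n_nodes
    rows, cols, vals = [], [], []
    for el in mesh.elems:
        dofs = np.column_stack([2 * el, 2 * el + 1]).ravel()
        r, c = np.meshgrid(dofs, dofs, indexing="ij")
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(Ke.ravel())
    return sp.csr_matrix((np.concatenate(vals),
                          (np.concatenate(rows), np.concatenate(cols))),
                         shape=(ndof, ndof))


def lumped_foundation(mesh: QuadMesh) -> sp.csr_matrix:
    """Diagonal matrix of nodal tributary areas (for a spring foundation
    with stiffness density Y the foundation matrix is Y · this)."""
    area = np.zeros(mesh.n_nodes)
    per_node = mesh.spacing**2 / 4.0
    for el in mesh.elems:
        area[el] += per_node
    diag = np.repeat(area, 2)
    return sp.diags(diag).tocsr()


def load_from_body_force(mesh: QuadMesh, bx: np.ndarray, by: np.ndarray
                         ) -> np.ndarray:
    """Consistent load vector for a per-element constant body force
    (force/area)."""
    f = np.zeros(2 * mesh.n_nodes)
    w = mesh.spacing**2 / 4.0
    for e, el in enumerate(mesh.elems):
        f[2 * el] += bx[e] * w
        f[2 * el + 1] += by[e] * w
    return f


def load_from_prestress(mesh: QuadMesh, s_voigt: np.ndarray) -> np.ndarray:
    """Load equivalent to a per-element pre-stress (e.g. active stress):
    f = −∫ Bᵀ σ0 dA, σ0 in Voigt order per element (n_elems, 3)."""
    f = np.zeros(2 * mesh.n_nodes)
    detJ = (mesh.spacing / 2.0) ** 2
    Bs = [_B_matrix(xi, eta, mesh.spacing) for xi, eta in _GP]
    BtSum = sum(B.T for B in Bs) * detJ  # 8×3 (σ0 constant per element)
    for e, el in enumerate(mesh.elems):
        fe = -BtSum @ s_voigt[e]
        dofs = np.column_stack([2 * el, 2 * el + 1]).ravel()
        f[dofs] += fe
    return f


def element_strains(mesh: QuadMesh, u: np.ndarray) -> np.ndarray:
    """Strain (Voigt) at element centres, shape (n_elems, 3)."""
    B0 = _B_matrix(0.0, 0.0, mesh.spacing)
    out = np.empty((mesh.n_elems, 3))
    for e, el in enumerate(mesh.elems):
        dofs = np.column_stack([2 * el, 2 * el + 1]).ravel()
        out[e] = B0 @ u[dofs]
    return out


def rigid_body_constraints(mesh: QuadMesh) -> sp.csr_matrix:
    """3×(2n) constraint rows removing the two translations and the
    rotation about the mesh centroid."""
    n = mesh.n_nodes
    cx, cy = mesh.nodes.mean(axis=0)
    C = np.zeros((3, 2 * n))
    C[0, 0::2] = 1.0
    C[1, 1::2] = 1.0
    C[2, 0::2] = -(mesh.nodes[:, 1] - cy)
    C[2, 1::2] = (mesh.nodes[:, 0] - cx)
    return sp.csr_matrix(C)


def solve_neumann(K: sp.spmatrix, f: np.ndarray, mesh: QuadMesh) -> np.ndarray:
    """Solve the pure-Neumann system K u = f with rigid modes removed via
    Lagrange multipliers (f must be self-equilibrated)."""
    C = rigid_body_constraints(mesh)
    n = K.shape[0]
    A = sp.bmat([[K, C.T], [C, None]], format="csc")
    rhs = np.concatenate([f, np.zeros(3)])
    sol = spla.spsolve(A, rhs)
    return sol[:n]
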