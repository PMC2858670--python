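"""P1 finite elements on a triangle mesh: mass/stiffness assembly and SPD solves.

The Laplace-Beltrami operator on the discrete surface is represented by the
standard linear-element stiffness matrix (equivalent to the cotangent
formula); products of basis functions give the consistent mass matrix, with a
row-sum lumped variant available. These two sparse symmetric operators turn
each semi-implicit time step of the reaction-diffusion system into two SPD
linear solves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh_core import TriangleMesh, GeometryCache, compute_geometry

__all__ = [
    "FEMSystem",
    "assemble_mass",
    "assemble_stiffness",
    "assemble_system",
    "lump_mass",
    "solve_spd",
]


@dataclass
class FEMSystem:
    """Assembled operators for one mesh snapshot.

    ``mass`` is the consistent (or lumped) P1 mass matrix M with
    ``sum(M) = surface area``; ``stiffness`` is the symmetric positive
    semi-definite Laplace-Beltrami stiffness matrix K with ``K @ 1 = 0``.
    ``mass_lumped`` holds the row-sum diagonal of the consistent mass (the
    barycentric vertex areas), used for pointwise reaction coefficients.
    """

    mass: sp.csr_matrix
    stiffness: sp.csr_matrix
    mass_lumped: np.ndarray
    vertex_count: int


def assemble_mass(mesh: TriangleMesh, geometry: GeometryCache) -> sp.csr_matrix:
    """Consistent P1 mass matrix: per-triangle contribution A/6 on the
    diagonal and A/12 off-diagonal (exact integration of products of affine
    hat functions over each flat triangle)."""
    f = mesh.faces
    A = geometry.face_areas
    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(f[:, i])
            cols.append(f[:, j])
            vals.append(A / 6.0 if i == j else A / 12.0)
    M = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return M


def lump_mass(mass: sp.csr_matrix) -> np.ndarray:
    """Row-sum lumping; equals the barycentric vertex areas for P1."""
    return np.asarray(mass.sum(axis=1)).ravel()


def assemble_stiffness(mesh: TriangleMesh, geometry: GeometryCache) -> sp.csr_matrix:
    """P1 stiffness matrix of the Laplace-Beltrami operator.

    The gradient of hat function i on a flat triangle has magnitude 1/h_i
    (h_i the height from vertex i), giving diagonal contributions A/h_i²;
    off-diagonals are the corresponding in-plane gradient dot products,
    computed here as e_i . e_j / (4A) with e_i the edge opposite vertex i —
    algebraically identical to the cotangent formula.
    """
    f = mesh.faces
    A = geometry.face_areas
    e = geometry.edge_vectors  # (m, 3, 3)
    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(f[:, i])
            cols.append(f[:, j])
            vals.append(np.einsum("mk,mk->m", e[:, i], e[:, j]) / (4.0 * A))
    K = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return K


def assemble_system(mesh: TriangleMesh, geometry: GeometryCache | None = None) -> FEMSystem:
    """Assemble mass and stiffness for the current mesh in one call."""
    if geometry is None:
        geometry = compute_geometry(mesh)
    M = assemble_mass(mesh, geometry)
    K = assemble_stiffness(mesh, geometry)
    return FEMSystem(mass=M, stiffness=K, mass_lumped=lump_mass(M), vertex_count=mesh.n_vertices)


def solve_spd(
    A: sp.spmatrix,
    b: np.ndarray,
    tol: float = 1e-10,
    x0: np.ndarray | None = None,
    maxiter: int | None = None,
) -> np.ndarray:
    """Solve A x = b for symmetric positive definite sparse A.

    Conjugate gradients with Jacobi preconditioning and a relative-residual
    contract ||Ax - b|| <= tol * ||b||; deterministic for fixed inputs.

    Raises
    ------
    RuntimeError
        If CG does not reach the tolerance within the iteration cap; the
        message carries the achieved relative residual.
    """
    b = np.asarray(b, dtype=float)
    nrm = np.linalg.norm(b)
    if nrm == 0.0:
        return np.zeros_like(b)
    n = A.shape[0]
    diag = A.diagonal()
    if (diag <= 0).any():
        raise ValueError("system matrix has a non-positive diagonal entry")
    Mpre = spla.LinearOperator((n, n), matvec=lambda r: r / diag)
    if maxiter is None:
        maxiter = max(200, 10 * n)
    x, info = spla.cg(A, b, x0=x0, rtol=tol, atol=0.0, M=Mpre, maxiter=maxiter)
    if info != 0:
        res = np.linalg.norm(A @ x - b) / nrm
        raise RuntimeError(f"CG failed to converge (info={info}, relative residual {res:.3e})")
    return x


def dump_matrix_market(A: sp.spmatrix, path) -> None:
    """Debug export of an assembled operator to Matrix Market format."""
    from scipy.io import mmwrite

    mmwrite(path, sp.coo_matrix(A))
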