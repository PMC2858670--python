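"""Closed triangle meshes: generation, geometry, refinement, smoothing, resampling.

The simulation domain is a closed orientable surface discretized as a triangle
mesh. This module owns the mesh container and every purely geometric
operation: icosphere generation, the per-face/per-vertex geometry cache used
by the finite-element assembly and by the deformation step, the red-green
midpoint refinement that keeps triangle areas bounded as the surface grows,
neighbour-mean smoothing, and barycentric field transfer between meshes that
share a spherical topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = [
    "TriangleMesh",
    "GeometryCache",
    "make_icosphere",
    "compute_geometry",
    "refine_mesh",
    "smooth_mesh",
    "resample_field",
    "vertex_adjacency",
    "read_off",
    "write_off",
    "read_ply",
    "write_ply",
    "read_scalar_map",
    "write_scalar_map",
]


@dataclass
class TriangleMesh:
    """A closed orientable triangulated surface.

    Attributes
    ----------
    vertices : (n, 3) float array
        3-D vertex positions (arbitrary length units).
    faces : (m, 3) int array
        Vertex-index triples with consistent outward winding.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) sorted-index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def validate(self) -> None:
        """Check the closed-2-manifold invariants; raise ValueError on failure."""
        f = self.faces
        if f.min(initial=0) < 0 or f.max(initial=-1) >= self.n_vertices:
            raise ValueError("face indices out of range")
        if (f[:, 0] == f[:, 1]).any() or (f[:, 1] == f[:, 2]).any() or (f[:, 0] == f[:, 2]).any():
            raise ValueError("face with a repeated vertex index")
        # consistent orientation <=> each directed edge appears exactly once,
        # closed <=> each undirected edge appears exactly twice
        de = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        uniq, counts = np.unique(de, axis=0, return_counts=True)
        if (counts != 1).any():
            raise ValueError("inconsistent winding: duplicated directed edge")
        ue = np.sort(uniq, axis=1)
        _, ucounts = np.unique(ue, axis=0, return_counts=True)
        if (ucounts != 2).any():
            raise ValueError("surface is not closed: edge not shared by exactly two faces")
        if self.enclosed_volume() <= 0:
            raise ValueError("winding is inward (negative enclosed volume)")

    def enclosed_volume(self) -> float:
        """Signed volume via the divergence theorem; positive for outward winding."""
        p0 = self.vertices[self.faces[:, 0]]
        p1 = self.vertices[self.faces[:, 1]]
        p2 = self.vertices[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", p0, np.cross(p1, p2)).sum() / 6.0)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())


@dataclass
class GeometryCache:
    """Per-face and per-vertex geometric quantities for one mesh snapshot.

    ``sqrt_g`` is the square root of the determinant of the surface metric of
    the per-triangle affine parameterization; for a flat triangle this is the
    Gram determinant of two edge vectors, i.e. exactly twice the triangle
    area. ``vertex_areas`` are barycentric: one third of each incident face.
    """

    face_areas: np.ndarray        # (m,)
    face_normals: np.ndarray      # (m, 3) unit
    edge_vectors: np.ndarray      # (m, 3, 3): edge opposite vertex i of face
    heights: np.ndarray           # (m, 3): height of face from vertex i
    sqrt_g: np.ndarray            # (m,) = 2 * face_areas
    vertex_normals: np.ndarray    # (n, 3) outward unit
    vertex_areas: np.ndarray      # (n,) barycentric

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())


def compute_geometry(mesh: TriangleMesh) -> GeometryCache:
    """Populate the geometry cache for ``mesh``.

    Raises
    ------
    ValueError
        If a face is degenerate (zero area); the message names the face.
    """
    v, f = mesh.vertices, mesh.faces
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    # edge opposite vertex i (standard FEM convention)
    e0 = p2 - p1
    e1 = p0 - p2
    e2 = p1 - p0
    cross = np.cross(e2, -e1)  # (p1-p0) x (p2-p0)
    double_area = np.linalg.norm(cross, axis=1)
    if (double_area < 1e-300).any():
        bad = int(np.argmin(double_area))
        raise ValueError(f"degenerate (zero-area) face at index {bad}")
    areas = 0.5 * double_area
    normals = cross / double_area[:, None]

    edge_len = np.stack(
        [np.linalg.norm(e0, axis=1), np.linalg.norm(e1, axis=1), np.linalg.norm(e2, axis=1)],
        axis=1,
    )
    heights = double_area[:, None] / edge_len  # h_i = 2A / |opposite edge|

    n = mesh.n_vertices
    vert_normals = np.zeros((n, 3))
    weighted = normals * areas[:, None]
    for i in range(3):
        np.add.at(vert_normals, f[:, i], weighted)
    norms = np.linalg.norm(vert_normals, axis=1)
    if (norms < 1e-300).any():
        raise ValueError("vanishing vertex normal (degenerate neighbourhood)")
    vert_normals /= norms[:, None]

    vert_areas = np.zeros(n)
    third = areas / 3.0
    for i in range(3):
        np.add.at(vert_areas, f[:, i], third)

    return GeometryCache(
        face_areas=areas,
        face_normals=normals,
        edge_vectors=np.stack([e0, e1, e2], axis=1),
        heights=heights,
        sqrt_g=2.0 * areas,
        vertex_normals=vert_normals,
        vertex_areas=vert_areas,
    )


# ---------------------------------------------------------------------------
# icosphere

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=float,
)

_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def make_icosphere(subdivisions: int = 4, radius: float = 1.0) -> TriangleMesh:
    """Geodesic icosphere: an icosahedron subdivided ``subdivisions`` times.

    Each subdivision splits every face into 4 at the edge midpoints, then all
    vertices are projected back to the sphere of the given radius, so the
    vertex count is ``10 * 4**subdivisions + 2``. The icosahedral construction
    avoids the polar mesh artifacts of latitude-longitude spheres.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be positive")
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS[0])
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        verts, faces = _subdivide_all(verts, faces)
        verts /= np.linalg.norm(verts, axis=1)[:, None]
    return TriangleMesh(verts * radius, faces)


def _subdivide_all(verts: np.ndarray, faces: np.ndarray):
    """Uniform 1-to-4 midpoint subdivision of every face."""
    midpoint: dict[tuple[int, int], int] = {}
    new_verts = [verts]
    next_idx = len(verts)

    def mid(a: int, b: int) -> int:
        nonlocal next_idx
        key = (a, b) if a < b else (b, a)
        if key not in midpoint:
            midpoint[key] = next_idx
            new_verts.append(0.5 * (verts[a] + verts[b]))
            next_idx += 1
        return midpoint[key]

    new_faces = np.empty((4 * len(faces), 3), dtype=np.int64)
    for t, (a, b, c) in enumerate(faces):
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces[4 * t: 4 * t + 4] = [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
    stacked = np.vstack([new_verts[0]] + [np.atleast_2d(x) for x in new_verts[1:]])
    return stacked, new_faces


# ---------------------------------------------------------------------------
# adaptive refinement

def refine_mesh(
    mesh: TriangleMesh,
    fields: Sequence[np.ndarray],
    reference_area: float,
    threshold_factor: float = 2.0,
) -> tuple[TriangleMesh, list[np.ndarray]]:
    """Red-green midpoint refinement of over-grown faces.

    Every face whose area exceeds ``threshold_factor * reference_area``
    (``reference_area`` is the mean face area of the *initial* mesh) is split
    into 4 triangles on its edge midpoints; a neighbour sharing one split edge
    is bisected across the inserted midpoint, a neighbour sharing two split
    edges is cut into three, and a neighbour with all three edges split gets
    the full 4-way subdivision. Midpoint subdivision is planar per face, so
    total area is preserved exactly and the mesh stays a closed 2-manifold.

    Per-vertex ``fields`` are extended to the inserted midpoints by averaging
    the two edge endpoints (linear interpolation, consistent with P1
    elements). Returns the (possibly identical) mesh and the extended fields.
    """
    for arr in fields:
        if len(arr) != mesh.n_vertices:
            raise ValueError("field length does not match vertex count")
    geom = compute_geometry(mesh)
    marked = geom.face_areas > threshold_factor * reference_area
    if not marked.any():
        return mesh, [np.asarray(a, dtype=float) for a in fields]

    f = mesh.faces
    midpoint: dict[tuple[int, int], int] = {}
    new_positions: list[np.ndarray] = []
    new_field_vals: list[list[float]] = [[] for _ in fields]
    next_idx = mesh.n_vertices

    def edge_key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    def mid(a: int, b: int) -> int:
        nonlocal next_idx
        key = edge_key(a, b)
        if key not in midpoint:
            midpoint[key] = next_idx
            new_positions.append(0.5 * (mesh.vertices[a] + mesh.vertices[b]))
            for j, arr in enumerate(fields):
                new_field_vals[j].append(0.5 * (arr[a] + arr[b]))
            next_idx += 1
        return midpoint[key]

    # red pass: register midpoints on every edge of every marked face
    for t in np.flatnonzero(marked):
        a, b, c = f[t]
        mid(a, b), mid(b, c), mid(c, a)

    out_faces: list[tuple[int, int, int]] = []
    for t in range(mesh.n_faces):
        a, b, c = (int(x) for x in f[t])
        split = [edge_key(a, b) in midpoint, edge_key(b, c) in midpoint, edge_key(c, a) in midpoint]
        ns = sum(split)
        if marked[t] or ns == 3:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            out_faces += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
        elif ns == 0:
            out_faces.append((a, b, c))
        else:
            # rotate so the first edge (a,b) is split
            while not split[0]:
                a, b, c = b, c, a
                split = split[1:] + split[:1]
            if ns == 1:
                m = midpoint[edge_key(a, b)]
                out_faces += [(a, m, c), (m, b, c)]
            else:
                # make the two split edges (a,b) and (b,c); pattern is either
                # [T,T,F] (done) or [T,F,T], fixed by two cyclic rotations
                if not split[1]:
                    a, b, c = c, a, b
                m1 = midpoint[edge_key(a, b)]
                m2 = midpoint[edge_key(b, c)]
                out_faces += [(m1, b, m2), (a, m1, m2), (a, m2, c)]

    new_verts = np.vstack([mesh.vertices] + [p[None, :] for p in new_positions])
    out = TriangleMesh(new_verts, np.array(out_faces, dtype=np.int64))
    out_fields = [
        np.concatenate([np.asarray(arr, dtype=float), np.array(vals, dtype=float)])
        for arr, vals in zip(fields, new_field_vals)
    ]
    return out, out_fields


# ---------------------------------------------------------------------------
# smoothing and resampling

def vertex_adjacency(mesh: TriangleMesh) -> sp.csr_matrix:
    """Symmetric 0/1 vertex adjacency matrix from mesh edges."""
    e = mesh.edges()
    n = mesh.n_vertices
    data = np.ones(2 * len(e))
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def smooth_mesh(mesh: TriangleMesh, iterations: int) -> TriangleMesh:
    """Neighbour-mean smoothing: each iteration simultaneously replaces every
    vertex by the arithmetic mean of its 1-ring neighbours. Connectivity is
    unchanged; the surface shrinks (the map is averaging, hence contractive).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    adj = vertex_adjacency(mesh)
    inv_deg = 1.0 / np.asarray(adj.sum(axis=1)).ravel()
    v = mesh.vertices
    for _ in range(iterations):
        v = (adj @ v) * inv_deg[:, None]
    return TriangleMesh(v, mesh.faces.copy())


def _project_unit(mesh: TriangleMesh) -> np.ndarray:
    """Centre at the centroid and radially project vertices to the unit sphere."""
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    r = np.linalg.norm(v, axis=1)
    if (r < 1e-300).any():
        raise ValueError("vertex at centroid; cannot project to sphere")
    return v / r[:, None]


def resample_field(
    source_mesh: TriangleMesh,
    field: np.ndarray,
    target_mesh: TriangleMesh,
    smoothing_iterations: int = 100,
) -> np.ndarray:
    """Transfer a per-vertex field between meshes sharing spherical topology.

    Both meshes are neighbour-mean smoothed (which recovers a near-sphere for
    the star-shaped deformations produced by the simulator), centred, and
    radially projected onto the unit sphere; each target direction is then
    assigned the barycentric interpolation of the field on the source face its
    ray pierces. Smoothing before projection avoids fold-over ambiguities of
    the radial map on heavily folded meshes.
    """
    field = np.asarray(field, dtype=float)
    if len(field) != source_mesh.n_vertices:
        raise ValueError("field length does not match source vertex count")
    if source_mesh.n_faces == 0:
        raise ValueError("empty source mesh")
    if smoothing_iterations > 0:
        src = _project_unit(smooth_mesh(source_mesh, smoothing_iterations))
        tgt = _project_unit(smooth_mesh(target_mesh, smoothing_iterations))
    else:
        src = _project_unit(source_mesh)
        tgt = _project_unit(target_mesh)

    faces = source_mesh.faces
    # faces incident to each source vertex
    incident: list[list[int]] = [[] for _ in range(source_mesh.n_vertices)]
    for t, (a, b, c) in enumerate(faces):
        incident[a].append(t)
        incident[b].append(t)
        incident[c].append(t)

    tree = cKDTree(src)
    out = np.empty(target_mesh.n_vertices)
    _, nearest = tree.query(tgt, k=1)
    k_fallback = min(8, source_mesh.n_vertices)
    for i, (d, nn) in enumerate(zip(tgt, nearest)):
        cand = incident[nn]
        w, t_best = _best_face(src, faces, cand, d)
        if w is None or w.min() < -1e-6:
            # rare: ray falls outside the nearest vertex's star; widen search
            _, nns = tree.query(d, k=k_fallback)
            cand = sorted({t for v in np.atleast_1d(nns) for t in incident[v]})
            w2, t2 = _best_face(src, faces, cand, d)
            if w2 is not None and (w is None or w2.min() > w.min()):
                w, t_best = w2, t2
        if w is None:
            raise ValueError("closest-face search failed")
        w = np.clip(w, 0.0, None)
        w /= w.sum()
        out[i] = w @ field[faces[t_best]]
    return out


def _best_face(src: np.ndarray, faces: np.ndarray, candidates, direction: np.ndarray):
    """Barycentric weights of the central projection of ``direction`` onto each
    candidate face; returns the weights and face index with the largest minimum
    weight (least outside)."""
    best_w, best_t, best_min = None, -1, -np.inf
    for t in candidates:
        tri = src[faces[t]]  # (3, 3) rows = corners
        try:
            w = np.linalg.solve(tri.T, direction)
        except np.linalg.LinAlgError:
            continue
        s = w.sum()
        if abs(s) < 1e-12:
            continue
        w = w / s
        if w.min() > best_min:
            best_w, best_t, best_min = w, t, w.min()
    return best_w, best_t


# ---------------------------------------------------------------------------
# I/O: ASCII OFF / PLY and per-vertex scalar text maps

def write_off(mesh: TriangleMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        for a, b, c in mesh.faces:
            fh.write(f"3 {a} {b} {c}\n")


def read_off(path) -> TriangleMesh:
    with open(path) as fh:
        tokens = [t for line in fh for t in line.split("#", 1)[0].split()]
    if not tokens or tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    verts = np.array(tokens[pos: pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    faces = np.empty((nf, 3), dtype=np.int64)
    for i in range(nf):
        cnt = int(tokens[pos])
        if cnt != 3:
            raise ValueError("only triangle faces are supported")
        faces[i] = [int(tokens[pos + 1]), int(tokens[pos + 2]), int(tokens[pos + 3])]
        pos += 1 + cnt
    return TriangleMesh(verts, faces)


def write_ply(mesh: TriangleMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {mesh.n_vertices}\n"
            "property float x\nproperty float y\nproperty float z\n"
            f"element face {mesh.n_faces}\n"
            "property list uchar int vertex_indices\nend_header\n"
        )
        for p in mesh.vertices:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        for a, b, c in mesh.faces:
            fh.write(f"3 {a} {b} {c}\n")


def read_ply(path) -> TriangleMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError("not a PLY file")
    nv = nf = 0
    i = 1
    while i < len(lines):
        parts = lines[i].split()
        if parts[:1] == ["format"] and parts[1] != "ascii":
            raise ValueError("only ASCII PLY is supported")
        if parts[:2] == ["element", "vertex"]:
            nv = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            nf = int(parts[2])
        elif parts[:1] == ["end_header"]:
            i += 1
            break
        i += 1
    verts = np.array([lines[i + j].split()[:3] for j in range(nv)], dtype=float)
    faces = np.empty((nf, 3), dtype=np.int64)
    for j in range(nf):
        parts = lines[i + nv + j].split()
        if int(parts[0]) != 3:
            raise ValueError("only triangle faces are supported")
        faces[j] = [int(parts[1]), int(parts[2]), int(parts[3])]
    return TriangleMesh(verts, faces)


def write_scalar_map(values: np.ndarray, path) -> None:
    """One value per line, ordered by vertex index."""
    np.savetxt(path, np.asarray(values, dtype=float), fmt="%.17g")


def read_scalar_map(path) -> np.ndarray:
    return np.loadtxt(path, dtype=float, ndmin=1)
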