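"""Mesh generation, geometry, refinement, smoothing, resampling and I/O."""

import numpy as np
import pytest

from turingfold import (
    TriangleMesh,
    make_icosphere,
    compute_geometry,
    refine_mesh,
    smooth_mesh,
    resample_field,
)
from turingfold.mesh_core import (
    read_off,
    write_off,
    read_ply,
    write_ply,
    read_scalar_map,
    write_scalar_map,
)


# ---------------------------------------------------------------------------
# icosphere and geometry


@pytest.mark.parametrize(
    "sub, nv, nf",
    [(0, 12, 20), (1, 42, 80), (3, 642, 1280), (4, 2562, 5120)],
)
def test_icosphere_counts(sub, nv, nf):
    m = make_icosphere(sub)
    assert (m.n_vertices, m.n_faces) == (nv, nf)
    m.validate()
    assert np.allclose(np.linalg.norm(m.vertices, axis=1), 1.0, atol=1e-12)


def test_icosphere_radius_and_area(geom4):
    # summed face areas converge to the analytic sphere area 4*pi
    assert abs(geom4.total_area - 4 * np.pi) / (4 * np.pi) < 0.01


def test_icosphere_rejects_bad_args():
    with pytest.raises(ValueError):
        make_icosphere(-1)
    with pytest.raises(ValueError):
        make_icosphere(2, radius=0.0)


def test_geometry_equilateral_triangle_heights():
    # closed tetrahedron made of equilateral side-1 triangles
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(2) / 2  # edge length 1
    f = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
    mesh = TriangleMesh(v, f)
    mesh.validate()
    g = compute_geometry(mesh)
    assert np.allclose(g.heights, np.sqrt(3) / 2, atol=1e-12)
    assert np.allclose(g.face_areas, np.sqrt(3) / 4, atol=1e-12)


def test_geometry_sqrt_g_is_twice_area_and_area_partition(geom3):
    assert np.allclose(geom3.sqrt_g, 2 * geom3.face_areas, rtol=1e-14)
    assert abs(geom3.vertex_areas.sum() - geom3.total_area) < 1e-12 * geom3.total_area
    assert np.allclose(np.linalg.norm(geom3.vertex_normals, axis=1), 1.0, atol=1e-12)


def test_geometry_sphere_normals_radial(icosphere4, geom4):
    radial = icosphere4.vertices / np.linalg.norm(icosphere4.vertices, axis=1)[:, None]
    cosang = np.einsum("ij,ij->i", radial, geom4.vertex_normals)
    assert np.degrees(np.arccos(np.clip(cosang, -1, 1))).max() < 1.0


def test_geometry_degenerate_face_raises():
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
    f = np.array([[0, 1, 3], [1, 2, 3], [0, 3, 2], [0, 2, 1]])
    with pytest.raises(ValueError, match="degenerate"):
        compute_geometry(TriangleMesh(v, f))


def test_validate_rejects_open_and_misoriented_meshes():
    m = make_icosphere(1)
    open_mesh = TriangleMesh(m.vertices, m.faces[:-1])
    with pytest.raises(ValueError):
        open_mesh.validate()
    flipped = m.faces.copy()
    flipped[0] = flipped[0, ::-1]
    with pytest.raises(ValueError):
        TriangleMesh(m.vertices, flipped).validate()


# ---------------------------------------------------------------------------
# refinement


def _one_big_face_fixture():
    """Icosahedron with face 0 enlarged so only it exceeds twice the reference."""
    m = make_icosphere(0)
    v = m.vertices.copy()
    v[m.faces[0]] *= 1.8
    mesh = TriangleMesh(v, m.faces)
    areas = compute_geometry(mesh).face_areas
    order = np.argsort(areas)[::-1]
    assert order[0] == 0
    second = areas[order[1]]
    reference = (areas[0] + second) / 4.0  # 2*ref strictly between the two
    return mesh, reference


def test_refine_isolated_face_counts():
    # one 4-way split plus three neighbour bisections: 20 -> 26 faces
    mesh, ref = _one_big_face_fixture()
    out, _ = refine_mesh(mesh, [], ref, threshold_factor=2.0)
    assert out.n_faces == 26
    assert out.n_vertices == mesh.n_vertices + 3
    out.validate()
    assert out.euler_characteristic() == 2


def test_refine_noop_below_threshold(icosphere3):
    ref = compute_geometry(icosphere3).face_areas.mean()
    out, fields = refine_mesh(icosphere3, [np.ones(icosphere3.n_vertices)], ref, 2.0)
    assert out is icosphere3
    assert np.array_equal(fields[0], np.ones(icosphere3.n_vertices))


def test_refine_preserves_area_and_interpolates_fields(rng):
    mesh, ref = _one_big_face_fixture()
    field = rng.normal(size=mesh.n_vertices)
    a0 = compute_geometry(mesh).total_area
    out, (f2,) = refine_mesh(mesh, [field], ref, 2.0)
    assert abs(compute_geometry(out).total_area - a0) < 1e-12 * a0
    # midpoints got the mean of their edge endpoints
    a, b, c = mesh.faces[0]
    mids = out.vertices[mesh.n_vertices:]
    for x, y in [(a, b), (b, c), (c, a)]:
        expect_pos = 0.5 * (mesh.vertices[x] + mesh.vertices[y])
        j = int(np.argmin(np.linalg.norm(mids - expect_pos, axis=1)))
        assert np.allclose(mids[j], expect_pos)
        assert np.isclose(f2[mesh.n_vertices + j], 0.5 * (field[x] + field[y]))
    # linear field stays linear under midpoint interpolation
    lin = mesh.vertices[:, 0] + 2 * mesh.vertices[:, 1]
    _, (lin2,) = refine_mesh(mesh, [lin], ref, 2.0)
    assert np.allclose(lin2, out.vertices[:, 0] + 2 * out.vertices[:, 1])


def test_refine_adjacent_marked_faces_stay_manifold(rng):
    # grow the whole mesh so every face is refined (all-marked limit)
    m = make_icosphere(1)
    ref = compute_geometry(m).face_areas.mean() / 10.0
    out, _ = refine_mesh(m, [], ref, 2.0)
    out.validate()
    assert out.n_faces == 4 * m.n_faces
    assert out.euler_characteristic() == 2


def test_refine_mixed_patterns_manifold(rng):
    # random radial bumps mark an irregular subset of faces, exercising the
    # 1-, 2- and 3-split neighbour cases together
    m = make_icosphere(2)
    bump = 1.0 + 0.5 * (rng.random(m.n_vertices) > 0.7)
    mesh = TriangleMesh(m.vertices * bump[:, None], m.faces)
    ref = compute_geometry(make_icosphere(2)).face_areas.mean()
    a0 = compute_geometry(mesh).total_area
    out, _ = refine_mesh(mesh, [], ref, 2.0)
    out.validate()
    assert out.euler_characteristic() == 2
    assert abs(compute_geometry(out).total_area - a0) < 1e-10 * a0


# ---------------------------------------------------------------------------
# smoothing


def test_smooth_icosphere_shrinks_radially():
    m = make_icosphere(1)
    s = smooth_mesh(m, 1)
    r = np.linalg.norm(s.vertices, axis=1)
    # two vertex orbits at subdivision 1: the 12 originals and 30 midpoints
    assert r.max() < 1.0
    assert np.ptp(r[:12]) < 1e-9
    assert np.ptp(r[12:]) < 1e-9
    # moves are radial: smoothed position parallel to the original
    cross = np.cross(s.vertices, m.vertices)
    assert np.abs(cross).max() < 1e-9


def test_smooth_rejects_zero_iterations(icosphere3):
    with pytest.raises(ValueError):
        smooth_mesh(icosphere3, 0)


def test_smooth_composition(icosphere3):
    once_twice = smooth_mesh(smooth_mesh(icosphere3, 1), 1)
    twice = smooth_mesh(icosphere3, 2)
    assert np.allclose(once_twice.vertices, twice.vertices, atol=1e-14)


def test_smooth_decreases_area_of_folded_mesh():
    m = make_icosphere(3)
    r = 1.0 + 0.3 * np.sin(5 * m.vertices[:, 2]) * np.cos(4 * np.arctan2(m.vertices[:, 1], m.vertices[:, 0]))
    folded = TriangleMesh(m.vertices * r[:, None], m.faces)
    areas = [compute_geometry(folded).total_area]
    cur = folded
    for _ in range(100):
        cur = smooth_mesh(cur, 1)
        areas.append(compute_geometry(cur).total_area)
    assert all(a1 < a0 for a0, a1 in zip(areas, areas[1:]))


# ---------------------------------------------------------------------------
# resampling


def test_resample_constant_field(icosphere3, icosphere4):
    out = resample_field(icosphere4, np.full(icosphere4.n_vertices, 3.5), icosphere3,
                         smoothing_iterations=10)
    assert np.allclose(out, 3.5, atol=1e-12)


def test_resample_identity(icosphere3):
    field = icosphere3.vertices[:, 2]
    out = resample_field(icosphere3, field, icosphere3, smoothing_iterations=0)
    assert np.allclose(out, field, atol=1e-12)


@pytest.mark.parametrize("smoothing", [0, 100])
def test_resample_linear_field_fine_to_coarse(icosphere3, icosphere4, smoothing):
    field = icosphere4.vertices[:, 2]
    out = resample_field(icosphere4, field, icosphere3, smoothing_iterations=smoothing)
    assert np.abs(out - icosphere3.vertices[:, 2]).max() < 0.01


# ---------------------------------------------------------------------------
# I/O


def test_off_ply_roundtrip(tmp_path, icosphere3):
    for writer, reader, name in [
        (write_off, read_off, "m.off"),
        (write_ply, read_ply, "m.ply"),
    ]:
        p = tmp_path / name
        writer(icosphere3, p)
        back = reader(p)
        assert np.allclose(back.vertices, icosphere3.vertices)
        assert np.array_equal(back.faces, icosphere3.faces)


def test_scalar_map_roundtrip(tmp_path, rng):
    vals = rng.normal(size=100)
    p = tmp_path / "map.txt"
    write_scalar_map(vals, p)
    assert np.allclose(read_scalar_map(p), vals)
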