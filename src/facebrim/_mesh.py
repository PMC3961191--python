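"""Low-level triangle-mesh geometry shared by the mask and FSCP modules.

Conventions (fixed for bit-reproducibility):
  * per-vertex area = one-third of the summed areas of incident triangles
    (barycentric lumping), so vertex areas partition the total mesh area;
  * vertex normal = angle-weighted average of incident face normals;
  * discrete mean curvature = half the norm of the cotangent
    Laplace-Beltrami applied to the coordinates, signed by agreement with
    the outward vertex normal.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "grid_triangles",
    "triangle_areas",
    "vertex_areas",
    "vertex_normals",
    "mean_curvature",
    "boundary_vertices",
]


def grid_triangles(rows: int, cols: int) -> np.ndarray:
    """Triangulate a rows x cols vertex grid with consistent orientation.

    Vertex (r, j) has index r*cols + j.  Each grid quad is split along one
    diagonal; triangles are counter-clockwise when viewed from +z for a grid
    with x increasing along columns and y increasing along rows.
    """
    r, j = np.meshgrid(np.arange(rows - 1), np.arange(cols - 1), indexing="ij")
    v00 = (r * cols + j).ravel()
    v01 = v00 + 1
    v10 = v00 + cols
    v11 = v10 + 1
    upper = np.stack([v00, v01, v11], axis=1)
    lower = np.stack([v00, v11, v10], axis=1)
    return np.concatenate([upper, lower], axis=0).astype(np.int64)


def _face_cross(coords: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p0 = coords[triangles[:, 0]]
    p1 = coords[triangles[:, 1]]
    p2 = coords[triangles[:, 2]]
    return np.cross(p1 - p0, p2 - p0)


def triangle_areas(coords: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(_face_cross(coords, triangles), axis=1)


def vertex_areas(coords: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Barycentric (one-third) vertex areas; sums exactly to total area."""
    fa = triangle_areas(coords, triangles)
    va = np.zeros(len(coords))
    for c in range(3):
        np.add.at(va, triangles[:, c], fa / 3.0)
    return va


def _corner_angles(coords: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Interior angle at each triangle corner, shape (n_tri, 3)."""
    p = coords[triangles]  # (m, 3, 3)
    angles = np.empty(triangles.shape)
    for c in range(3):
        a = p[:, (c + 1) % 3] - p[:, c]
        b = p[:, (c + 2) % 3] - p[:, c]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosang = np.einsum("ij,ij->i", a, b) / np.maximum(na * nb, 1e-300)
        angles[:, c] = np.arccos(np.clip(cosang, -1.0, 1.0))
    return angles


def vertex_normals(coords: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Angle-weighted unit vertex normals (orientation from triangle winding)."""
    cross = _face_cross(coords, triangles)
    nrm = np.linalg.norm(cross, axis=1)
    fn = cross / np.maximum(nrm, 1e-300)[:, None]
    ang = _corner_angles(coords, triangles)
    vn = np.zeros_like(coords)
    for c in range(3):
        np.add.at(vn, triangles[:, c], ang[:, c][:, None] * fn)
    length = np.linalg.norm(vn, axis=1)
    return vn / np.maximum(length, 1e-300)[:, None]


def boundary_vertices(n_vertices: int, triangles: np.ndarray) -> np.ndarray:
    """Indices of vertices incident to an edge used by only one triangle."""
    edges = np.concatenate(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    border_edges = uniq[counts == 1]
    return np.unique(border_edges.ravel())


def mean_curvature(
    coords: np.ndarray, triangles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Signed discrete mean curvature per vertex (1/length units).

    Returns (curvature, boundary_flag).  Positive where the surface is
    convex toward the outward normal.  Boundary values are computed but the
    cotangent stencil is incomplete there, so they are flagged unreliable.
    """
    n = len(coords)
    ang = _corner_angles(coords, triangles)
    cot = 1.0 / np.tan(np.clip(ang, 1e-9, np.pi - 1e-9))

    lap = np.zeros_like(coords)
    # edge opposite corner c connects the other two corners; the cotangent at
    # corner c weights that edge
    for c in range(3):
        i = triangles[:, (c + 1) % 3]
        j = triangles[:, (c + 2) % 3]
        w = 0.5 * cot[:, c][:, None]
        diff = coords[i] - coords[j]
        np.add.at(lap, i, w * diff)
        np.add.at(lap, j, -w * diff)

    va = vertex_areas(coords, triangles)
    # lap = (1/2) sum (cot a + cot b)(x_i - x_j); Meyer's mean-curvature
    # normal is lap / A with |.| = 2H, so H = |lap| / (2 A) = |k_vec|
    k_vec = lap / (2.0 * np.maximum(va, 1e-300)[:, None])
    h = np.linalg.norm(k_vec, axis=1)
    vn = vertex_normals(coords, triangles)
    sign = np.sign(np.einsum("ij,ij->i", k_vec, vn))
    sign[sign == 0] = 1.0
    curvature = sign * h

    boundary = np.zeros(n, dtype=bool)
    boundary[boundary_vertices(n, triangles)] = True
    return curvature, boundary
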