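"""Face shape change parameters (FSCPs).

Quantitative comparisons of two corresponded surfaces — typically the -k SD
and +k SD shape transformations of an effect — as per-landmark maps (area
ratio, curvature difference or ratio, signed normal displacement) plus
global scalars (inter-landmark distances and angles, facial squareness,
a head-circumference proxy), with empirical significance by permutation of
the effect variable across individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._mesh import mean_curvature, triangle_areas, vertex_areas, vertex_normals
from .mask import AnthropometricMask

__all__ = [
    "FSCPMaps",
    "local_area_map",
    "area_ratio",
    "mean_curvature_map",
    "curvature_compare",
    "normal_displacement",
    "compare_surfaces",
    "permutation_significance",
    "facial_squareness",
    "circumference_proxy",
    "interlandmark_fscp",
]


def _check(config: np.ndarray, mask: AnthropometricMask) -> np.ndarray:
    c = np.asarray(config, dtype=float)
    if c.shape != (mask.n_landmarks, 3):
        raise ValueError(
            f"configuration shape {c.shape} does not conform to mask "
            f"({mask.n_landmarks} landmarks)"
        )
    return c


@dataclass
class FSCPMaps:
    """Per-landmark comparison of two corresponded surfaces a -> b."""

    area_ratio: np.ndarray
    curvature_difference: np.ndarray
    curvature_ratio: np.ndarray
    normal_displacement: np.ndarray
    boundary: np.ndarray  # curvature unreliable on the open boundary
    r2: np.ndarray | None = None
    p_values: np.ndarray | None = None
    significant_mask: np.ndarray | None = None
    alpha: float | None = None


def local_area_map(config: np.ndarray, mask: AnthropometricMask) -> np.ndarray:
    """Per-landmark surface area: one third of incident triangle areas (mm^2).

    The landmark areas partition the mesh: they sum exactly to the total
    surface area.
    """
    c = _check(config, mask)
    fa = triangle_areas(c, mask.triangles)
    if np.any(fa <= 0):
        warnings.warn(
            f"{int((fa <= 0).sum())} degenerate (zero-area) triangles", stacklevel=2
        )
    return vertex_areas(c, mask.triangles)


def area_ratio(
    config_a: np.ndarray, config_b: np.ndarray, mask: AnthropometricMask
) -> np.ndarray:
    """Elementwise local area of b over local area of a (dimensionless)."""
    a = local_area_map(config_a, mask)
    b = local_area_map(config_b, mask)
    out = np.full(len(a), np.nan)
    ok = a > 0
    if not ok.all():
        warnings.warn("zero local area in reference surface; ratio undefined there",
                      stacklevel=2)
    out[ok] = b[ok] / a[ok]
    return out


def mean_curvature_map(config: np.ndarray, mask: AnthropometricMask):
    """Signed discrete mean curvature per landmark (1/mm).

    Cotangent Laplace-Beltrami estimate signed by agreement with the outward
    vertex normal: convex-outward regions positive.  Returns (curvature,
    boundary_flag); boundary values are computed but unreliable.
    """
    c = _check(config, mask)
    return mean_curvature(c, mask.triangles)


def curvature_compare(
    config_a: np.ndarray,
    config_b: np.ndarray,
    mask: AnthropometricMask,
    mode: str = "difference",
    eps: float = 1e-6,
):
    """Per-landmark curvature difference (b - a) or ratio (b / a).

    In ratio mode landmarks where |curvature of a| < eps are NaN-flagged.
    """
    ka, _ = mean_curvature_map(config_a, mask)
    kb, boundary = mean_curvature_map(config_b, mask)
    if mode == "difference":
        return kb - ka, boundary
    if mode == "ratio":
        out = np.full(len(ka), np.nan)
        ok = np.abs(ka) >= eps
        out[ok] = kb[ok] / ka[ok]
        return out, boundary
    raise ValueError("mode must be 'difference' or 'ratio'")


def normal_displacement(
    config_a: np.ndarray, config_b: np.ndarray, mask: AnthropometricMask
) -> np.ndarray:
    """Signed displacement of each landmark along a's outward normal (mm).

    (b_i - a_i) . n_i with n_i the angle-weighted unit vertex normal of
    config_a; positive means outward motion.
    """
    a = _check(config_a, mask)
    b = _check(config_b, mask)
    n = vertex_normals(a, mask.triangles)
    return np.einsum("ij,ij->i", b - a, n)


def compare_surfaces(
    config_a: np.ndarray, config_b: np.ndarray, mask: AnthropometricMask
) -> FSCPMaps:
    """All per-landmark FSCP maps for the ordered pair (a, b)."""
    diff, boundary = curvature_compare(config_a, config_b, mask, "difference")
    ratio, _ = curvature_compare(config_a, config_b, mask, "ratio")
    return FSCPMaps(
        area_ratio=area_ratio(config_a, config_b, mask),
        curvature_difference=diff,
        curvature_ratio=ratio,
        normal_displacement=normal_displacement(config_a, config_b, mask),
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# permutation significance


def permutation_significance(
    rip: np.ndarray,
    shapes: np.ndarray,
    statistic=None,
    B: int = 999,
    alpha: float = 0.001,
    seed: int = 0,
):
    """Empirical p-values for per-landmark statistics by permuting the RIP.

    ``statistic(rip_values) -> per-landmark array`` is recomputed for B
    permutations of the RIP across individuals; one-sided p on the
    statistic's magnitude, p = (1 + #{perm >= observed}) / (B + 1).  The
    default statistic is the per-landmark pooled-coordinate R^2 of the
    shapes on the RIP (computed vectorized).  Returns (p_values, mask).
    """
    rip = np.asarray(rip, dtype=float)
    if B < 99:
        raise ValueError("B must be at least 99")
    if alpha < 1.0 / (B + 1):
        raise ValueError(
            f"alpha={alpha} unreachable with B={B} (min achievable p is 1/(B+1))"
        )
    rng = np.random.default_rng(seed)

    if statistic is None:
        S = np.asarray(shapes, dtype=float)
        if len(S) != len(rip):
            raise ValueError("rip not row-matched to shapes")
        kland = S.shape[1] // 3
        Sc = S - S.mean(axis=0)
        tot_l = (Sc**2).sum(axis=0).reshape(kland, 3).sum(axis=1)

        def r2_stat(perm_matrix):
            # perm_matrix: (B+1, n) centered rip rows; vectorized R^2
            X = perm_matrix - perm_matrix.mean(axis=1, keepdims=True)
            sxx = np.einsum("bn,bn->b", X, X)
            cross = X @ Sc  # (B+1, 3k)
            reg = cross**2 / sxx[:, None]
            reg_l = reg.reshape(len(X), kland, 3).sum(axis=2)
            return reg_l / np.maximum(tot_l, 1e-300)

        all_rows = np.empty((B + 1, len(rip)))
        all_rows[0] = rip
        for b in range(B):
            all_rows[b + 1] = rng.permutation(rip)
        stats = r2_stat(all_rows)
        observed, perms = np.abs(stats[0]), np.abs(stats[1:])
    else:
        observed = np.abs(np.asarray(statistic(rip), dtype=float))
        perms = np.empty((B, np.size(observed)))
        for b in range(B):
            perms[b] = np.abs(np.asarray(statistic(rng.permutation(rip)), float))

    p = (1.0 + (perms >= observed[None, :]).sum(axis=0)) / (B + 1.0)
    return p, p < alpha


# ---------------------------------------------------------------------------
# global FSCPs


def _square_rms(params, pts):
    cx, cy, theta, half = params
    c, s = np.cos(theta), np.sin(theta)
    u = c * (pts[:, 0] - cx) + s * (pts[:, 1] - cy)
    v = -s * (pts[:, 0] - cx) + c * (pts[:, 1] - cy)
    qx = np.abs(u) - abs(half)
    qy = np.abs(v) - abs(half)
    outside = np.hypot(np.maximum(qx, 0.0), np.maximum(qy, 0.0))
    inside = np.minimum(np.maximum(qx, qy), 0.0)
    d = outside - inside  # unsigned distance to the square boundary
    return float(np.sqrt(np.mean(d**2)))


def facial_squareness(
    config: np.ndarray, mask: AnthropometricMask
) -> float:
    """Dissimilarity of the facial border from its best-fitting square.

    The border landmarks are projected onto the XY plane and a square
    (center, side, in-plane rotation) is fit by least squares; the score is
    the RMS point-to-square distance in mm.  Lower = more square.
    Invariant to in-plane rotation and translation.
    """
    if len(mask.border) < 8:
        raise ValueError("mask designates fewer than 8 border landmarks")
    c = _check(config, mask)
    pts = c[mask.border][:, :2]
    ctr = pts.mean(axis=0)
    spread = np.mean(np.abs(pts - ctr))
    best = np.inf
    for theta0 in (0.0, np.pi / 6, np.pi / 3):
        res = minimize(
            _square_rms,
            x0=[ctr[0], ctr[1], theta0, spread],
            args=(pts,),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
        )
        best = min(best, res.fun)
    return float(best)


def _fit_circle_2d(pts: np.ndarray):
    """Algebraic least-squares circle fit; returns (center, radius)."""
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c0 = sol
    r = np.sqrt(c0 + cx**2 + cy**2)
    return np.array([cx, cy]), float(r)


def circumference_proxy(config: np.ndarray, mask: AnthropometricMask) -> float:
    """Radius (mm) of a circle fit to the forehead cross-section.

    The mesh is intersected with the plane halfway between the glabella and
    top-of-forehead landmarks, oriented along their connecting direction,
    and a circle is fit to the intersection curve by least squares.  The
    radius is a head-circumference proxy.
    """
    for name in ("glabella", "forehead_top"):
        if name not in mask.landmark_names:
            raise ValueError(f"mask does not designate a {name!r} landmark")
    c = _check(config, mask)
    g = c[mask.landmark_names["glabella"]]
    t = c[mask.landmark_names["forehead_top"]]
    normal = t - g
    nn = np.linalg.norm(normal)
    if nn < 1e-9:
        raise ValueError("glabella and forehead-top landmarks coincide")
    normal = normal / nn
    origin = 0.5 * (g + t)

    import trimesh

    mesh = trimesh.Trimesh(vertices=c, faces=mask.triangles, process=False)
    segments = trimesh.intersections.mesh_plane(
        mesh, plane_normal=normal, plane_origin=origin
    )
    if len(segments) == 0:
        raise ValueError("plane does not intersect the mesh")
    pts3 = np.asarray(segments).reshape(-1, 3)
    # orthonormal in-plane basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rel = pts3 - origin
    pts2 = np.column_stack([rel @ e1, rel @ e2])
    _, radius = _fit_circle_2d(pts2)
    return radius


def interlandmark_fscp(config: np.ndarray, pairs=(), triples=()):
    """Euclidean distances (mm) for index pairs and interior angles (degrees)
    at the middle landmark for index triples."""
    c = np.asarray(config, dtype=float)
    distances = np.array(
        [np.linalg.norm(c[i] - c[j]) for i, j in pairs], dtype=float
    )
    angles = []
    for i, j, k in triples:
        u = c[i] - c[j]
        v = c[k] - c[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-12 or nv < 1e-12:
            raise ValueError(f"coincident points in triple ({i}, {j}, {k})")
        angles.append(np.degrees(np.arccos(np.clip(u @ v / (nu * nv), -1, 1))))
    return distances, np.array(angles, dtype=float)
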