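"""Face shape change parameters: areas, curvature, displacement, permutation
significance, and the global scalar measures."""

import numpy as np
import pytest

import facebrim as fb
from facebrim._mesh import grid_triangles, vertex_normals
from facebrim.mask import AnthropometricMask
from conftest_helpers import random_rotation


def _patch_mask(pts, rows, cols, outward_reference=None):
    """Minimal mask for an arbitrary structured-grid patch (tests only)."""
    tri = grid_triangles(rows, cols)
    if outward_reference is not None:
        vn = vertex_normals(pts, tri)
        if np.mean(np.einsum("ij,ij->i", vn, outward_reference)) < 0:
            tri = tri[:, ::-1]
    n = rows * cols
    return AnthropometricMask(
        n_landmarks=n,
        triangles=tri,
        bilateral_pairs=np.empty((0, 2), dtype=np.int64),
        midline=np.arange(n),
        template=pts,
    )


def sphere_patch(rows, cols, radius):
    th = np.linspace(0.25, 0.75, rows)
    ph = np.linspace(0.0, 0.5, cols)
    T, P = np.meshgrid(th, ph, indexing="ij")
    pts = np.column_stack(
        [
            (radius * np.sin(T) * np.cos(P)).ravel(),
            (radius * np.sin(T) * np.sin(P)).ravel(),
            (radius * np.cos(T)).ravel(),
        ]
    )
    return _patch_mask(pts, rows, cols, outward_reference=pts), pts


# ---------------------------------------------------------------------------
# areas


def test_single_triangle_landmark_areas():
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
    mask = AnthropometricMask(
        n_landmarks=3,
        triangles=np.array([[0, 1, 2]]),
        bilateral_pairs=np.empty((0, 2), dtype=np.int64),
        midline=np.arange(3),
    )
    areas = fb.local_area_map(pts, mask)
    assert np.abs(areas - 1.0 / 6.0).max() < 1e-15


def test_landmark_areas_partition_surface(mask5):
    from facebrim._mesh import triangle_areas

    areas = fb.local_area_map(mask5.template, mask5)
    total = triangle_areas(mask5.template, mask5.triangles).sum()
    assert abs(areas.sum() - total) < 1e-12 * total


def test_sphere_patch_area_analytic():
    """Total landmark area of a fine spherical patch matches the analytic
    patch area (r^2 * dphi * (cos t0 - cos t1)) within 2%."""
    r = 10.0
    mask, pts = sphere_patch(80, 80, r)
    total = fb.local_area_map(pts, mask).sum()
    analytic = r**2 * 0.5 * (np.cos(0.25) - np.cos(0.75))
    assert abs(total - analytic) / analytic < 0.02


def test_area_ratio_identity_and_scaling(mask5):
    ratio = fb.area_ratio(mask5.template, mask5.template, mask5)
    assert np.abs(ratio - 1.0).max() < 1e-12
    ratio2 = fb.area_ratio(mask5.template, 2.0 * mask5.template, mask5)
    assert np.abs(ratio2 - 4.0).max() < 1e-10


def test_area_ratio_reciprocal(mask5):
    rng = np.random.default_rng(2)
    b = mask5.template + rng.normal(0, 1.0, mask5.template.shape)
    fwd = fb.area_ratio(mask5.template, b, mask5)
    bwd = fb.area_ratio(b, mask5.template, mask5)
    assert np.abs(fwd * bwd - 1.0).max() < 1e-10


def test_area_ratio_bump_support():
    mask = fb.make_mask_grid(20, 25)
    tpl = mask.template
    b = tpl.copy()
    d2 = tpl[:, 0] ** 2 + tpl[:, 1] ** 2
    bump = 8.0 * np.exp(-0.5 * d2 / 15.0**2)
    b[:, 2] += bump
    ratio = fb.area_ratio(tpl, b, mask)
    inside = bump > 4.0
    outside = bump < 0.1
    assert ratio[inside].mean() > 1.02
    assert np.abs(ratio[outside] - 1.0).max() < 0.02


# ---------------------------------------------------------------------------
# curvature


def test_flat_grid_zero_curvature():
    xx, yy = np.meshgrid(np.linspace(0, 10, 20), np.linspace(0, 10, 20))
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(400)])
    mask = _patch_mask(pts, 20, 20)
    k, boundary = fb.mean_curvature_map(pts, mask)
    assert np.abs(k[~boundary]).max() < 1e-8


@pytest.mark.parametrize("r", [10.0, 20.0])
def test_sphere_curvature_analytic(r):
    mask, pts = sphere_patch(60, 60, r)
    k, boundary = fb.mean_curvature_map(pts, mask)
    interior = k[~boundary]
    assert abs(interior.mean() - 1.0 / r) / (1.0 / r) < 0.05
    assert (interior > 0).all()  # convex outward => positive


def test_cylinder_curvature_analytic():
    r = 10.0
    rows, cols = 60, 60
    ph = np.linspace(0, 1.0, cols)
    zz = np.linspace(0, 15, rows)
    Z, P = np.meshgrid(zz, ph, indexing="ij")
    pts = np.column_stack([(r * np.cos(P)).ravel(), (r * np.sin(P)).ravel(), Z.ravel()])
    radial = pts.copy()
    radial[:, 2] = 0.0
    mask = _patch_mask(pts, rows, cols, outward_reference=radial)
    k, boundary = fb.mean_curvature_map(pts, mask)
    expected = 1.0 / (2 * r)
    assert abs(k[~boundary].mean() - expected) / expected < 0.05


def test_curvature_difference_of_spheres():
    m1, p1 = sphere_patch(60, 60, 10.0)
    _, p2 = sphere_patch(60, 60, 20.0)
    diff, boundary = fb.curvature_compare(p1, p2, m1, mode="difference")
    expected = 1.0 / 20 - 1.0 / 10
    assert abs(diff[~boundary].mean() - expected) / abs(expected) < 0.05


def test_curvature_compare_identity_and_definition(mask5):
    diff, _ = fb.curvature_compare(mask5.template, mask5.template, mask5)
    assert np.abs(diff).max() == 0.0
    ratio, _ = fb.curvature_compare(mask5.template, mask5.template, mask5, mode="ratio")
    ok = ~np.isnan(ratio)
    assert np.abs(ratio[ok] - 1.0).max() < 1e-12
    rng = np.random.default_rng(3)
    b = mask5.template + rng.normal(0, 0.5, mask5.template.shape)
    diff2, _ = fb.curvature_compare(mask5.template, b, mask5)
    ka, _ = fb.mean_curvature_map(mask5.template, mask5)
    kb, _ = fb.mean_curvature_map(b, mask5)
    assert np.array_equal(diff2, kb - ka)


# ---------------------------------------------------------------------------
# normal displacement


def test_normal_displacement_zero_and_construction(mask5):
    nd = fb.normal_displacement(mask5.template, mask5.template, mask5)
    assert np.abs(nd).max() == 0.0
    n = vertex_normals(mask5.template, mask5.triangles)
    b = mask5.template + 0.37 * n
    nd2 = fb.normal_displacement(mask5.template, b, mask5)
    assert np.abs(nd2 - 0.37).max() < 1e-6


def test_normal_displacement_matches_dot_product(mask5):
    rng = np.random.default_rng(4)
    b = mask5.template + rng.normal(0, 1.0, mask5.template.shape)
    nd = fb.normal_displacement(mask5.template, b, mask5)
    n = vertex_normals(mask5.template, mask5.triangles)
    oracle = np.einsum("ij,ij->i", b - mask5.template, n)
    assert np.abs(nd - oracle).max() < 1e-12


def test_normal_displacement_first_order_antisymmetry(mask5):
    eps = 1e-3
    rng = np.random.default_rng(5)
    b = mask5.template + eps * rng.normal(0, 1.0, mask5.template.shape)
    fwd = fb.normal_displacement(mask5.template, b, mask5)
    bwd = fb.normal_displacement(b, mask5.template, mask5)
    assert np.abs(fwd + bwd).max() < 50 * eps**2


# ---------------------------------------------------------------------------
# permutation significance


def test_permutation_null_calibration():
    rng = np.random.default_rng(6)
    n, k = 60, 40
    shapes = rng.normal(size=(n, 3 * k))
    rip = rng.normal(size=n)
    p, sig = fb.permutation_significance(rip, shapes, B=999, alpha=0.05, seed=0)
    frac = (p < 0.05).mean()
    # landmarks are independent here: binomial(40, 0.05) 99% band
    assert frac < 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / k)
    assert sig.sum() == (p < 0.05).sum()


def test_permutation_saturates_on_strong_effect():
    rng = np.random.default_rng(7)
    n, k = 100, 5
    rip = rng.normal(size=n)
    shapes = rng.normal(size=(n, 3 * k)) * 0.01
    shapes[:, 0:3] += rip[:, None] * 5.0  # landmark 0 exactly driven by rip
    p, _ = fb.permutation_significance(rip, shapes, B=999, alpha=0.01, seed=1)
    assert p[0] == pytest.approx(1.0 / 1000.0)


def test_permutation_guards():
    rng = np.random.default_rng(8)
    shapes = rng.normal(size=(30, 9))
    rip = rng.normal(size=30)
    with pytest.raises(ValueError, match="at least 99"):
        fb.permutation_significance(rip, shapes, B=50)
    with pytest.raises(ValueError, match="unreachable"):
        fb.permutation_significance(rip, shapes, B=99, alpha=0.001)


def test_permutation_pvalues_superuniform_under_null():
    """p-values from 200 independent null replicates are (super)uniform:
    Kolmogorov-Smirnov test does not reject, and rejection rates at 0.05 and
    0.1 stay within their binomial confidence bands."""
    from scipy import stats as sps

    rng = np.random.default_rng(9)
    pvals = []
    for _ in range(200):
        shapes = rng.normal(size=(25, 3))  # single landmark
        rip = rng.normal(size=25)
        p, _ = fb.permutation_significance(
            rip, shapes, B=199, alpha=0.05, seed=int(rng.integers(2**31))
        )
        pvals.append(p[0])
    pvals = np.array(pvals)
    assert sps.kstest(pvals, "uniform").pvalue > 0.01
    for alpha in (0.05, 0.1):
        frac = (pvals < alpha).mean()
        assert frac < alpha + 2.6 * np.sqrt(alpha * (1 - alpha) / 200)


# ---------------------------------------------------------------------------
# global FSCPs


def _square_border_config(mask):
    """Configuration whose border landmarks lie exactly on a square."""
    cfg = mask.template.copy()
    border = mask.border
    t = np.linspace(0, 4, len(border), endpoint=False)
    side = 100.0
    pts = []
    for u in t:
        edge = int(u)
        frac = u - edge
        if edge == 0:
            pts.append((-side / 2 + side * frac, -side / 2))
        elif edge == 1:
            pts.append((side / 2, -side / 2 + side * frac))
        elif edge == 2:
            pts.append((side / 2 - side * frac, side / 2))
        else:
            pts.append((-side / 2, side / 2 - side * frac))
    cfg[border, 0] = [p[0] for p in pts]
    cfg[border, 1] = [p[1] for p in pts]
    return cfg


def test_squareness_zero_on_exact_square():
    mask = fb.make_mask_grid(10, 11)
    cfg = _square_border_config(mask)
    assert fb.facial_squareness(cfg, mask) < 1e-6


def test_squareness_circle_matches_dense_oracle():
    mask = fb.make_mask_grid(10, 11)
    cfg = mask.template.copy()
    r = 80.0
    t = np.linspace(0, 2 * np.pi, len(mask.border), endpoint=False)
    cfg[mask.border, 0] = r * np.cos(t)
    cfg[mask.border, 1] = r * np.sin(t)
    score = fb.facial_squareness(cfg, mask)

    # oracle: best square for a circle is concentric; optimize the half-side
    # against a dense angular sampling
    from scipy.optimize import minimize_scalar

    tt = np.linspace(0, 2 * np.pi, 20000, endpoint=False)
    px, py = r * np.cos(tt), r * np.sin(tt)

    def rms(half):
        qx = np.abs(px) - half
        qy = np.abs(py) - half
        outside = np.hypot(np.maximum(qx, 0), np.maximum(qy, 0))
        inside = np.minimum(np.maximum(qx, qy), 0.0)
        return np.sqrt(np.mean((outside - inside) ** 2))

    res = minimize_scalar(rms, bounds=(0.5 * r, 1.5 * r), method="bounded")
    assert abs(score - res.fun) / res.fun < 0.01


def test_squareness_rigid_invariance():
    mask = fb.make_mask_grid(10, 11)
    cfg = _square_border_config(mask)
    th = 0.4
    R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    moved = cfg @ R.T + np.array([13.0, -7.0, 5.0])
    assert abs(fb.facial_squareness(moved, mask) - fb.facial_squareness(cfg, mask)) < 1e-6


def test_circumference_proxy_spherical_cap():
    """Plane-sphere intersection radius sqrt(R^2 - d^2) recovered within 1%."""
    rows, cols = 41, 41
    R = 100.0
    xs = np.linspace(-60, 60, cols)
    ys = np.linspace(-60, 60, rows)
    X, Y = np.meshgrid(xs, ys)
    Z = np.sqrt(R**2 - X**2 - Y**2)
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    mask = fb.make_mask_grid(rows, cols)
    mask = AnthropometricMask(
        n_landmarks=mask.n_landmarks,
        triangles=mask.triangles,
        bilateral_pairs=mask.bilateral_pairs,
        midline=mask.midline,
        template=pts,
        landmark_names=mask.landmark_names,
        border=mask.border,
        grid_shape=mask.grid_shape,
    )
    g = pts[mask.landmark_names["glabella"]]
    t = pts[mask.landmark_names["forehead_top"]]
    mid = 0.5 * (g + t)
    normal = (t - g) / np.linalg.norm(t - g)
    d = abs(mid @ normal)  # sphere centered at origin
    expected = np.sqrt(R**2 - d**2)
    got = fb.circumference_proxy(pts, mask)
    assert abs(got - expected) / expected < 0.01


def test_circumference_proxy_invariances():
    mask = fb.make_mask_grid(20, 25)
    cfg = mask.template
    base = fb.circumference_proxy(cfg, mask)
    rng = np.random.default_rng(10)
    moved = cfg @ random_rotation(rng).T + rng.normal(0, 20, 3)
    assert abs(fb.circumference_proxy(moved, mask) - base) < 1e-6
    assert abs(fb.circumference_proxy(1.7 * cfg, mask) - 1.7 * base) < 1e-8 * base


def test_interlandmark_distances_and_angles():
    cfg = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [5, 0, 0]])
    d, a = fb.interlandmark_fscp(cfg, pairs=[(0, 1)], triples=[(0, 1, 2)])
    assert d[0] == pytest.approx(1.0)
    assert a[0] == pytest.approx(90.0)
    with pytest.raises(ValueError, match="coincident"):
        fb.interlandmark_fscp(cfg, triples=[(0, 0, 2)])


def test_interlandmark_rigid_invariance():
    rng = np.random.default_rng(11)
    cfg = rng.normal(size=(6, 3))
    moved = cfg @ random_rotation(rng).T + rng.normal(0, 5, 3)
    d1, a1 = fb.interlandmark_fscp(cfg, pairs=[(0, 3), (1, 4)], triples=[(0, 2, 4)])
    d2, a2 = fb.interlandmark_fscp(moved, pairs=[(0, 3), (1, 4)], triples=[(0, 2, 4)])
    assert np.abs(d1 - d2).max() < 1e-10
    assert np.abs(a1 - a2).max() < 1e-8
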