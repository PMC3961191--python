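"""Procrustes morphometrics of corresponded quasi-landmark configurations.

Workflow: each configuration is reflected (x-sign flip plus bilateral
relabeling), originals and reflections are superimposed jointly by
generalized Procrustes analysis (GPA), the symmetric and asymmetric
components are extracted, shapes are projected to the tangent space of
Kendall shape space at the consensus, and a PCA of the symmetric shapes
yields the low-dimensional face space used downstream.

Conventions: configurations are centered and scaled to unit centroid size
(classical full Procrustes); rotations are proper (det +1) so mirror
correspondence is handled only by the explicit reflect-and-relabel step;
PCA axes are oriented so the loading of largest magnitude is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mask import AnthropometricMask

__all__ = [
    "AlignedSample",
    "ShapeSpace",
    "reflect_configuration",
    "generalized_procrustes",
    "symmetrize",
    "symmetric_components",
    "project_tangent",
    "fit_shape_pca",
    "scores",
    "reconstruct",
    "reconstruction_rmse",
    "axis_transformation",
]


# ---------------------------------------------------------------------------
# reflection


def reflect_configuration(coords: np.ndarray, mask: AnthropometricMask) -> np.ndarray:
    """Mirror a configuration: negate x and relabel by the bilateral pairing.

    Landmark i of the output is the mirror-image homologue of landmark i of
    the input, so output and input are in correspondence.  Applying the
    operation twice is the identity.
    """
    if mask.bilateral_pairs.size == 0 and mask.midline.size != mask.n_landmarks:
        raise ValueError("mask has no bilateral pairing")
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (mask.n_landmarks, 3):
        raise ValueError(
            f"configuration shape {coords.shape} does not conform to mask "
            f"({mask.n_landmarks} landmarks)"
        )
    out = coords.copy()
    out[:, 0] = -out[:, 0]
    return out[mask.mirror_permutation]


# ---------------------------------------------------------------------------
# generalized Procrustes analysis


@dataclass
class AlignedSample:
    """Procrustes shape coordinates for a sample of configurations.

    ``shapes`` is (n_total, 3k) with each row a centered, unit-centroid-size,
    rotated configuration (flattened row-major: x1,y1,z1,x2,...).  When the
    sample was built with reflections, rows 0..n-1 are the originals and rows
    n..2n-1 the corresponding reflections, and ``consensus`` is bilaterally
    symmetric.
    """

    shapes: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    n_original: int
    includes_reflections: bool = False
    tangent_projected: bool = False
    n_iterations: int = 0
    ids: list | None = None

    @property
    def n_landmarks(self) -> int:
        return self.shapes.shape[1] // 3

    def configurations(self) -> np.ndarray:
        return self.shapes.reshape(len(self.shapes), -1, 3)


def centroid_size(coords: np.ndarray) -> float:
    """Root summed squared distance of landmarks from their centroid."""
    c = coords - coords.mean(axis=0)
    return float(np.linalg.norm(c))


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||source @ R - target||."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    return u @ vt


def _canonical_orientation(consensus: np.ndarray, bilateral: bool) -> np.ndarray:
    """Proper rotation bringing the consensus to a canonical pose.

    Pins the global rotation left free by superimposition, making GPA
    output invariant to rigid motions of its inputs.  For a bilateral
    (reflection-including) sample the mirror plane must remain x = 0, so
    only the in-plane (yz) principal axes are canonicalized and the x axis
    is kept; otherwise all three principal axes are used.  Axis signs are
    chosen so the third moment of the coordinates along each axis is
    positive; sign-ambiguous axes (third moment near zero, e.g. the
    bilateral axis of a symmetric consensus) are resolved last by requiring
    det = +1.
    """
    if bilateral:
        cov2 = consensus[:, 1:].T @ consensus[:, 1:]
        evals, v2 = np.linalg.eigh(cov2)
        v2 = v2[:, np.argsort(evals)[::-1]]
        vecs = np.eye(3)
        vecs[1:, 1:] = v2
    else:
        cov = consensus.T @ consensus
        evals, vecs = np.linalg.eigh(cov)
        vecs = vecs[:, np.argsort(evals)[::-1]]
    rotated = consensus @ vecs
    skew = (rotated**3).sum(axis=0)
    scale = np.abs(rotated).max(axis=0) ** 3 * len(consensus)
    ambiguous = np.abs(skew) < 1e-9 * np.maximum(scale, 1e-300)
    signs = np.where(skew >= 0, 1.0, -1.0)
    signs[ambiguous] = 1.0
    vecs = vecs * signs
    if np.linalg.det(vecs) < 0:
        amb_idx = np.flatnonzero(ambiguous)
        flip = amb_idx[-1] if len(amb_idx) else 2
        vecs[:, flip] *= -1.0
    return vecs


def generalized_procrustes(
    configs,
    mask: AnthropometricMask | None = None,
    include_reflections: bool = False,
    tol: float = 1e-10,
    max_iterations: int = 100,
    ids: list | None = None,
) -> AlignedSample:
    """Iterative generalized Procrustes superimposition.

    Each configuration is centered and scaled to unit centroid size, then
    repeatedly rotated (proper rotations only) to the running consensus until
    the consensus RMS change drops below ``tol``.  With
    ``include_reflections`` the originals and their reflect-and-relabeled
    mirror images are superimposed jointly, which makes the consensus
    bilaterally symmetric and enables the symmetric/asymmetric decomposition.
    """
    arr = np.asarray(configs, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("configs must be (n, k, 3)")
    n, k, _ = arr.shape
    if n < 2:
        raise ValueError("need at least 2 configurations")
    if include_reflections:
        if mask is None:
            raise ValueError("include_reflections requires a mask")
        refl = np.stack([reflect_configuration(c, mask) for c in arr])
        work = np.concatenate([arr, refl], axis=0)
    else:
        work = arr.copy()

    sizes = np.empty(len(work))
    for i, c in enumerate(work):
        c -= c.mean(axis=0)
        s = np.linalg.norm(c)
        if s < 1e-12:
            raise ValueError(f"configuration {i} has zero centroid size")
        sizes[i] = s
        work[i] = c / s

    # consensus is kept as the arithmetic mean of the aligned configurations;
    # the optimal rotation is scale-invariant in its target, so no consensus
    # renormalization is needed during iteration
    consensus = work[0].copy()
    if include_reflections:
        # a bilaterally symmetric consensus is a fixed point of the joint
        # iteration; symmetrizing the running consensus pins the global
        # rotation so the final consensus equals its own reflection exactly
        consensus = 0.5 * (consensus + reflect_configuration(consensus, mask))
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        for i in range(len(work)):
            work[i] = work[i] @ _optimal_rotation(work[i], consensus)
        new = work.mean(axis=0)
        if include_reflections:
            new = 0.5 * (new + reflect_configuration(new, mask))
        new -= new.mean(axis=0)
        change = np.sqrt(np.mean((new - consensus) ** 2))
        consensus = new
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iterations} iterations "
            f"(last consensus RMS change {change:.3e})"
        )

    rot = _canonical_orientation(consensus, include_reflections)
    consensus = consensus @ rot
    work = work @ rot

    return AlignedSample(
        shapes=work.reshape(len(work), -1),
        consensus=consensus.ravel(),
        centroid_sizes=sizes[:n],
        n_original=n,
        includes_reflections=include_reflections,
        n_iterations=n_iter,
        ids=list(ids) if ids is not None else None,
    )


# ---------------------------------------------------------------------------
# symmetric / asymmetric decomposition


def symmetrize(aligned_original: np.ndarray, aligned_reflected: np.ndarray):
    """Split a shape into its symmetric and asymmetric components.

    The symmetric component is the average of the original and its
    (reflect-and-relabeled, jointly aligned) mirror image; the asymmetric
    component is half their difference, so symmetric + asymmetric
    reconstructs the original exactly.
    """
    a = np.asarray(aligned_original, dtype=float)
    b = np.asarray(aligned_reflected, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape length mismatch between original and reflection")
    return 0.5 * (a + b), 0.5 * (a - b)


def symmetric_components(sample: AlignedSample):
    """Per-individual (symmetric, asymmetric) shapes from a joint GPA."""
    if not sample.includes_reflections:
        raise ValueError("sample was not aligned with include_reflections")
    n = sample.n_original
    return symmetrize(sample.shapes[:n], sample.shapes[n:])


# ---------------------------------------------------------------------------
# tangent projection


def project_tangent(sample: AlignedSample) -> AlignedSample:
    """Project aligned shapes onto the tangent space at the consensus.

    Shapes live near the unit sphere in configuration space; each is mapped
    to the affine hyperplane through the consensus orthogonal to it
    (orthogonal projection), the linearization of Kendall shape space at the
    consensus.  Idempotent; the consensus is a fixed point.
    """
    c = sample.consensus / np.linalg.norm(sample.consensus)
    shapes = np.asarray(sample.shapes, dtype=float)
    coef = 1.0 - shapes @ c  # distance of each shape from the hyperplane
    projected = shapes + coef[:, None] * c[None, :]
    return replace(sample, shapes=projected, tangent_projected=True)


# ---------------------------------------------------------------------------
# shape PCA


@dataclass
class ShapeSpace:
    """PCA model of a shape sample about the consensus.

    ``axes`` holds all computed orthonormal axes (rows); the first
    ``n_retained`` explain at least ``retained_fraction_target`` of the total
    variance.  ``variances`` are the per-axis sample variances (divisor n-1).
    """

    mean: np.ndarray
    axes: np.ndarray
    variances: np.ndarray
    n_retained: int
    retained_fraction: float
    total_variance: float

    @property
    def n_landmarks(self) -> int:
        return len(self.mean) // 3

    @property
    def retained_axes(self) -> np.ndarray:
        return self.axes[: self.n_retained]

    @property
    def retained_variances(self) -> np.ndarray:
        return self.variances[: self.n_retained]


def fit_shape_pca(
    sample, retained_fraction: float = 0.98, center: np.ndarray | None = None
) -> ShapeSpace:
    """PCA of shape coordinates about the consensus.

    ``sample`` may be an :class:`AlignedSample` (its consensus is the center)
    or an (n, 3k) array (``center`` defaults to the column mean).  Retains
    the smallest number of axes whose cumulative variance reaches
    ``retained_fraction`` of the total.
    """
    if retained_fraction <= 0 or retained_fraction > 1:
        raise ValueError("retained_fraction must be in (0, 1]")
    if isinstance(sample, AlignedSample):
        shapes = sample.shapes
        if center is None:
            center = sample.consensus
    else:
        shapes = np.asarray(sample, dtype=float)
    if shapes.ndim != 2 or len(shapes) < 3:
        raise ValueError("need at least 3 shapes")
    if center is None:
        center = shapes.mean(axis=0)
    center = np.asarray(center, dtype=float)

    dev = shapes - center
    # SVD of deviations: right singular vectors are the covariance eigenvectors
    _, s, vt = np.linalg.svd(dev, full_matrices=False)
    variances = s**2 / (len(shapes) - 1)
    total = float(variances.sum())
    cum = np.cumsum(variances)
    n_retained = int(np.searchsorted(cum, retained_fraction * total - 1e-12) + 1)
    n_retained = min(n_retained, len(variances))

    # deterministic sign: largest-magnitude loading of each axis positive
    axes = vt.copy()
    flip = np.sign(axes[np.arange(len(axes)), np.abs(axes).argmax(axis=1)])
    flip[flip == 0] = 1.0
    axes *= flip[:, None]

    return ShapeSpace(
        mean=center,
        axes=axes,
        variances=variances,
        n_retained=n_retained,
        retained_fraction=float(cum[n_retained - 1] / total),
        total_variance=total,
    )


def scores(space: ShapeSpace, shapes: np.ndarray) -> np.ndarray:
    """Project shape(s) onto the retained axes."""
    arr = np.atleast_2d(np.asarray(shapes, dtype=float))
    sc = (arr - space.mean) @ space.retained_axes.T
    return sc[0] if np.asarray(shapes).ndim == 1 else sc


def reconstruct(space: ShapeSpace, score_vec: np.ndarray) -> np.ndarray:
    """Rebuild shape(s) from retained-axis scores: mean + sum(score * axis)."""
    arr = np.atleast_2d(np.asarray(score_vec, dtype=float))
    if arr.shape[1] != space.n_retained:
        raise ValueError(
            f"score length {arr.shape[1]} != retained axis count {space.n_retained}"
        )
    out = space.mean + arr @ space.retained_axes
    return out[0] if np.asarray(score_vec).ndim == 1 else out


def reconstruction_rmse(space: ShapeSpace, shapes: np.ndarray) -> np.ndarray:
    """Per-shape RMSE per landmark of the retained-rank reconstruction.

    Reported in the shapes' coordinate units per landmark (the per-landmark
    root mean of the squared 3D reconstruction displacement).
    """
    arr = np.atleast_2d(np.asarray(shapes, dtype=float))
    rec = reconstruct(space, scores(space, arr))
    resid = (arr - rec).reshape(len(arr), -1, 3)
    per_shape = np.sqrt((resid**2).sum(axis=2).mean(axis=1))
    return per_shape[0] if np.asarray(shapes).ndim == 1 else per_shape


def axis_transformation(
    space: ShapeSpace,
    direction: np.ndarray,
    k: float,
    sample_scores: np.ndarray,
):
    """Shape transformations at -k and +k SD along a score-space direction.

    ``direction`` is a vector in retained-score space (normalized here);
    the SD is that of ``sample_scores`` projected on the direction.  Returns
    (shape_minus, shape_plus) as (n_landmarks, 3) configurations.
    """
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm < 1e-300:
        raise ValueError("zero direction")
    d = d / nrm
    proj = np.asarray(sample_scores, dtype=float) @ d
    sd = proj.std(ddof=1)
    lo = reconstruct(space, -abs(k) * sd * d)
    hi = reconstruct(space, abs(k) * sd * d)
    kk = space.n_landmarks
    return lo.reshape(kk, 3), hi.reshape(kk, 3)
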