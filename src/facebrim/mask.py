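"""The anthropometric mask: shared quasi-landmark topology.

Every individual's configuration is an ordered point set with one point per
mask vertex, so all individuals are in dense point-to-point correspondence.
The mask records the triangulation, the left-right (bilateral) pairing used
to reflect and relabel configurations, the midline vertices fixed by that
pairing, and optionally a template embedding plus named landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._mesh import boundary_vertices, grid_triangles

__all__ = ["AnthropometricMask", "make_mask_grid"]

# template embedding extents (mm): a face-like smooth convex height field
_FACE_HALF_WIDTH = 70.0
_FACE_HALF_HEIGHT = 90.0
_FACE_DEPTH = 55.0


@dataclass(frozen=True)
class AnthropometricMask:
    """Quasi-landmark template topology shared by all configurations.

    Attributes
    ----------
    n_landmarks : total vertex count.
    triangles : (m, 3) vertex-index triples with consistent orientation.
    bilateral_pairs : (P, 2) index pairs (i, mirror(i)) with i != mirror(i);
        each off-midline vertex appears in exactly one pair.
    midline : indices with mirror(i) == i.
    template : optional (n, 3) template coordinates in mm, bilaterally
        symmetric about the x = 0 plane.
    landmark_names : optional named anatomical positions (index per name).
    border : indices of open-boundary vertices.
    """

    n_landmarks: int
    triangles: np.ndarray
    bilateral_pairs: np.ndarray
    midline: np.ndarray
    template: np.ndarray | None = None
    landmark_names: dict = field(default_factory=dict)
    border: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    grid_shape: tuple | None = None

    def __post_init__(self):
        tri = np.asarray(self.triangles, dtype=np.int64)
        pairs = np.asarray(self.bilateral_pairs, dtype=np.int64).reshape(-1, 2)
        mid = np.asarray(self.midline, dtype=np.int64)
        object.__setattr__(self, "triangles", tri)
        object.__setattr__(self, "bilateral_pairs", pairs)
        object.__setattr__(self, "midline", mid)
        if tri.size and (tri.min() < 0 or tri.max() >= self.n_landmarks):
            raise ValueError("triangle indices out of range")
        covered = np.concatenate([pairs.ravel(), mid])
        if len(np.unique(covered)) != self.n_landmarks or len(covered) != self.n_landmarks:
            raise ValueError(
                "every landmark must be in exactly one bilateral pair or on the midline"
            )
        perm = self.mirror_permutation
        if not np.array_equal(perm[perm], np.arange(self.n_landmarks)):
            raise ValueError("bilateral pairing is not an involution")

    @property
    def mirror_permutation(self) -> np.ndarray:
        """perm[i] = index of the mirror-image homologue of landmark i."""
        perm = np.arange(self.n_landmarks)
        perm[self.bilateral_pairs[:, 0]] = self.bilateral_pairs[:, 1]
        perm[self.bilateral_pairs[:, 1]] = self.bilateral_pairs[:, 0]
        return perm


def template_height(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Smooth convex face-like height field z(x, y), symmetric in x (mm)."""
    return (
        _FACE_DEPTH
        * np.cos(0.5 * np.pi * x / (1.15 * _FACE_HALF_WIDTH))
        * np.cos(0.5 * np.pi * y / (1.15 * _FACE_HALF_HEIGHT))
    )


def _named_landmarks(rows: int, cols: int) -> dict:
    cmid = (cols - 1) // 2

    def idx(rfrac, cfrac):
        r = int(round(rfrac * (rows - 1)))
        j = int(round(cfrac * (cols - 1)))
        return r * cols + j

    names = {
        "pogonion": idx(0.0, 0.5),          # chin, bottom midline
        "labiale_inferius": idx(0.18, 0.5),
        "subnasale": idx(0.40, 0.5),
        "pronasale": idx(0.50, 0.5),        # template apex
        "glabella": idx(0.75, 0.5),
        "forehead_top": (rows - 1) * cols + cmid,
        "cheilion_right": idx(0.22, 0.30),
        "cheilion_left": idx(0.22, 0.70),
        "exocanthion_right": idx(0.68, 0.15),
        "exocanthion_left": idx(0.68, 0.85),
        "zygion_right": idx(0.55, 0.05),
        "zygion_left": idx(0.55, 0.95),
    }
    return names


def make_mask_grid(rows: int, cols: int) -> AnthropometricMask:
    """Build a rectangular-grid quasi-landmark mask with a face-like template.

    The grid spans x in [-70, 70] mm (columns) and y in [-90, 90] mm (rows)
    and is embedded as a smooth convex height field so outward is +z.
    ``cols`` must be odd so the central column is a genuine midline; column j
    pairs with column cols-1-j.
    """
    if rows < 4 or cols < 4:
        raise ValueError("grid needs at least 4 rows and 4 columns")
    if cols % 2 == 0:
        raise ValueError("cols must be odd so a midline column exists")

    cmid = (cols - 1) // 2
    xs_half = np.linspace(0.0, _FACE_HALF_WIDTH, cmid + 1)
    xs = np.concatenate([-xs_half[:0:-1], xs_half])  # exactly antisymmetric
    ys = np.linspace(-_FACE_HALF_HEIGHT, _FACE_HALF_HEIGHT, rows)
    xx, yy = np.meshgrid(xs, ys)  # row-major: vertex (r, j) -> r*cols + j
    zz = template_height(np.abs(xx), yy)  # even in x, bit-exact mirror symmetry
    template = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    triangles = grid_triangles(rows, cols)

    left_cols = np.arange(cmid + 1, cols)
    pairs = []
    for r in range(rows):
        for j in left_cols:
            pairs.append((r * cols + j, r * cols + (cols - 1 - j)))
    pairs = np.array(pairs, dtype=np.int64)
    midline = (np.arange(rows) * cols + cmid).astype(np.int64)

    border = boundary_vertices(rows * cols, triangles)
    return AnthropometricMask(
        n_landmarks=rows * cols,
        triangles=triangles,
        bilateral_pairs=pairs,
        midline=midline,
        template=template,
        landmark_names=_named_landmarks(rows, cols),
        border=border,
        grid_shape=(rows, cols),
    )
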