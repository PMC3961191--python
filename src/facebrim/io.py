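"""File formats: meshes (OBJ/PLY), wide landmark tables, covariate and
genotype tables, the JSON mask file, and the shape-space archive.

Conventions: right-handed coordinates in mm, x = subject's left-right
(reflection flips its sign); landmark indices are 0-based internally (OBJ
faces are converted from their 1-based on-disk form); tables are
comma-delimited with coordinates written at 9 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mask import AnthropometricMask
from .morphometry import ShapeSpace

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_landmark_table",
    "write_landmark_table",
    "read_mask",
    "write_mask",
    "read_covariates",
    "write_covariates",
    "read_genotypes",
    "write_genotypes",
    "load_shape_space",
    "save_shape_space",
]


# ---------------------------------------------------------------------------
# meshes


def read_mesh(path):
    """Load an OBJ or PLY triangle mesh; returns (vertices, faces) with
    0-based faces regardless of the on-disk convention."""
    import trimesh

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mesh = trimesh.load_mesh(str(path), process=False)
    faces = np.asarray(mesh.faces)
    if faces.ndim != 2 or faces.shape[1] != 3:
        bad = 0 if faces.ndim != 2 else int(np.argmax(faces.shape[1] != 3))
        raise ValueError(f"non-triangle face at index {bad} in {path}")
    return np.asarray(mesh.vertices, dtype=float), faces.astype(np.int64)


def write_mesh(vertices, faces, path):
    """Write a triangle mesh as ascii OBJ or PLY (by file extension)."""
    import trimesh

    path = Path(path)
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if path.suffix.lower() == ".ply":
        # ascii PLY with double-precision coordinates (trimesh's exporter
        # downcasts to float32, violating the round-trip contract)
        lines = [
            "ply",
            "format ascii 1.0",
            f"element vertex {len(vertices)}",
            "property double x",
            "property double y",
            "property double z",
            f"element face {len(faces)}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        lines += [f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in vertices]
        lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in faces]
        path.write_text("\n".join(lines) + "\n")
    elif path.suffix.lower() == ".obj":
        mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
        path.write_text(trimesh.exchange.obj.export_obj(mesh))
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")


# ---------------------------------------------------------------------------
# landmark tables (wide: id, x1, y1, z1, x2, ...)


def write_landmark_table(configs, ids, path):
    configs = np.asarray(configs, dtype=float)
    flat = configs.reshape(len(configs), -1)
    k = flat.shape[1] // 3
    cols = [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y", "z")]
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "id", list(ids))
    df.to_csv(path, index=False, float_format="%.9g")


def read_landmark_table(path, mask: AnthropometricMask | None = None):
    """Read configurations; returns (configs (n, k, 3), ids)."""
    df = pd.read_csv(path)
    if df.columns[0] != "id":
        raise ValueError("first column must be 'id'")
    ncoord = df.shape[1] - 1
    if ncoord % 3:
        raise ValueError(f"coordinate column count {ncoord} is not a multiple of 3")
    if mask is not None and ncoord != 3 * mask.n_landmarks:
        raise ValueError(
            f"expected {3 * mask.n_landmarks} coordinate columns for the mask, "
            f"found {ncoord}"
        )
    vals = df.iloc[:, 1:].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("missing or non-finite coordinates")
    return vals.reshape(len(df), ncoord // 3, 3), df["id"].tolist()


# ---------------------------------------------------------------------------
# mask


def write_mask(mask: AnthropometricMask, path):
    payload = {
        "n_landmarks": mask.n_landmarks,
        "triangles": mask.triangles.tolist(),
        "bilateral_pairs": mask.bilateral_pairs.tolist(),
        "midline": mask.midline.tolist(),
        "landmark_names": {k: int(v) for k, v in mask.landmark_names.items()},
        "border": mask.border.tolist(),
        "grid_shape": list(mask.grid_shape) if mask.grid_shape else None,
        "template": None if mask.template is None else mask.template.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_mask(path) -> AnthropometricMask:
    d = json.loads(Path(path).read_text())
    return AnthropometricMask(
        n_landmarks=d["n_landmarks"],
        triangles=np.asarray(d["triangles"], dtype=np.int64),
        bilateral_pairs=np.asarray(d["bilateral_pairs"], dtype=np.int64).reshape(-1, 2),
        midline=np.asarray(d["midline"], dtype=np.int64),
        template=None if d.get("template") is None else np.asarray(d["template"]),
        landmark_names=d.get("landmark_names", {}),
        border=np.asarray(d.get("border", []), dtype=np.int64),
        grid_shape=tuple(d["grid_shape"]) if d.get("grid_shape") else None,
    )


# ---------------------------------------------------------------------------
# covariates and genotypes


def write_covariates(path, ids, sex, q_true=None, ancestry_estimate=None):
    df = pd.DataFrame({"id": list(ids), "sex": np.asarray(sex).astype(int)})
    if q_true is not None:
        df["q_true"] = np.asarray(q_true, dtype=float)
    if ancestry_estimate is not None:
        df["ancestry_estimate"] = np.asarray(ancestry_estimate, dtype=float)
    df.to_csv(path, index=False, float_format="%.9g")


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df.columns or "sex" not in df.columns:
        raise ValueError("covariate table needs 'id' and 'sex' columns")
    return df


def write_genotypes(path, ids, genotypes, snp_names=None):
    g = np.asarray(genotypes)
    if snp_names is None:
        snp_names = [f"snp{j}" for j in range(g.shape[1])]
    df = pd.DataFrame(g, columns=list(snp_names))
    df.insert(0, "id", list(ids))
    df.to_csv(path, index=False)


def read_genotypes(path, coding: str = "auto") -> pd.DataFrame:
    """Read a genotype table; values recoded to -1/0/+1 additive coding.

    ``coding='auto'`` detects {0,1,2} (shifted by -1) versus {-1,0,1}
    (taken as is); pass 'counts' or 'signed' to override.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "id":
        raise ValueError("first column must be 'id'")
    vals = df.iloc[:, 1:].to_numpy()
    uniq = set(np.unique(vals).tolist())
    if coding == "auto":
        coding = "signed" if -1 in uniq else "counts"
    if coding == "counts":
        if not uniq <= {0, 1, 2}:
            raise ValueError("additive counts must be in {0, 1, 2}")
        df.iloc[:, 1:] = vals - 1
    elif coding == "signed":
        if not uniq <= {-1, 0, 1}:
            raise ValueError("signed coding must be in {-1, 0, 1}")
    else:
        raise ValueError("coding must be 'auto', 'counts' or 'signed'")
    return df


# ---------------------------------------------------------------------------
# shape-space archive


def save_shape_space(space: ShapeSpace, path):
    np.savez_compressed(
        path,
        mean=space.mean,
        axes=space.axes,
        variances=space.variances,
        n_retained=space.n_retained,
        retained_fraction=space.retained_fraction,
        total_variance=space.total_variance,
    )


def load_shape_space(path) -> ShapeSpace:
    with np.load(path) as d:
        return ShapeSpace(
            mean=d["mean"],
            axes=d["axes"],
            variances=d["variances"],
            n_retained=int(d["n_retained"]),
            retained_fraction=float(d["retained_fraction"]),
            total_variance=float(d["total_variance"]),
        )
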