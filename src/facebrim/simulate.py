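"""Synthetic admixed cohorts with known latent facial effects.

Stands in for protected study data: individual ancestry proportions drawn
from a Beta mixture (admixture stratification), binary sex, SNP genotypes
binomial in ancestry-weighted parental allele frequencies, and a smooth
surface phenotype built as

    template + q * v_A + s * v_S + sum_j (g_j - 1) * v_Gj + noise + asymmetry

where the effect axes v are smooth bump displacement fields along the
template surface normals (localized or multi-region, mimicking principal
components that affect only particular parts of the face versus global
ones), the noise is a low-rank set of smooth correlated fields (the latent
covariance structure that response-based imputation exploits), and the
asymmetry term is an antisymmetric field exercising the symmetrization
stage.  Every draw is determined by the config seed.  Random rigid motions
and scale jitter are applied last so the Procrustes stage has real work to
do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._mesh import vertex_normals
from .mask import AnthropometricMask, make_mask_grid

__all__ = ["CohortConfig", "SyntheticCohort", "simulate_cohort", "simulate_aim_panel"]


# named template regions (x, y in mm, kernel width in mm) used to build
# smooth effect fields; off-midline regions are mirrored automatically
_REGIONS = {
    "nose": (0.0, 0.0, 18.0),
    "nose_wings": (12.0, 5.0, 12.0),
    "brow": (0.0, 45.0, 25.0),
    "lips": (0.0, -40.0, 15.0),
    "chin": (0.0, -75.0, 22.0),
    "cheeks": (35.0, -10.0, 22.0),
    "eyes": (25.0, 35.0, 12.0),
    "forehead": (0.0, 70.0, 30.0),
    "jaw": (40.0, -50.0, 25.0),
}

# default composition of the causal axes: ancestry and sex are multi-region
# ("global") effects, SNP axes are localized single regions
_ANCESTRY_REGIONS = (("nose", 1.0), ("nose_wings", 0.8), ("lips", 0.9), ("brow", 0.5))
_SEX_REGIONS = (("brow", 1.0), ("jaw", 0.8), ("cheeks", -0.6), ("chin", 0.7))
_SNP_REGIONS = ("nose", "lips", "eyes", "chin", "cheeks", "forehead", "jaw", "brow")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort (all lengths in mm).

    ``effect_*`` magnitudes are RMS per-landmark displacements of the unit
    effect fields; ``noise_magnitudes`` likewise, one per smooth noise field
    with independent standard-normal coefficients per individual.
    """

    n_individuals: int = 500
    grid_rows: int = 20
    grid_cols: int = 25
    ancestry_distribution: tuple = ((1 / 3, 2.0, 6.0), (1 / 3, 5.0, 5.0), (1 / 3, 6.0, 2.0))
    sex_ratio: float = 0.5
    n_snps: int = 4
    parental_freqs: tuple | None = None  # per SNP (p_parentA, p_parentB)
    effect_ancestry: float = 10.0
    effect_sex: float = 5.0
    effect_snps: tuple | None = None  # defaults to 1.5 mm each
    noise_magnitudes: tuple = tuple(1.8 * 0.95**i for i in range(60))
    asymmetry_magnitude: float = 1.0
    rigid_jitter: bool = True
    orthogonalize_axes: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows < 4 or self.grid_cols < 4:
            raise ValueError("grid needs at least 4 rows and columns")
        if self.parental_freqs is None:
            self.parental_freqs = tuple((0.8, 0.2) for _ in range(self.n_snps))
        if self.effect_snps is None:
            self.effect_snps = tuple(1.5 for _ in range(self.n_snps))
        if len(self.parental_freqs) != self.n_snps or len(self.effect_snps) != self.n_snps:
            raise ValueError("parental_freqs/effect_snps length must equal n_snps")
        for pa, pb in self.parental_freqs:
            if not (0 <= pa <= 1 and 0 <= pb <= 1):
                raise ValueError("allele frequencies must be in [0, 1]")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """A generated cohort with its latent ground truth recorded."""

    mask: AnthropometricMask
    configurations: np.ndarray  # (n, k, 3) mm
    ancestry_true: np.ndarray  # q in [0, 1]
    sex: np.ndarray  # 0 = male, 1 = female
    genotypes: np.ndarray  # (n, n_snps) additive counts {0, 1, 2}
    causal_axes: dict = field(default_factory=dict)  # name -> (k, 3) unit-RMS field
    asymmetry_field: np.ndarray | None = None
    asymmetry_coeffs: np.ndarray | None = None
    noise_fields: np.ndarray | None = None
    config: CohortConfig | None = None

    @property
    def n_individuals(self) -> int:
        return len(self.configurations)

    @property
    def ids(self) -> list:
        return [f"ind{i:04d}" for i in range(self.n_individuals)]


def _bump_field(
    mask: AnthropometricMask, regions, normals: np.ndarray
) -> np.ndarray:
    """Smooth displacement field along vertex normals from weighted regions."""
    tpl = mask.template
    f = np.zeros(len(tpl))
    for name, w in regions:
        xc, yc, s = _REGIONS[name]
        centers = [(xc, yc)] if xc == 0 else [(xc, yc), (-xc, yc)]
        for cx, cy in centers:
            d2 = (tpl[:, 0] - cx) ** 2 + (tpl[:, 1] - cy) ** 2
            f += w * np.exp(-0.5 * d2 / s**2)
    return f[:, None] * normals


def _similarity_tangent_basis(tpl: np.ndarray) -> np.ndarray:
    """Orthonormal basis (7, 3k) of the similarity-group tangent space at
    the template: rigid translations, infinitesimal rotations, and scaling."""
    k = len(tpl)
    c = tpl - tpl.mean(axis=0)
    gens = []
    for a in range(3):  # translations
        g = np.zeros((k, 3))
        g[:, a] = 1.0
        gens.append(g.ravel())
    for a in range(3):  # infinitesimal rotations about axis a
        e = np.zeros(3)
        e[a] = 1.0
        gens.append(np.cross(np.broadcast_to(e, (k, 3)), c).ravel())
    gens.append(c.ravel())  # scaling
    B = np.stack(gens)
    # Gram-Schmidt
    out = []
    for g in B:
        for o in out:
            g = g - (g @ o) * o
        nrm = np.linalg.norm(g)
        if nrm > 1e-12:
            out.append(g / nrm)
    return np.stack(out)


def _unit_rms(field_: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(np.sum(field_**2, axis=1)))
    if rms < 1e-300:
        raise ValueError("degenerate effect field")
    return field_ / rms


def _sample_ancestry(rng, mixture, n):
    weights = np.array([m[0] for m in mixture], dtype=float)
    weights /= weights.sum()
    comp = rng.choice(len(mixture), size=n, p=weights)
    q = np.empty(n)
    for i, (_, a, b) in enumerate(mixture):
        sel = comp == i
        q[sel] = rng.beta(a, b, size=sel.sum())
    return q


def _random_rotation(rng, max_angle: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle, max_angle)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one cohort; bit-identical output for identical configs."""
    rng = np.random.default_rng(config.seed)
    mask = make_mask_grid(config.grid_rows, config.grid_cols)
    tpl = mask.template
    k = mask.n_landmarks
    normals = vertex_normals(tpl, mask.triangles)

    # --- causal effect axes (unit RMS, optionally orthogonalized) ---
    raw = [
        _bump_field(mask, _ANCESTRY_REGIONS, normals),
        _bump_field(mask, _SEX_REGIONS, normals),
    ]
    names = ["ancestry", "sex"]
    for j in range(config.n_snps):
        region = _SNP_REGIONS[j % len(_SNP_REGIONS)]
        raw.append(_bump_field(mask, ((region, 1.0),), normals))
        names.append(f"snp{j}")
    flat = np.stack([f.ravel() for f in raw])
    # Superimposition removes the similarity-group tangent space at the
    # template (3 translations, 3 rotations, 1 scaling), so only the
    # component of an effect field orthogonal to those 7 directions is
    # identifiable as shape; without this projection any two outward bump
    # fields (which share net displacement and size components) become
    # negatively correlated after alignment and blend into a single
    # principal component.
    sim_basis = _similarity_tangent_basis(tpl)
    flat -= (flat @ sim_basis.T) @ sim_basis
    if config.orthogonalize_axes:
        for i in range(len(flat)):
            for jj in range(i):
                flat[i] -= (flat[i] @ flat[jj]) / (flat[jj] @ flat[jj]) * flat[jj]
    axes = {n: _unit_rms(f.reshape(k, 3)) for n, f in zip(names, flat)}

    # --- smooth correlated noise fields: random Gaussian bumps at random
    # mirrored centers, orthogonalized against the causal axes and against
    # one another so the covariance spectrum of the cohort is exactly the
    # prescribed (slowly decaying) magnitude sequence — emulating the rich,
    # gently decaying facial covariance structure that the imputation
    # iteration exploits ---
    n_noise = len(config.noise_magnitudes)
    noise_fields = np.empty((n_noise, k, 3))
    basis = list(sim_basis) + [a.ravel() for a in axes.values()]
    m = 0
    attempts = 0
    while m < n_noise:
        if attempts < 10:
            # smooth random bump field (mirrored for bilateral symmetry)
            f = np.zeros(k)
            for _ in range(3):
                xc = rng.uniform(0.0, 60.0)
                yc = rng.uniform(-80.0, 80.0)
                s = rng.uniform(10.0, 35.0)
                w = rng.normal()
                for cx in ({0.0} if xc == 0 else {xc, -xc}):
                    d2 = (tpl[:, 0] - cx) ** 2 + (tpl[:, 1] - yc) ** 2
                    f += w * np.exp(-0.5 * d2 / s**2)
            vec = (f[:, None] * normals).ravel()
        else:
            # the smooth-bump span is exhausted (coarse grids): complete the
            # basis with a white-noise vector field symmetrized under
            # reflect-and-relabel (spans the full bilateral subspace)
            w = rng.normal(size=(k, 3))
            mirror = mask.mirror_permutation
            w_ref = w[mirror].copy()
            w_ref[:, 0] *= -1.0
            vec = (0.5 * (w + w_ref)).ravel()
        pre = np.linalg.norm(vec)
        for b in basis:
            vec -= (vec @ b) / (b @ b) * b
        if np.linalg.norm(vec) < 1e-3 * pre:
            attempts += 1
            continue
        attempts = 0
        # re-symmetrize: orthogonalization only preserves bilateral symmetry
        # up to float error, which normalization would amplify
        fld = vec.reshape(k, 3)
        ref = fld[mask.mirror_permutation].copy()
        ref[:, 0] *= -1.0
        fld = 0.5 * (fld + ref)
        basis.append(fld.ravel())
        noise_fields[m] = _unit_rms(fld)
        m += 1

    # --- antisymmetric field (left-right contrast of a smooth bump);
    # like the other fields, only its similarity-orthogonal part survives
    # alignment, so project that part out up front ---
    asym = _bump_field(mask, (("cheeks", 1.0), ("eyes", 0.6)), normals)
    asym[tpl[:, 0] < 0] *= -1.0
    asym[tpl[:, 0] == 0] = 0.0
    avec = asym.ravel()
    avec = avec - (avec @ sim_basis.T) @ sim_basis
    asym = _unit_rms(avec.reshape(k, 3))

    # --- covariates and genotypes ---
    q = _sample_ancestry(rng, config.ancestry_distribution, config.n_individuals)
    sex = (rng.random(config.n_individuals) < config.sex_ratio).astype(int)
    pf = np.asarray(config.parental_freqs, dtype=float)
    freq = q[:, None] * pf[None, :, 0] + (1 - q[:, None]) * pf[None, :, 1]
    genotypes = rng.binomial(2, freq)

    # --- assemble configurations ---
    configs = np.broadcast_to(tpl, (config.n_individuals, k, 3)).copy()
    configs += q[:, None, None] * (config.effect_ancestry * axes["ancestry"])
    configs += sex[:, None, None] * (config.effect_sex * axes["sex"])
    for j in range(config.n_snps):
        configs += (
            (genotypes[:, j] - 1)[:, None, None]
            * config.effect_snps[j]
            * axes[f"snp{j}"]
        )
    noise_coeffs = rng.normal(size=(config.n_individuals, n_noise))
    for m in range(n_noise):
        configs += (
            noise_coeffs[:, m][:, None, None]
            * config.noise_magnitudes[m]
            * noise_fields[m]
        )
    asym_coeffs = rng.normal(size=config.n_individuals)
    configs += asym_coeffs[:, None, None] * config.asymmetry_magnitude * asym

    # self-intersection guard: a folded surface flips triangle orientations
    # relative to the template
    tri = mask.triangles
    ref_normals = np.cross(
        tpl[tri[:, 1]] - tpl[tri[:, 0]], tpl[tri[:, 2]] - tpl[tri[:, 0]]
    )
    p0, p1, p2 = configs[:, tri[:, 0]], configs[:, tri[:, 1]], configs[:, tri[:, 2]]
    new_normals = np.cross(p1 - p0, p2 - p0)
    flipped = np.einsum("ntj,tj->nt", new_normals, ref_normals) <= 0
    if flipped.any():
        warnings.warn(
            f"effect magnitudes fold the surface: {int(flipped.any(axis=1).sum())} "
            "of the generated configurations have flipped triangles",
            stacklevel=2,
        )

    if config.rigid_jitter:
        for i in range(config.n_individuals):
            rot = _random_rotation(rng, 0.15)
            scale = float(np.exp(rng.normal(0.0, 0.05)))
            trans = rng.normal(0.0, 10.0, size=3)
            configs[i] = scale * configs[i] @ rot.T + trans

    return SyntheticCohort(
        mask=mask,
        configurations=configs,
        ancestry_true=q,
        sex=sex,
        genotypes=genotypes,
        causal_axes=axes,
        asymmetry_field=asym,
        asymmetry_coeffs=asym_coeffs,
        noise_fields=noise_fields,
        config=config,
    )


def simulate_aim_panel(
    cohort: SyntheticCohort, n_markers: int, delta: float, seed: int
):
    """Independent ancestry-informative marker panel for an existing cohort.

    Each marker has parental allele frequencies (0.5 + delta/2, 0.5 - delta/2)
    and genotypes binomial in the individual's ancestry-weighted frequency.
    Returns (genotypes (n, m) additive counts, parental_freqs (m, 2)).
    Larger n_markers * delta^2 gives lower-variance ancestry estimates.
    """
    if not 0 < delta <= 1:
        raise ValueError("delta must be in (0, 1] (delta=0 is uninformative)")
    rng = np.random.default_rng(seed)
    pa, pb = 0.5 + delta / 2, 0.5 - delta / 2
    freqs = np.full((n_markers, 2), (pa, pb))
    q = cohort.ancestry_true
    f = q[:, None] * pa + (1 - q[:, None]) * pb
    genotypes = rng.binomial(2, np.broadcast_to(f, (len(q), n_markers)))
    return genotypes, freqs
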