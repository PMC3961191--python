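"""Association and validation statistics for RIP variables.

Genotype ANOVA on RIP-G, rank-based ROC/AUC for binary predictors,
maximum-likelihood individual ancestry from marker panels under a dihybrid
(two ancestral populations) model, and the robustness protocol: noise
injection into a continuous predictor, label misclassification, and
repeated BRIM runs across degradation levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from .brim import BRIMConfig, run_brim

__all__ = [
    "ANOVAResult",
    "RobustnessReport",
    "genotype_anova",
    "roc_auc",
    "ml_ancestry",
    "inject_noise",
    "calibrate_noise",
    "misclassify",
    "robustness_experiment",
]


@dataclass
class ANOVAResult:
    """One-way fixed-effects ANOVA of a RIP across genotype groups."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict
    trend_slope: float
    trend_p: float


def genotype_anova(rip: np.ndarray, genotypes: np.ndarray) -> ANOVAResult:
    """Test for mean RIP differences by genotype category (-1/0/+1 coding).

    Also reports the additive-trend regression of the RIP on the allele
    count coding and its p-value.
    """
    rip = np.asarray(rip, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    if rip.shape != g.shape:
        raise ValueError("rip and genotypes must be row-matched")
    levels = np.unique(g)
    groups = [rip[g == lv] for lv in levels]
    groups = [grp for grp in groups if len(grp) > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty genotype groups")

    grand = rip.mean()
    ss_between = sum(len(grp) * (grp.mean() - grand) ** 2 for grp in groups)
    ss_within = sum(((grp - grp.mean()) ** 2).sum() for grp in groups)
    df_b = len(groups) - 1
    df_w = len(rip) - len(groups)
    if df_w <= 0 or ss_within <= 0:
        raise ValueError("degenerate within-group variance")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))

    lr = sps.linregress(g, rip)
    return ANOVAResult(
        f_statistic=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        group_means={float(lv): float(rip[g == lv].mean()) for lv in levels},
        trend_slope=float(lr.slope),
        trend_p=float(lr.pvalue),
    )


def roc_auc(score: np.ndarray, labels: np.ndarray):
    """AUC by the rank (Mann-Whitney) statistic, ties averaged.

    Returns (auc, (fpr, tpr) curve points).  Invariant to strictly monotone
    transforms of the scores.
    """
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(score)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1)

    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, score)
    return float(auc), (fpr, tpr)


def _panel_loglik(q, g, pa, pb):
    f = np.clip(q * pa + (1 - q) * pb, 1e-12, 1 - 1e-12)
    return float(np.sum(g * np.log(f) + (2 - g) * np.log(1 - f)))


def ml_ancestry(genotypes: np.ndarray, parental_freqs: np.ndarray) -> np.ndarray:
    """Maximum-likelihood individual ancestry under two ancestral populations.

    For each individual, q-hat maximizes the binomial log-likelihood
    sum_j log Binom(g_j; 2, q*pA_j + (1-q)*pB_j) over q in [0, 1].
    Individuals with a flat likelihood (no informative markers) get 0.5 with
    a warning.
    """
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    pf = np.asarray(parental_freqs, dtype=float).reshape(-1, 2)
    if G.shape[1] != len(pf):
        raise ValueError("genotype columns must match marker count")
    pa, pb = pf[:, 0], pf[:, 1]
    informative = ~np.isclose(pa, pb)
    if not informative.any():
        warnings.warn("flat likelihood: no informative markers; returning 0.5",
                      stacklevel=2)
        return np.full(len(G), 0.5)
    # impossible genotypes: allele absent from both parental populations
    both_zero = (pa == 0) & (pb == 0)
    if np.any(both_zero & (G > 0).any(axis=0)):
        raise ValueError("observed allele at a marker with frequency 0 in both "
                         "parental populations")
    both_one = (pa == 1) & (pb == 1)
    if np.any(both_one & (G < 2).any(axis=0)):
        raise ValueError("missing allele at a marker fixed in both parental "
                         "populations")

    out = np.empty(len(G))
    for i, g in enumerate(G):
        res = minimize_scalar(
            lambda q: -_panel_loglik(q, g, pa, pb),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        out[i] = res.x
        # snap to the boundary when it is the true optimum
        for edge in (0.0, 1.0):
            if -_panel_loglik(edge, g, pa, pb) <= res.fun + 1e-12:
                out[i] = edge
    return out


def inject_noise(
    values: np.ndarray,
    c: float,
    seed: int = 0,
    valid_range: tuple | None = None,
):
    """Degrade a predictor: A' = A + c * sd(A) * eps, eps standard normal.

    The magnification constant c sets the injected noise level; larger c,
    lower correlation with the original.  Values are clipped to
    ``valid_range`` when given.  Returns (degraded, achieved_correlation).
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    a = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(len(a))
    noisy = a + c * a.std(ddof=1) * eps
    if valid_range is not None:
        noisy = np.clip(noisy, *valid_range)
    r = float(np.corrcoef(a, noisy)[0, 1]) if c > 0 else 1.0
    return noisy, r


def calibrate_noise(
    values: np.ndarray,
    target_r2: float,
    seed: int = 0,
    valid_range: tuple | None = None,
    tol: float = 0.02,
):
    """Find c so the degraded predictor hits a target r^2 with the original.

    Uses the closed-form start c0 = sqrt(1/r^2 - 1) (exact without
    clipping), then bisects on the achieved r^2 for the fixed noise draw.
    Returns (degraded, achieved_r2, c).
    """
    if not 0 < target_r2 <= 1:
        raise ValueError("target_r2 must be in (0, 1]")
    a = np.asarray(values, dtype=float)
    c0 = float(np.sqrt(1.0 / target_r2 - 1.0))

    def achieved(c):
        noisy, r = inject_noise(a, c, seed=seed, valid_range=valid_range)
        return noisy, r * r

    noisy, r2 = achieved(c0)
    lo, hi = 0.0, max(2 * c0, 1e-6)
    _, r2_hi = achieved(hi)
    while r2_hi > target_r2 and hi < 1e3:
        hi *= 2.0
        _, r2_hi = achieved(hi)
    c = c0
    for _ in range(60):
        if abs(r2 - target_r2) <= tol:
            break
        if r2 > target_r2:
            lo = c
        else:
            hi = c
        c = 0.5 * (lo + hi)
        noisy, r2 = achieved(c)
    return noisy, float(r2), float(c)


def misclassify(labels: np.ndarray, fraction: float, seed: int = 0) -> np.ndarray:
    """Flip exactly round(fraction * n) binary labels, chosen uniformly.

    Fractions above 0.5 are rejected (the label meaning would invert).
    """
    if not 0 <= fraction <= 0.5:
        raise ValueError("fraction must be in [0, 0.5]")
    lab = np.asarray(labels).astype(int).copy()
    n_flip = int(round(fraction * len(lab)))
    if n_flip:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(lab), size=n_flip, replace=False)
        lab[idx] = 1 - lab[idx]
    return lab


@dataclass
class RobustnessReport:
    """Per-level, per-iteration BRIM robustness summary."""

    levels: np.ndarray  # target r^2 levels or misclassification fractions
    kind: str  # "noise" | "misclassification"
    corr_with_clean_rip: np.ndarray  # (n_levels, n_iterations)
    corr_with_truth: np.ndarray  # (n_levels, n_iterations)
    auc_by_level: np.ndarray | None = None  # binary predictors only
    achieved: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_frame(self):
        import pandas as pd

        rows = []
        for li, lv in enumerate(self.levels):
            for it in range(self.corr_with_clean_rip.shape[1]):
                rows.append(
                    {
                        "level": lv,
                        "iteration": it + 1,
                        "corr_with_clean_rip": self.corr_with_clean_rip[li, it],
                        "corr_with_truth": self.corr_with_truth[li, it],
                        "auc": None
                        if self.auc_by_level is None
                        else self.auc_by_level[li, it],
                    }
                )
        return pd.DataFrame(rows)


def _iter_corrs(result, reference):
    out = np.full(result.per_iteration.shape[0], np.nan)
    for t, vals in enumerate(result.per_iteration):
        out[t] = np.corrcoef(vals, reference)[0, 1]
    return out


def robustness_experiment(
    predictor: np.ndarray,
    truth: np.ndarray,
    responses: np.ndarray,
    levels,
    config: BRIMConfig | None = None,
    kind: str = "noise",
    labels: np.ndarray | None = None,
    seed: int = 0,
    valid_range: tuple | None = None,
) -> RobustnessReport:
    """Run BRIM from degraded predictors across degradation levels.

    ``kind='noise'``: levels are target r^2 values of the degraded vs clean
    continuous predictor (noise injection with calibration).
    ``kind='misclassification'``: levels are flip fractions of a binary
    predictor; AUC of each iteration's RIP against the true labels is also
    recorded.  Correlations per iteration are reported against (a) the
    clean-predictor RIP at the same iteration and (b) the latent truth.
    """
    if config is None:
        config = BRIMConfig()
    predictor = np.asarray(predictor, dtype=float)
    truth = np.asarray(truth, dtype=float)
    levels = np.asarray(levels, dtype=float)

    clean = run_brim(predictor, responses, config=config)
    T = config.max_iterations
    n_levels = len(levels)
    corr_clean = np.full((n_levels, T), np.nan)
    corr_truth = np.full((n_levels, T), np.nan)
    auc = np.full((n_levels, T), np.nan) if kind == "misclassification" else None
    achieved = np.full(n_levels, np.nan)

    for li, lv in enumerate(levels):
        if kind == "noise":
            if lv >= 1.0:
                degraded, achieved[li] = predictor, 1.0
            else:
                degraded, achieved[li], _ = calibrate_noise(
                    predictor, lv, seed=seed + li, valid_range=valid_range
                )
        elif kind == "misclassification":
            flipped = misclassify(
                (labels if labels is not None else predictor).astype(int),
                lv,
                seed=seed + li,
            )
            degraded = flipped.astype(float)
            achieved[li] = lv
        else:
            raise ValueError("kind must be 'noise' or 'misclassification'")

        res = run_brim(degraded, responses, config=config)
        for t in range(res.per_iteration.shape[0]):
            tc = min(t, clean.per_iteration.shape[0] - 1)
            corr_clean[li, t] = np.corrcoef(
                res.per_iteration[t], clean.per_iteration[tc]
            )[0, 1]
            corr_truth[li, t] = np.corrcoef(res.per_iteration[t], truth)[0, 1]
            if auc is not None and labels is not None:
                auc[li, t], _ = roc_auc(res.per_iteration[t], labels)

    return RobustnessReport(
        levels=levels,
        kind=kind,
        corr_with_clean_rip=corr_clean,
        corr_with_truth=corr_truth,
        auc_by_level=auc,
        achieved=achieved,
    )
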