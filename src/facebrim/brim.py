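"""Bootstrapped response-based imputation modeling (BRIM).

BRIM refines an initial predictor variable (sex, genomic ancestry, or a SNP
genotype) using a multivariate response matrix (retained shape-space PC
scores).  In a leave-one-out forced imputation setup, a predictor->response
regression is fit on all individuals but one, and the left-out individual's
predictor value is re-imputed as the value whose predicted response is
closest (least squares) to the observed response.  Iterating — each round
imputes from the previous round's imputed values — yields the
response-based imputed predictor (RIP) variable.  Each fold's model may be
bagged over bootstrap resamples of its training rows.  Partial BRIM models
a genotype's effect conditional on RIP-A and RIP-S by carrying the
conditioning covariates inside the predictor block and inverting only the
genotype coordinate.

The forward regression is partial least squares (PLS); with the component
count equal to the predictor-block rank PLS coincides with ordinary least
squares, and the leave-one-out loop then uses an exact closed-form
normal-equation downdate instead of per-fold refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PredictorVariable",
    "BRIMConfig",
    "RIPResult",
    "PLSModel",
    "fit_pls",
    "impute_predictor_loo",
    "run_brim",
    "run_partial_brim",
    "rip_effect_maps",
    "EffectMaps",
]


@dataclass
class PredictorVariable:
    """An initial predictor: binary sex, ancestry proportion, or genotype.

    Genotypes use the additive coding -1/0/+1 (homozygote, heterozygote,
    homozygote).
    """

    values: np.ndarray
    kind: str = "continuous"  # binary | continuous | genotype
    name: str = "predictor"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.name}: non-finite predictor values")
        if self.kind not in ("binary", "continuous", "genotype"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.kind == "genotype" and not np.isin(v, (-1.0, 0.0, 1.0)).all():
            raise ValueError("genotype predictors must be coded -1/0/+1")
        self.values = v


@dataclass
class BRIMConfig:
    """Iteration, bootstrap, and convergence settings for one BRIM run."""

    n_components: int | str = "auto"
    max_iterations: int = 6
    tolerance: float = 1e-4  # stop when corr(iter t, t-1) >= 1 - tolerance
    n_bootstrap: int = 50  # resamples per leave-one-out fold; 0 = plain LOO
    n_worlds: int = 10  # cross-fitted nesting folds; 0 = unnested iteration
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0 < self.tolerance < 1:
            raise ValueError("tolerance must be in (0, 1)")
        if self.n_worlds < 0:
            raise ValueError("n_worlds must be >= 0")


@dataclass
class RIPResult:
    """A response-based imputed predictor with its iteration trace."""

    rip: np.ndarray
    per_iteration: np.ndarray  # (n_iter, n)
    convergence_trace: np.ndarray  # corr(iter t, iter t-1)
    initial_correlation_trace: np.ndarray  # corr(iter t, initial predictor)
    conditioning: tuple = ()
    name: str = "rip"

    @property
    def n_iterations(self) -> int:
        return len(self.per_iteration)


# ---------------------------------------------------------------------------
# forward PLS model


@dataclass
class PLSModel:
    """Linear predictor->response map: Y ~ intercept + X @ coef."""

    coef: np.ndarray  # (p, q)
    intercept: np.ndarray  # (q,)
    n_components: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.coef + self.intercept


def auto_components(X: np.ndarray, cap: int = 10, explained: float = 0.99) -> int:
    """Smallest component count explaining ``explained`` of the predictor-block
    covariance, capped at ``cap``.

    Computed on the standardized block (correlation scale) so the choice is
    invariant to the units of individual predictor columns; a column count
    is only dropped when columns are nearly collinear.
    """
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    Xc = Xc / np.where(sd < 1e-12, 1.0, sd)
    ev = np.linalg.svd(Xc, compute_uv=False) ** 2
    total = ev.sum()
    if total <= 0:
        return 1
    k = int(np.searchsorted(np.cumsum(ev), explained * total - 1e-12) + 1)
    return max(1, min(k, cap, X.shape[1]))


def fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a PLS (NIPALS) regression of responses on predictors.

    Components maximize predictor-response covariance; with ``n_components``
    equal to the predictor rank the fit coincides with ordinary least
    squares.  A constant predictor column raises; a component count above
    the rank is clipped with a warning; zero predictor-response covariance
    yields a zero coefficient map.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n != len(Y):
        raise ValueError("X and Y row counts differ")
    sd = X.std(axis=0)
    if np.any(sd < 1e-12):
        raise ValueError("constant predictor column")
    if n_components < 1 or n <= n_components:
        raise ValueError("need n > n_components >= 1")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds predictor rank {rank}; clipped",
            stacklevel=2,
        )
        n_components = rank
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    if np.linalg.norm(Xc.T @ Yc) < 1e-10 * max(1.0, np.linalg.norm(Xc)) * max(
        1.0, np.linalg.norm(Yc)
    ):
        return PLSModel(
            coef=np.zeros((p, Y.shape[1])), intercept=Y.mean(axis=0),
            n_components=n_components,
        )
    coef, intercept = _pls_coef(X, Y, n_components)
    return PLSModel(coef=coef, intercept=intercept, n_components=n_components)


def _pls_coef(X: np.ndarray, Y: np.ndarray, ncomp: int):
    """NIPALS PLS2 regression coefficients (coef (p, q), intercept (q,)).

    Matches the fitted linear map of :func:`fit_pls` (asserted in tests);
    used in the leave-one-out inner loop where per-fold estimator objects
    would dominate the runtime.
    """
    mx = X.mean(axis=0)
    my = Y.mean(axis=0)
    Xd = X - mx
    Yd = Y - my
    p = X.shape[1]
    W = np.empty((p, ncomp))
    P = np.empty((p, ncomp))
    Q = np.empty((Y.shape[1], ncomp))
    for a in range(ncomp):
        S = Xd.T @ Yd
        u, sv, _vt = np.linalg.svd(S, full_matrices=False)
        if sv[0] < 1e-14:
            W, P, Q = W[:, :a], P[:, :a], Q[:, :a]
            break
        w = u[:, 0]
        t = Xd @ w
        tt = t @ t
        if tt < 1e-24:
            W, P, Q = W[:, :a], P[:, :a], Q[:, :a]
            break
        p_ = Xd.T @ t / tt
        q_ = Yd.T @ t / tt
        Xd -= np.outer(t, p_)
        Yd -= np.outer(t, q_)
        W[:, a], P[:, a], Q[:, a] = w, p_, q_
    if W.shape[1] == 0:
        return np.zeros((p, Y.shape[1])), my.copy()
    R = W @ np.linalg.inv(P.T @ W)
    coef = R @ Q.T
    return coef, my - mx @ coef


# ---------------------------------------------------------------------------
# leave-one-out imputation


def _impute_from_model(coef, intercept, c_row, y_row, x_mean_fallback):
    """Closed-form inversion: project the response residual (conditioning
    held at observed values) onto the predictor effect direction."""
    b = coef[-1]
    denom = float(b @ b)
    if denom < 1e-24:
        return x_mean_fallback, True
    base = intercept + (c_row @ coef[:-1] if len(coef) > 1 else 0.0)
    return float((y_row - base) @ b) / denom, False


def _loo_closed_form(M, Y, x_col_index):
    """Exact leave-one-out OLS imputations via Sherman-Morrison downdates.

    M is the augmented design [1, conditioning, x]; returns per-individual
    imputed x plus a flag array marking degenerate (zero-effect) folds.
    """
    n, m = M.shape
    A = M.T @ M
    R = M.T @ Y
    Ainv = np.linalg.inv(A)
    beta_full = Ainv @ R  # (m, q)
    G = M @ Ainv  # row i = m_i^T Ainv
    h = np.einsum("ij,ij->i", G, M)  # leverages
    yhat = M @ beta_full  # (n, q)
    E = Y - yhat
    scale = E / (1.0 - h)[:, None]  # (n, q)

    u_last = G[:, x_col_index]
    b_full = beta_full[x_col_index]  # (q,)
    # per-fold effect direction b_i and conditional baseline base_i
    B = b_full[None, :] - u_last[:, None] * scale
    x = M[:, x_col_index]
    base_full = yhat - x[:, None] * b_full[None, :]
    t = h - x * u_last  # m_i(with x zeroed) . u_i
    base = base_full - t[:, None] * scale

    denom = np.einsum("ij,ij->i", B, B)
    numer = np.einsum("ij,ij->i", Y - base, B)
    # fallback: training-mean predictor for folds with a vanished effect
    sum_x = x.sum()
    fallback = (sum_x - x) / (n - 1)
    bad = denom < 1e-24
    out = np.where(bad, fallback, numer / np.maximum(denom, 1e-300))
    return out, bad


def _bootstrap_counts(rng, n, i, n_bootstrap):
    """Multinomial resample counts over the n-1 training rows of fold i."""
    train = np.concatenate([np.arange(i), np.arange(i + 1, n)])
    idx = rng.integers(0, n - 1, size=(n_bootstrap, n - 1))
    flat = (idx + (np.arange(n_bootstrap) * (n - 1))[:, None]).ravel()
    counts = np.bincount(flat, minlength=n_bootstrap * (n - 1)).reshape(
        n_bootstrap, n - 1
    )
    W = np.zeros((n_bootstrap, n))
    W[:, train] = counts
    return W


def _loo_bootstrap(M, Y, x_col_index, n_bootstrap, rng):
    """Per-fold bagged OLS imputations: each fold's model is refit on
    ``n_bootstrap`` resamples of its training rows and the imputations are
    averaged."""
    n, m = M.shape
    q = Y.shape[1]
    Mout = np.einsum("nj,nk->njk", M, M).reshape(n, m * m)
    MY = np.stack([M[:, j][:, None] * Y for j in range(m)], axis=1)  # (n, m, q)
    MYflat = MY.reshape(n, m * q)
    out = np.empty(n)
    any_bad = False
    for i in range(n):
        W = _bootstrap_counts(rng, n, i, n_bootstrap)
        A = (W @ Mout).reshape(n_bootstrap, m, m)
        R = (W @ MYflat).reshape(n_bootstrap, m, q)
        # ridge-free solve; singular resamples (degenerate draws) get a tiny
        # jitter on the diagonal
        try:
            beta = np.linalg.solve(A, R)
        except np.linalg.LinAlgError:
            A = A + 1e-8 * np.eye(m)[None]
            beta = np.linalg.solve(A, R)
        b = beta[:, x_col_index, :]  # (B, q)
        m_i0 = M[i].copy()
        x_i = m_i0[x_col_index]
        m_i0[x_col_index] = 0.0
        base = np.einsum("j,bjq->bq", m_i0, beta)
        denom = np.einsum("bq,bq->b", b, b)
        numer = np.einsum("q,bq->b", Y[i], b) - np.einsum("bq,bq->b", base, b)
        good = denom > 1e-24
        if not np.any(good):
            out[i] = (M[:, x_col_index].sum() - x_i) / (n - 1)
            any_bad = True
        else:
            out[i] = float(np.mean(numer[good] / denom[good]))
    return out, any_bad


def impute_predictor_loo(
    predictor,
    responses: np.ndarray,
    conditioning: np.ndarray | None = None,
    n_components: int | str = "auto",
    n_bootstrap: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Leave-one-out forced imputation of a predictor from responses.

    For each individual the forward model is fit on everyone else (with the
    conditioning covariates, if any, inside the predictor block) and the
    individual's predictor value is imputed as the least-squares inversion
    of the forward map at their observed response, conditioning covariates
    fixed at their observed values.  Row i is never used to fit fold i.
    """
    x = predictor.values if isinstance(predictor, PredictorVariable) else np.asarray(
        predictor, dtype=float
    )
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(x)
    if Y.shape[0] != n:
        raise ValueError("responses not row-matched to predictor")
    if n < 10:
        raise ValueError("need at least 10 individuals for leave-one-out BRIM")
    if x.std() < 1e-12:
        raise ValueError("constant predictor")
    C = None
    if conditioning is not None and np.size(conditioning):
        C = np.atleast_2d(np.asarray(conditioning, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("conditioning not row-matched to predictor")
    block = x[:, None] if C is None else np.column_stack([C, x])
    p = block.shape[1]
    ncomp = auto_components(block) if n_components == "auto" else int(n_components)
    ncomp = min(ncomp, p)

    if ncomp >= p:
        # full-rank PLS == OLS: exact closed-form leave-one-out
        M = np.column_stack([np.ones(n), block])
        if rng is None:
            rng = np.random.default_rng(0)
        if n_bootstrap > 0:
            out, bad = _loo_bootstrap(M, Y, M.shape[1] - 1, n_bootstrap, rng)
            if bad:
                warnings.warn(
                    "some bootstrap folds had a numerically zero effect "
                    "direction; fold-mean predictor imputed",
                    stacklevel=2,
                )
        else:
            out, badmask = _loo_closed_form(M, Y, M.shape[1] - 1)
            if badmask.any():
                warnings.warn(
                    f"{int(badmask.sum())} folds had a numerically zero effect "
                    "direction; fold-mean predictor imputed",
                    stacklevel=2,
                )
        return out

    # reduced-rank PLS path: per-fold refits with the in-house NIPALS core
    if rng is None:
        rng = np.random.default_rng(0)
    out = np.empty(n)
    warned = False
    c_row = np.empty(0)
    for i in range(n):
        sel = np.arange(n) != i
        train = np.flatnonzero(sel)
        if C is not None:
            c_row = C[i]
        fallback = float(x[sel].mean())
        if n_bootstrap > 0:
            vals = []
            for _ in range(n_bootstrap):
                tr = train[rng.integers(0, n - 1, size=n - 1)]
                coef, intercept = _pls_coef(block[tr], Y[tr], ncomp)
                v, bad = _impute_from_model(coef, intercept, c_row, Y[i], fallback)
                if not bad:
                    vals.append(v)
            out[i] = np.mean(vals) if vals else fallback
        else:
            coef, intercept = _pls_coef(block[sel], Y[sel], ncomp)
            out[i], bad = _impute_from_model(coef, intercept, c_row, Y[i], fallback)
            if bad and not warned:
                warnings.warn("zero effect direction; fold-mean imputed", stacklevel=2)
                warned = True
    return out


def _fit_and_impute(
    block_tr: np.ndarray,
    Y_tr: np.ndarray,
    C_eval: np.ndarray | None,
    Y_eval: np.ndarray,
    ncomp: int,
    n_bootstrap: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fit the forward model on training rows (optionally bagged over
    bootstrap resamples) and impute the predictor for held-out rows."""
    n_tr, p = block_tr.shape
    q = Y_tr.shape[1]
    n_ev = len(Y_eval)
    m = p + 1
    M = np.column_stack([np.ones(n_tr), block_tr])
    if C_eval is not None and np.size(C_eval):
        Me0 = np.column_stack([np.ones(n_ev), C_eval, np.zeros(n_ev)])
    else:
        Me0 = np.column_stack([np.ones(n_ev), np.zeros(n_ev)])

    if ncomp >= p:
        if n_bootstrap > 0:
            idx = rng.integers(0, n_tr, size=(n_bootstrap, n_tr))
            flat = (idx + (np.arange(n_bootstrap) * n_tr)[:, None]).ravel()
            W = np.bincount(flat, minlength=n_bootstrap * n_tr).reshape(
                n_bootstrap, n_tr
            ).astype(float)
            Mout = np.einsum("nj,nk->njk", M, M).reshape(n_tr, m * m)
            MY = np.stack([M[:, j][:, None] * Y_tr for j in range(m)], axis=1)
            A = (W @ Mout).reshape(n_bootstrap, m, m)
            R = (W @ MY.reshape(n_tr, m * q)).reshape(n_bootstrap, m, q)
            try:
                betas = np.linalg.solve(A, R)
            except np.linalg.LinAlgError:
                betas = np.linalg.solve(A + 1e-8 * np.eye(m)[None], R)
        else:
            A = M.T @ M
            betas = np.linalg.solve(A, M.T @ Y_tr)[None]
    else:
        coefs = []
        if n_bootstrap > 0:
            for _ in range(n_bootstrap):
                rows = rng.integers(0, n_tr, size=n_tr)
                coef, inter = _pls_coef(block_tr[rows], Y_tr[rows], ncomp)
                coefs.append(np.vstack([inter, coef]))
        else:
            coef, inter = _pls_coef(block_tr, Y_tr, ncomp)
            coefs.append(np.vstack([inter, coef]))
        betas = np.stack(coefs)

    b = betas[:, -1, :]  # (B, q) effect direction per resample
    base = np.einsum("ej,bjq->beq", Me0, betas)  # (n_ev, B, q)
    den = np.einsum("bq,bq->b", b, b)
    num = np.einsum("eq,bq->eb", Y_eval, b) - np.einsum("beq,bq->eb", base, b)
    good = den > 1e-24
    fallback = float(block_tr[:, -1].mean())
    if not good.any():
        return np.full(n_ev, fallback)
    vals = num[:, good] / den[good]
    return vals.mean(axis=1)


# ---------------------------------------------------------------------------
# the BRIM iteration


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-300 or nb < 1e-300:
        return 0.0
    return float(a @ b / (na * nb))


def run_brim(
    predictor,
    responses: np.ndarray,
    config: BRIMConfig | None = None,
    conditioning: np.ndarray | None = None,
    conditioning_labels: tuple = (),
    conditioning_mode: str = "joint",
) -> RIPResult:
    """Iterate leave-one-out response-based imputation to convergence.

    Iteration 1 imputes from the initial predictor; iteration t uses
    iteration t-1's imputed values.  Stops when the correlation between
    successive iterations reaches 1 - tolerance, or at ``max_iterations``.
    ``conditioning_mode='joint'`` keeps covariates inside the predictor
    block (only the target coordinate is inverted);
    ``'residualize'`` instead regresses the responses on the covariates
    once, up front, and runs plain BRIM on the residuals.
    """
    if config is None:
        config = BRIMConfig()
    pv = (
        predictor
        if isinstance(predictor, PredictorVariable)
        else PredictorVariable(values=np.asarray(predictor, dtype=float))
    )
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if len(Y) != len(pv.values):
        raise ValueError("responses not row-matched to predictor")

    C = conditioning
    if conditioning_mode == "residualize" and C is not None and np.size(C):
        Cm = np.column_stack([np.ones(len(Y)), np.atleast_2d(np.asarray(C, float))])
        coef, *_ = np.linalg.lstsq(Cm, Y, rcond=None)
        Y = Y - Cm @ coef
        C = None
    elif conditioning_mode not in ("joint", "residualize"):
        raise ValueError("conditioning_mode must be 'joint' or 'residualize'")

    rng = np.random.default_rng(config.seed)
    x0 = pv.values
    n = len(x0)
    if C is not None and np.size(C):
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != n:
            C = C.T
    else:
        C = None

    def orth(values, cond):
        # remove the span of [1, conditioning] from an imputation vector so
        # the RIP's association with the conditioning covariates is zero by
        # construction and successive predictors stay in their complement
        if cond is None:
            return values
        Cm = np.column_stack([np.ones(len(values)), cond])
        coef, *_ = np.linalg.lstsq(Cm, values, rcond=None)
        return values - Cm @ coef

    # resolve the PLS component count once, on the full predictor block
    full_block = x0[:, None] if C is None else np.column_stack([C, x0])
    ncomp = (
        auto_components(full_block)
        if config.n_components == "auto"
        else min(int(config.n_components), full_block.shape[1])
    )

    # nesting: K cross-fitted worlds; individual i's imputation at every
    # iteration comes from models fit on a world that excludes i entirely,
    # so no row's response ever leaks into its own RIP value ("nested
    # leave-one-out"); small samples fall back to the unnested iteration
    K = min(config.n_worlds, n // 20)
    nested = K >= 2
    if nested:
        fold_id = np.arange(n) % K
        train_rows = [fold_id != w for w in range(K)]
        Z = [x0[t].copy() for t in train_rows]

    current = x0
    per_iteration = []
    conv = []
    init_corr = []
    for _t in range(config.max_iterations):
        if nested:
            # each world imputes the whole cohort; worlds are affinely
            # aligned to their mean vector (each world's inversion has its
            # own scale, and unaligned folds would add fold-structured
            # artifacts to the assembled RIP); individual i's value is taken
            # from the world that excludes i entirely
            I = np.empty((K, n))
            for w in range(K):
                tr = train_rows[w]
                C_tr = C[tr] if C is not None else None
                block_tr = (
                    Z[w][:, None] if C is None else np.column_stack([C_tr, Z[w]])
                )
                I[w] = _fit_and_impute(
                    block_tr, Y[tr], C, Y, ncomp, config.n_bootstrap, rng
                )
                Z[w] = orth(
                    impute_predictor_loo(
                        Z[w],
                        Y[tr],
                        conditioning=C_tr,
                        n_components=ncomp,
                        n_bootstrap=config.n_bootstrap,
                        rng=rng,
                    ),
                    C_tr,
                )
            Ibar = I.mean(axis=0)
            new = np.empty(n)
            for w in range(K):
                A = np.column_stack([np.ones(n), I[w]])
                ab, *_ = np.linalg.lstsq(A, Ibar, rcond=None)
                ev = ~train_rows[w]
                new[ev] = ab[0] + ab[1] * I[w][ev]
            new = orth(new, C)
        else:
            new = orth(
                impute_predictor_loo(
                    current,
                    Y,
                    conditioning=C,
                    n_components=ncomp,
                    n_bootstrap=config.n_bootstrap,
                    rng=rng,
                ),
                C,
            )
        if not np.all(np.isfinite(new)):
            bad = np.flatnonzero(~np.isfinite(new))
            raise RuntimeError(
                f"non-finite imputations at iteration {_t + 1}, folds {bad[:10]}"
            )
        per_iteration.append(new)
        conv.append(_corr(new, current))
        init_corr.append(_corr(new, x0))
        current = new
        if conv[-1] >= 1.0 - config.tolerance:
            break

    return RIPResult(
        rip=current,
        per_iteration=np.asarray(per_iteration),
        convergence_trace=np.asarray(conv),
        initial_correlation_trace=np.asarray(init_corr),
        conditioning=tuple(conditioning_labels),
        name=f"RIP-{pv.name}" if pv.name != "predictor" else "rip",
    )


def run_partial_brim(
    genotype,
    responses: np.ndarray,
    rip_a: RIPResult,
    rip_s: RIPResult,
    config: BRIMConfig | None = None,
    conditioning_mode: str = "joint",
) -> RIPResult:
    """Partial BRIM: genotype effects independent of ancestry and sex.

    Runs BRIM for the genotype predictor while conditioning on the RIP-A and
    RIP-S variables (which outperform raw genomic ancestry and recorded sex
    as conditioning covariates), yielding RIP-G with its association to the
    conditioning variables removed.
    """
    pv = (
        genotype
        if isinstance(genotype, PredictorVariable)
        else PredictorVariable(values=np.asarray(genotype, float), kind="genotype",
                               name="G")
    )
    n = len(pv.values)
    if len(rip_a.rip) != n or len(rip_s.rip) != n:
        raise ValueError("RIP-A/RIP-S cohort sizes do not match the genotype")
    C = np.column_stack([rip_a.rip, rip_s.rip])
    if config is None:
        config = BRIMConfig()
    if config.n_components == "auto":
        # partialling requires the full predictor-block rank: with fewer
        # components than conditioning covariates, the covariate directions
        # mix into the genotype effect instead of being held fixed
        from dataclasses import replace as _replace

        config = _replace(config, n_components=3)
    return run_brim(
        pv,
        responses,
        config=config,
        conditioning=C,
        conditioning_labels=("RIP-A", "RIP-S"),
        conditioning_mode=conditioning_mode,
    )


# ---------------------------------------------------------------------------
# effect maps


@dataclass
class EffectMaps:
    """Per-landmark effect summary of a RIP on the aligned shapes."""

    r2: np.ndarray  # per landmark, pooled over x/y/z
    slopes: np.ndarray  # (3k,) per-coordinate regression slope on the RIP
    shape_minus: np.ndarray  # (k, 3)
    shape_plus: np.ndarray  # (k, 3)
    k_sd: float = 3.0


def rip_effect_maps(rip, shapes, center: np.ndarray | None = None, k: float = 3.0
                    ) -> EffectMaps:
    """Regress each landmark coordinate on a RIP variable.

    ``shapes`` is (n, 3k) (e.g. symmetric Procrustes shapes) or an
    AlignedSample whose symmetric components are used.  Per landmark the R^2
    pools the regression and total sums of squares of its three coordinates.
    The returned transformations are center ± k * SD(rip) along the
    per-coordinate slope field.
    """
    from .morphometry import AlignedSample, symmetric_components

    r = np.asarray(rip.rip if isinstance(rip, RIPResult) else rip, dtype=float)
    if isinstance(shapes, AlignedSample):
        sample = shapes
        if sample.includes_reflections:
            S, _ = symmetric_components(sample)
        else:
            S = sample.shapes
        if center is None:
            center = sample.consensus
    else:
        S = np.asarray(shapes, dtype=float)
    if center is None:
        center = S.mean(axis=0)
    if len(S) != len(r):
        raise ValueError("rip not row-matched to shapes")
    sd_r = r.std(ddof=1)
    if sd_r < 1e-12:
        raise ValueError("zero-variance RIP")

    rc = r - r.mean()
    Sc = S - S.mean(axis=0)
    sxx = float(rc @ rc)
    slopes = (rc @ Sc) / sxx  # (3k,)
    reg_ss = slopes**2 * sxx
    tot_ss = (Sc**2).sum(axis=0)
    kland = S.shape[1] // 3
    reg_l = reg_ss.reshape(kland, 3).sum(axis=1)
    tot_l = tot_ss.reshape(kland, 3).sum(axis=1)
    r2 = np.divide(reg_l, tot_l, out=np.zeros(kland), where=tot_l > 0)

    lo = (np.asarray(center) - k * sd_r * slopes).reshape(kland, 3)
    hi = (np.asarray(center) + k * sd_r * slopes).reshape(kland, 3)
    return EffectMaps(r2=r2, slopes=slopes, shape_minus=lo, shape_plus=hi, k_sd=k)
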