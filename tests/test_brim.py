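"""Response-based imputation: PLS forward model, leave-one-out inversion,
the iterated (nested) BRIM scheme, and effect maps."""

import numpy as np
import pytest

import facebrim as fb
from facebrim.brim import (
    _impute_from_model,
    _pls_coef,
    auto_components,
    impute_predictor_loo,
)


# ---------------------------------------------------------------------------
# forward PLS model


def test_pls_exact_line():
    x = np.linspace(-2, 2, 20)[:, None]
    y = 2.0 * x
    m = fb.fit_pls(x, y, 1)
    assert abs(m.coef[0, 0] - 2.0) < 1e-10
    assert abs(m.intercept[0]) < 1e-10


def test_pls_full_rank_equals_ols():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 3))
    Y = rng.normal(size=(40, 5))
    m = fb.fit_pls(X, Y, 3)
    M = np.column_stack([np.ones(40), X])
    beta, *_ = np.linalg.lstsq(M, Y, rcond=None)
    assert np.abs(m.coef - beta[1:]).max() < 1e-8
    assert np.abs(m.intercept - beta[0]).max() < 1e-8


def test_pls_zero_covariance_gives_zero_coef():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(40, 1))
    Y = rng.normal(size=(40, 5))
    xc = x - x.mean()
    Y = Y - xc * (xc.T @ Y) / (xc.T @ xc)  # exactly orthogonal responses
    m = fb.fit_pls(x, Y, 1)
    assert np.linalg.norm(m.coef) < 1e-8


def test_pls_constant_column_rejected():
    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(20), rng.normal(size=20)])
    with pytest.raises(ValueError, match="constant"):
        fb.fit_pls(X, rng.normal(size=(20, 2)), 2)


def test_pls_component_clip_warns():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(20, 1))
    X = np.column_stack([x, 2 * x])  # rank 1
    with pytest.warns(UserWarning, match="clipped"):
        fb.fit_pls(X, rng.normal(size=(20, 3)), 2)


def test_pls_reduced_rank_matches_sklearn():
    """The in-house NIPALS core agrees with scikit-learn's PLSRegression
    (which stops its inner power iteration at tol=1e-6, hence the loose
    comparison)."""
    from sklearn.cross_decomposition import PLSRegression

    rng = np.random.default_rng(5)
    X = rng.normal(size=(50, 4)) @ np.diag([1.0, 2.0, 3.0, 4.0])
    Y = rng.normal(size=(50, 6))
    for nc in (1, 2, 3):
        coef, intercept = _pls_coef(X, Y, nc)
        ref = PLSRegression(n_components=nc, scale=False).fit(X, Y)
        assert np.abs(coef - ref.coef_.T).max() < 1e-3
        pred_ref = ref.predict(X)
        pred = X @ coef + intercept
        assert np.abs(pred - pred_ref).max() < 1e-3


def test_auto_components_unit_invariant():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(100, 3))
    scaled = X * np.array([1.0, 1e-3, 1e3])
    assert auto_components(X) == auto_components(scaled) == 3


# ---------------------------------------------------------------------------
# leave-one-out imputation


def test_loo_exact_inversion_noiseless():
    rng = np.random.default_rng(7)
    x = rng.normal(size=30)
    b = rng.normal(size=8)
    xh = impute_predictor_loo(x, np.outer(x, b))
    assert np.abs(xh - x).max() < 1e-8


def test_inversion_rejects_orthogonal_noise_given_model():
    """With the effect direction known, response noise orthogonal to it
    leaves the imputation exact."""
    rng = np.random.default_rng(8)
    b = rng.normal(size=5)
    x = rng.normal(size=12)
    W = rng.normal(size=(12, 5))
    W -= np.outer(W @ b, b) / (b @ b)
    for i in range(12):
        v, bad = _impute_from_model(
            b[None, :], np.zeros(5), np.empty(0), x[i] * b + W[i], 0.0
        )
        assert not bad
        assert abs(v - x[i]) < 1e-8


@pytest.mark.parametrize("with_conditioning", [False, True])
def test_loo_matches_grid_search_oracle(with_conditioning):
    """Each imputed value matches a dense grid search over candidate
    predictor values minimizing the squared response distance."""
    rng = np.random.default_rng(9)
    n, q = 30, 8
    x = rng.normal(size=n)
    b = rng.normal(size=q)
    C = rng.normal(size=(n, 2)) if with_conditioning else None
    Y = np.outer(x, b) + rng.normal(0, 0.5, size=(n, q))
    if with_conditioning:
        Y += C @ rng.normal(size=(2, q))
    xh = impute_predictor_loo(x, Y, conditioning=C, n_components=3 if with_conditioning else 1)

    grid = np.arange(-4, 4, 1e-4)
    for i in range(0, n, 7):
        sel = np.arange(n) != i
        cols = [np.ones(n - 1)]
        if with_conditioning:
            cols.append(C[sel])
        cols.append(x[sel])
        M = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(M, Y[sel], rcond=None)
        base = beta[0] + (C[i] @ beta[1:3] if with_conditioning else 0.0)
        pred = base[None, :] + grid[:, None] * beta[-1][None, :]
        best = grid[np.argmin(((Y[i][None, :] - pred) ** 2).sum(axis=1))]
        assert abs(best - xh[i]) < 1e-4 + 1e-4


def test_loo_honesty_explicit_refit():
    """Fold i's imputation equals the closed-form inversion of a model fit
    on all-but-i: row i is never used in its own fold."""
    rng = np.random.default_rng(10)
    n, q = 25, 6
    x = rng.normal(size=n)
    Y = np.outer(x, rng.normal(size=q)) + rng.normal(0, 0.3, size=(n, q))
    xh = impute_predictor_loo(x, Y)
    for i in (0, 11, 24):
        sel = np.arange(n) != i
        M = np.column_stack([np.ones(n - 1), x[sel]])
        beta, *_ = np.linalg.lstsq(M, Y[sel], rcond=None)
        v = (Y[i] - beta[0]) @ beta[1] / (beta[1] @ beta[1])
        assert abs(v - xh[i]) < 1e-10


def test_loo_zero_effect_falls_back_to_fold_mean():
    rng = np.random.default_rng(11)
    x = rng.normal(size=20)
    Y = np.zeros((20, 4))  # degenerate responses: zero effect direction
    with pytest.warns(UserWarning, match="zero effect"):
        xh = impute_predictor_loo(x, Y)
    expected = (x.sum() - x) / (len(x) - 1)
    assert np.abs(xh - expected).max() < 1e-10


def test_loo_input_validation():
    rng = np.random.default_rng(12)
    with pytest.raises(ValueError, match="at least 10"):
        impute_predictor_loo(rng.normal(size=5), rng.normal(size=(5, 3)))
    with pytest.raises(ValueError, match="constant"):
        impute_predictor_loo(np.ones(20), rng.normal(size=(20, 3)))
    with pytest.raises(ValueError, match="row-matched"):
        impute_predictor_loo(rng.normal(size=20), rng.normal(size=(19, 3)))


# ---------------------------------------------------------------------------
# the BRIM iteration


def _toy_responses(rng, n=120, q=10, effect=3.0):
    x = rng.normal(size=n)
    B = rng.normal(size=q)
    B /= np.linalg.norm(B)
    Y = effect * np.outer(x, B) + rng.normal(size=(n, q))
    return x, Y


def test_brim_affine_equivariance():
    """Replacing the initial predictor x by a*x+b maps every iteration's
    imputed values by the same affine map; correlation traces unchanged."""
    rng = np.random.default_rng(13)
    x, Y = _toy_responses(rng)
    cfg = fb.BRIMConfig(n_bootstrap=20, seed=5, max_iterations=4)
    r1 = fb.run_brim(x, Y, cfg)
    r2 = fb.run_brim(3.0 * x - 2.0, Y, cfg)
    assert np.abs(3.0 * r1.per_iteration - 2.0 - r2.per_iteration).max() < 1e-8
    assert np.abs(r1.convergence_trace - r2.convergence_trace).max() < 1e-10


def test_brim_deterministic_under_seed():
    rng = np.random.default_rng(14)
    x, Y = _toy_responses(rng)
    cfg = fb.BRIMConfig(n_bootstrap=15, seed=9, max_iterations=3)
    r1 = fb.run_brim(x, Y, cfg)
    r2 = fb.run_brim(x, Y, cfg)
    assert np.array_equal(r1.per_iteration, r2.per_iteration)


def test_brim_final_iteration_is_rip():
    rng = np.random.default_rng(15)
    x, Y = _toy_responses(rng)
    res = fb.run_brim(x, Y, fb.BRIMConfig(n_bootstrap=0, seed=0))
    assert np.array_equal(res.rip, res.per_iteration[-1])
    assert np.abs(res.convergence_trace).max() <= 1.0


def test_brim_no_signal_control():
    """A predictor independent of the responses yields a RIP whose
    correlation with the latent truth stays below the 99% permutation null
    quantile."""
    rng = np.random.default_rng(16)
    n = 80
    truth = rng.normal(size=n)
    Y = rng.normal(size=(n, 8))  # responses carry no trace of the predictor
    res = fb.run_brim(truth, Y, fb.BRIMConfig(n_bootstrap=0, seed=1))
    observed = abs(np.corrcoef(res.rip, truth)[0, 1])
    null = []
    for _ in range(200):
        null.append(abs(np.corrcoef(res.rip, rng.permutation(truth))[0, 1]))
    assert observed < np.quantile(null, 0.99)


def test_brim_genotype_coding_validated():
    with pytest.raises(ValueError, match="-1/0"):
        fb.PredictorVariable(np.array([0.0, 1.0, 2.0]), kind="genotype")


def test_brim_noise_robustness_mechanism(small_cohort, small_aligned, small_shape_space):
    """RIPs seeded from a degraded ancestry predictor correlate more strongly
    with the clean predictor than with the degraded values used to seed them
    (the headline error-correcting property)."""
    sym, space = small_shape_space
    Y = fb.scores(space, sym)
    clean = small_cohort.ancestry_true
    noisy, r2, _ = fb.calibrate_noise(clean, 0.7, seed=99, valid_range=(0, 1))
    cfg = fb.BRIMConfig(n_bootstrap=0, seed=3)
    res = fb.run_brim(noisy, Y, cfg)
    assert abs(np.corrcoef(res.rip, clean)[0, 1]) > abs(np.corrcoef(res.rip, noisy)[0, 1])


def test_partial_brim_orthogonal_to_conditioning(small_cohort, small_shape_space):
    sym, space = small_shape_space
    Y = fb.scores(space, sym)
    cfg = fb.BRIMConfig(n_bootstrap=0, seed=4)
    rip_a = fb.run_brim(small_cohort.ancestry_true, Y, cfg)
    rip_s = fb.run_brim(small_cohort.sex.astype(float), Y, cfg)
    g = small_cohort.genotypes[:, 0].astype(float) - 1
    rip_g = fb.run_partial_brim(g, Y, rip_a, rip_s, cfg)
    assert abs(np.corrcoef(rip_g.rip, rip_a.rip)[0, 1]) < 0.1
    assert abs(np.corrcoef(rip_g.rip, rip_s.rip)[0, 1]) < 0.1
    assert rip_g.conditioning == ("RIP-A", "RIP-S")


def test_partial_brim_size_mismatch(small_cohort, small_shape_space):
    sym, space = small_shape_space
    Y = fb.scores(space, sym)
    cfg = fb.BRIMConfig(n_bootstrap=0, seed=4)
    rip_a = fb.run_brim(small_cohort.ancestry_true, Y, cfg)
    rip_s = fb.run_brim(small_cohort.sex.astype(float), Y, cfg)
    with pytest.raises(ValueError, match="sizes"):
        fb.run_partial_brim(np.zeros(10), Y, rip_a, rip_s, cfg)


# ---------------------------------------------------------------------------
# effect maps


def test_effect_map_exact_linear_landmark():
    rng = np.random.default_rng(17)
    n, k = 100, 6
    rip = rng.normal(size=n)
    shapes = rng.normal(size=(n, 3 * k))
    shapes[:, 0:3] = rip[:, None] * np.array([1.0, -2.0, 0.5])
    maps = fb.rip_effect_maps(rip, shapes, k=3)
    assert maps.r2[0] == pytest.approx(1.0)


def test_effect_map_null_landmark_r2_small():
    rng = np.random.default_rng(18)
    n, k = 500, 4
    rip = rng.normal(size=n)
    shapes = rng.normal(size=(n, 3 * k))
    maps = fb.rip_effect_maps(rip, shapes, k=3)
    assert maps.r2.max() < 0.03


def test_effect_map_matches_per_landmark_regression():
    rng = np.random.default_rng(19)
    n, k = 60, 5
    rip = rng.normal(size=n)
    shapes = rng.normal(size=(n, 3 * k)) + np.outer(rip, rng.normal(size=3 * k))
    maps = fb.rip_effect_maps(rip, shapes, k=3)
    rc = rip - rip.mean()
    Sc = shapes - shapes.mean(axis=0)
    for l in range(k):
        reg = tot = 0.0
        for c in range(3):
            y = Sc[:, 3 * l + c]
            slope = (rc @ y) / (rc @ rc)
            reg += slope**2 * (rc @ rc)
            tot += y @ y
        assert abs(maps.r2[l] - reg / tot) < 1e-10


def test_effect_map_transformations_span_sd():
    rng = np.random.default_rng(20)
    n, k = 80, 4
    rip = rng.normal(size=n)
    shapes = np.outer(rip, rng.normal(size=3 * k)) + 0.1 * rng.normal(size=(n, 3 * k))
    maps = fb.rip_effect_maps(rip, shapes, k=2.5)
    span = (maps.shape_plus - maps.shape_minus).ravel()
    expected = 2 * 2.5 * rip.std(ddof=1) * maps.slopes
    assert np.abs(span - expected).max() < 1e-10


def test_effect_map_zero_variance_rip():
    with pytest.raises(ValueError, match="zero-variance"):
        fb.rip_effect_maps(np.ones(30), np.random.default_rng(0).normal(size=(30, 6)))
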