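"""Unit tests for the PPCCA model: EM fit, likelihood, BIC selection."""

import numpy as np
import pytest
from scipy import linalg, stats

import explobatch as eb
from explobatch.ppcca import _marginal_loglik

from conftest import intercept_only, make_expression


def closed_form_ppca(Y: np.ndarray, q: int):
    """Independent oracle: the eigendecomposition ML solution of
    probabilistic PCA (isotropic noise, no covariates)."""
    n, p = Y.shape
    Yc = Y - Y.mean(axis=0)
    S = Yc.T @ Yc / n
    ev, V = linalg.eigh(S)
    ev, V = ev[::-1], V[:, ::-1]
    sigma2 = ev[q:].mean()
    W = V[:, :q] * np.sqrt(ev[:q] - sigma2)
    C = W @ W.T + sigma2 * np.eye(p)
    ll = -n / 2 * (p * np.log(2 * np.pi) + np.linalg.slogdet(C)[1]
                   + np.trace(np.linalg.solve(C, S)))
    return ll, sigma2


@pytest.mark.parametrize("n,p,q,seed", [(20, 5, 2, 0), (50, 30, 3, 1)])
def test_intercept_only_matches_closed_form_ppca(n, p, q, seed):
    rng = np.random.default_rng(seed)
    Y = rng.standard_normal((n, q)) @ rng.standard_normal((q, p)) \
        + 0.5 * rng.standard_normal((n, p))
    fit = eb.fit_ppcca(make_expression(Y), intercept_only(n), q)
    ll, sigma2 = closed_form_ppca(Y, q)
    assert abs(fit.loglik - ll) < 1e-6
    assert abs(fit.sigma2 - sigma2) < 1e-6


def test_mu_is_column_means(correlated_expression, two_batch_design):
    fit = eb.fit_ppcca(correlated_expression, two_batch_design, 2)
    np.testing.assert_array_equal(fit.mu,
                                  correlated_expression.values.mean(axis=0))


def test_em_loglik_monotone(correlated_expression, two_batch_design):
    fit = eb.fit_ppcca(correlated_expression, two_batch_design, 2)
    assert fit.converged
    assert np.all(np.diff(fit.loglik_trace) >= -1e-10)


def test_loglik_matches_dense_gaussian(rng):
    Y = rng.standard_normal((10, 4))
    em = make_expression(Y)
    X = eb.build_design(["a"] * 5 + ["b"] * 5)
    fit = eb.fit_ppcca(em, X, 2)
    mean = fit.mu + (X.values @ fit.beta.T) @ fit.W.T
    C = fit.W @ fit.W.T + fit.sigma2 * np.eye(4)
    dense = sum(stats.multivariate_normal.logpdf(Y[i], mean[i], C)
                for i in range(10))
    assert abs(eb.log_likelihood(fit, em, X) - dense) < 1e-8


def test_loglik_standard_normal_closed_form():
    # W=0, beta=0, sigma2=1, mu=0, y=0: each row contributes -p/2*log(2pi)
    ll = _marginal_loglik(np.zeros((1, 2)), np.ones((1, 1)),
                          np.zeros((2, 1)), np.zeros(2), np.zeros((1, 1)), 1.0)
    assert np.isclose(ll, -np.log(2 * np.pi))


def test_duplicating_samples_doubles_loglik(correlated_expression,
                                            two_batch_design):
    fit = eb.fit_ppcca(correlated_expression, two_batch_design, 2)
    ll1 = eb.log_likelihood(fit, correlated_expression, two_batch_design)
    Y2 = make_expression(np.vstack([correlated_expression.values] * 2))
    X2 = eb.DesignMatrix(np.vstack([two_batch_design.values] * 2),
                         two_batch_design.column_names,
                         two_batch_design.column_blocks)
    assert np.isclose(eb.log_likelihood(fit, Y2, X2), 2 * ll1, atol=1e-9)


def test_rotation_invariance(correlated_expression, two_batch_design, rng):
    fit = eb.fit_ppcca(correlated_expression, two_batch_design, 2)
    R = linalg.qr(rng.standard_normal((2, 2)))[0]
    rotated = eb.PPCCAFit(
        W=fit.W @ R, mu=fit.mu, beta=R.T @ fit.beta, sigma2=fit.sigma2,
        scores=fit.scores @ R, q=2, loglik=fit.loglik, bic=fit.bic,
        n_params=fit.n_params, converged=True, n_iter=fit.n_iter)
    ll0 = eb.log_likelihood(fit, correlated_expression, two_batch_design)
    ll1 = eb.log_likelihood(rotated, correlated_expression, two_batch_design)
    assert abs(ll0 - ll1) < 1e-8
    np.testing.assert_allclose(rotated.W @ rotated.W.T, fit.W @ fit.W.T,
                               atol=1e-8)


def test_bic_arithmetic():
    assert np.isclose(eb.bic_score(-100.0, 10, 50),
                      2 * (-100.0) - 10 * np.log(50))


def test_bic_penalty_prefers_smaller_model():
    assert eb.bic_score(-100.0, 10, 50) > eb.bic_score(-100.0, 12, 50)


def test_select_q_recovers_true_dimension():
    ds = eb.simulate(eb.SimulationConfig(
        n_per_batch=(75, 75), p=40, q_true=3, loading_scale=(1.6, 1.2, 0.9),
        sigma2=1.0, seed=7))
    sel = eb.select_q(ds.Y, intercept_only(150), range(1, 7))
    assert sel.q_opt == 3
    assert sel.bics[sel.q_candidates.index(3)] == sel.bics.max()


def test_select_q_tie_breaks_to_smaller_q(monkeypatch, correlated_expression):
    import explobatch.ppcca as ppcca_mod

    def fake_fit(Y, X, q, opts=None):
        return eb.PPCCAFit(W=np.zeros((Y.n_genes, q)), mu=np.zeros(Y.n_genes),
                           beta=np.zeros((q, 1)), sigma2=1.0,
                           scores=np.zeros((Y.n_samples, q)), q=q,
                           loglik=-10.0, bic=-42.0, n_params=q,
                           converged=True, n_iter=1)

    monkeypatch.setattr(ppcca_mod, "fit_ppcca", fake_fit)
    sel = ppcca_mod.select_q(correlated_expression,
                             intercept_only(correlated_expression.n_samples),
                             [2, 3, 4])
    assert sel.q_opt == 2


def test_beta_recovery_within_three_se():
    cfg = eb.SimulationConfig(n_per_batch=(100, 100), p=30, q_true=2,
                              batch_beta=[[2.0], [-2.0]],
                              loading_scale=(1.3, 0.8), seed=11)
    ds = eb.simulate(cfg)
    X = ds.truth.design
    fit = eb.fit_ppcca(ds.Y, X, 2)
    se = eb.estimate_se(ds.Y, X, 2, fit=fit)
    perm, signs = eb.align_components(ds.truth.W, fit.W)
    beta = fit.beta[perm] * signs[:, None]
    col = X.block_columns("batch")[0]
    for k in range(2):
        assert abs(beta[k, col] - ds.truth.beta[k, col]) < 3 * se[perm][k, col]


# --- validation / error contracts -----------------------------------------

def test_rejects_nonfinite_expression():
    vals = np.ones((4, 3)); vals[1, 2] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        make_expression(vals)


def test_rejects_q_out_of_range(correlated_expression):
    X = intercept_only(20)
    with pytest.raises(ValueError, match="q must satisfy"):
        eb.fit_ppcca(correlated_expression, X, 5)
    with pytest.raises(ValueError, match="q must satisfy"):
        eb.fit_ppcca(correlated_expression, X, 0)


def test_rank_deficient_design_names_columns():
    n = 12
    vals = np.column_stack([np.ones(n),
                            [0] * 6 + [1] * 6,
                            [0] * 6 + [1] * 6])
    with pytest.raises(ValueError, match="rank-deficient"):
        eb.DesignMatrix(vals, ("intercept", "batch[b]", "tissue[t]"),
                        {"batch": (1,), "tissue": (2,)})


def test_nonconvergence_warns(correlated_expression, two_batch_design):
    with pytest.warns(RuntimeWarning, match="did not converge"):
        fit = eb.fit_ppcca(correlated_expression, two_batch_design, 2,
                           eb.FitOptions(max_iter=1, tol=0.0))
    assert not fit.converged


def test_empty_q_range_rejected(correlated_expression):
    with pytest.raises(ValueError, match="empty"):
        eb.select_q(correlated_expression, intercept_only(20), [])
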