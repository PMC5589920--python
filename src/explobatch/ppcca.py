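"""Probabilistic principal component and covariates analysis (PPCCA).

The model couples a probabilistic PCA observation layer with a linear
regression of the latent scores on sample-level covariates::

    y_i = W u_i + mu + xi_i,        xi_i  ~ MVN_p(0, sigma2 * I)
    u_i = beta x_i + eps_i,         eps_i ~ MVN_q(0, I)

so that marginally ``y_i | x_i ~ MVN_p(W beta x_i + mu, W W^T + sigma2 I)``.
Here ``Y`` is an n x p expression matrix (samples x genes, log scale),
``X`` an n x l design matrix (intercept plus dummy-coded covariates such as
batch membership), ``W`` a p x q loadings matrix, and ``beta`` a q x l
coefficient matrix quantifying how each covariate shifts each probabilistic
principal component (pPC) score, in latent-score units.

Fitting is by EM on the marginal likelihood; the number of components q is
chosen by maximising a larger-is-better BIC, ``2*loglik - n_params*log(n)``.

All likelihood evaluations go through the q-dimensional Woodbury /
matrix-determinant-lemma form, never through a dense p x p factorisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ExpressionMatrix",
    "DesignMatrix",
    "FitOptions",
    "PPCCAFit",
    "ModelSelectionResult",
    "build_design",
    "fit_ppcca",
    "log_likelihood",
    "bic_score",
    "n_parameters",
    "select_q",
    "align_components",
]

SIGMA2_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """Samples x genes matrix of (already normalised, log-scale) expression.

    Parameters
    ----------
    values
        n x p float array, finite everywhere.
    sample_ids, gene_ids
        Unique row / column identifiers aligned with ``values``.
    """

    values: np.ndarray
    sample_ids: tuple
    gene_ids: tuple

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("expression values must be a 2-D samples x genes matrix")
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[:5]
            raise ValueError(
                f"expression matrix contains non-finite entries, e.g. at {bad.tolist()}"
            )
        n, p = vals.shape
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if p < 2:
            raise ValueError(f"need at least 2 genes, got {p}")
        sids = tuple(str(s) for s in self.sample_ids)
        gids = tuple(str(g) for g in self.gene_ids)
        if len(sids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(gids) != p:
            raise ValueError("gene_ids length does not match number of columns")
        if len(set(sids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(gids)) != p:
            dup = sorted({g for g in gids if gids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dup[:10]}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", sids)
        object.__setattr__(self, "gene_ids", gids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), tuple(df.index), tuple(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.gene_ids))

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same identifiers, new values (shape-checked)."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("replacement values have a different shape")
        return ExpressionMatrix(values, self.sample_ids, self.gene_ids)


@dataclass(frozen=True)
class DesignMatrix:
    """Covariate design: intercept plus dummy-coded categorical blocks.

    ``column_blocks`` maps a covariate name (e.g. ``"batch"``) to the indices
    of its columns in ``values``; a categorical covariate with g levels
    contributes g-1 dummy columns (reference level dropped).
    """

    values: np.ndarray
    column_names: tuple
    column_blocks: Mapping[str, tuple]
    reference_levels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("design values must be 2-D")
        if not np.all(np.isfinite(vals)):
            raise ValueError("design matrix contains non-finite entries")
        if not np.allclose(vals[:, 0], 1.0):
            raise ValueError("first design column must be an all-ones intercept")
        names = tuple(str(c) for c in self.column_names)
        if len(names) != vals.shape[1]:
            raise ValueError("column_names length does not match design width")
        _check_full_rank(vals, names)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "column_names", names)
        object.__setattr__(
            self, "column_blocks",
            {k: tuple(int(i) for i in v) for k, v in self.column_blocks.items()},
        )

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def block_columns(self, name: str) -> tuple:
        if name not in self.column_blocks:
            raise KeyError(f"no covariate block named {name!r}; "
                           f"have {sorted(self.column_blocks)}")
        return self.column_blocks[name]


def _check_full_rank(values: np.ndarray, names: Sequence[str]) -> None:
    """Reject a rank-deficient design, naming the dependent columns."""
    n, l = values.shape
    if n < l:
        raise ValueError(f"design has more columns ({l}) than rows ({n})")
    _, r, piv = linalg.qr(values, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(values.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < l:
        offenders = sorted(names[j] for j in piv[rank:])
        raise ValueError(
            "design matrix is rank-deficient (confounded covariates); "
            f"linearly dependent columns: {offenders}"
        )


def build_design(
    batch: Sequence,
    covariates: Mapping[str, Sequence] | None = None,
    reference: str | None = None,
) -> DesignMatrix:
    """Intercept + batch dummies + optional extra covariate columns.

    Categorical covariates are dummy-coded 0/1 with the first level in sorted
    order as the dropped reference (overridable for batch via ``reference``);
    numeric covariates are z-scaled.
    """
    batch = pd.Series(list(batch), dtype="object").astype(str)
    n = len(batch)
    cols = [np.ones(n)]
    names = ["intercept"]
    blocks: dict = {}
    refs: dict = {}

    def add_categorical(name: str, labels: pd.Series, ref: str | None):
        levels = sorted(labels.unique())
        if len(levels) < 2:
            raise ValueError(f"covariate {name!r} has a single level {levels}")
        if ref is None:
            ref = levels[0]
        elif ref not in levels:
            raise ValueError(f"reference level {ref!r} not among levels of {name!r}")
        idx = []
        for lev in levels:
            if lev == ref:
                continue
            idx.append(len(names))
            names.append(f"{name}[{lev}]")
            cols.append((labels == lev).to_numpy(float))
        blocks[name] = tuple(idx)
        refs[name] = ref

    add_categorical("batch", batch, reference)
    for name, vals in (covariates or {}).items():
        ser = pd.Series(list(vals))
        if len(ser) != n:
            raise ValueError(f"covariate {name!r} length {len(ser)} != n = {n}")
        if pd.api.types.is_numeric_dtype(ser):
            x = ser.to_numpy(float)
            sd = x.std()
            if sd == 0:
                raise ValueError(f"numeric covariate {name!r} is constant")
            blocks[name] = (len(names),)
            names.append(name)
            cols.append((x - x.mean()) / sd)
        else:
            add_categorical(name, ser.astype(str), None)

    return DesignMatrix(np.column_stack(cols), tuple(names), blocks, refs)


@dataclass(frozen=True)
class FitOptions:
    """EM controls.

    Convergence uses Aitken acceleration: with per-iteration ratio
    ``c_t = (l_t - l_{t-1}) / (l_{t-1} - l_{t-2})``, the asymptotic
    log-likelihood is projected as ``l_inf = l_{t-1} + (l_t - l_{t-1})/(1 - c_t)``
    and EM stops once ``|l_inf - l_t| < tol * (1 + |l_t|)``. Unlike a raw
    per-step change rule, this does not stop early when EM converges slowly
    (small steps, large remaining climb).

    ``init`` is either ``"eigen"`` (deterministic start from the sample
    covariance eigendecomposition) or a warm-start triple
    ``(W0, beta0, sigma2_0)``.
    """

    max_iter: int = 2000
    tol: float = 1e-7
    init: object = "eigen"


@dataclass(frozen=True)
class PPCCAFit:
    """Maximum-likelihood PPCCA fit and the posterior pPC scores."""

    W: np.ndarray           # p x q loadings
    mu: np.ndarray          # p mean vector (column means of Y)
    beta: np.ndarray        # q x l covariate coefficients, latent-score units
    sigma2: float           # isotropic residual variance
    scores: np.ndarray      # n x q posterior means E[u_i | y_i, x_i]
    q: int
    loglik: float
    bic: float
    n_params: int
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class ModelSelectionResult:
    q_candidates: tuple
    bics: np.ndarray
    logliks: np.ndarray
    q_opt: int
    fits: Mapping[int, PPCCAFit] | None = None

    @property
    def best_fit(self) -> PPCCAFit | None:
        return None if self.fits is None else self.fits[self.q_opt]


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _marginal_loglik(Y: np.ndarray, X: np.ndarray, W: np.ndarray,
                     mu: np.ndarray, beta: np.ndarray, sigma2: float) -> float:
    """sum_i log MVN_p(y_i; W beta x_i + mu, W W^T + sigma2 I).

    Uses the Woodbury identity and matrix determinant lemma so the cost is
    O(n p q + q^3) regardless of p.
    """
    n, p = Y.shape
    q = W.shape[1]
    D = Y - mu - (X @ beta.T) @ W.T          # n x p residuals from the marginal mean
    M = W.T @ W + sigma2 * np.eye(q)
    L = linalg.cholesky(M, lower=True)
    T = linalg.solve_triangular(L, (D @ W).T, lower=True)   # q x n
    quad = (np.einsum("ij,ij->", D, D) - np.einsum("ij,ij->", T, T)) / sigma2
    logdet = (p - q) * np.log(sigma2) + 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (n * p * np.log(2.0 * np.pi) + n * logdet + quad)


def log_likelihood(fit: PPCCAFit, Y: ExpressionMatrix, X: DesignMatrix) -> float:
    """Marginal log-likelihood of ``Y`` given ``X`` under a fitted model."""
    yv, xv = Y.values, X.values
    if yv.shape[0] != xv.shape[0]:
        raise ValueError("Y and X have different numbers of samples")
    if fit.W.shape[0] != yv.shape[1]:
        raise ValueError("fit dimension p does not match Y")
    if fit.beta.shape[1] != xv.shape[1]:
        raise ValueError("fit dimension l does not match X")
    return _marginal_loglik(yv, xv, fit.W, fit.mu, fit.beta, fit.sigma2)


def n_parameters(p: int, q: int, l: int) -> int:
    """Free-parameter count: mu (p) + sigma2 (1) + beta (q*l) + rotation-
    corrected loadings (p*q - q*(q-1)/2)."""
    return p + 1 + q * l + (p * q - q * (q - 1) // 2)


def bic_score(loglik: float, n_params: int, n: int) -> float:
    """Larger-is-better BIC: ``2*loglik - n_params*log(n)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 * loglik - n_params * np.log(n)


# ---------------------------------------------------------------------------
# EM fit
# ---------------------------------------------------------------------------

def _eigen_init(Yc: np.ndarray, q: int):
    """Deterministic start: probabilistic-PCA closed form of the centred data.

    W0 = U_q (lambda_q - sigma2_0)^{1/2}, sigma2_0 = mean of the discarded
    sample-covariance eigenvalues (ML convention, divisor n).
    """
    n, p = Yc.shape
    _, s, Vt = linalg.svd(Yc, full_matrices=False)
    ev = np.zeros(p)
    ev[: s.size] = s**2 / n                  # eigenvalues of S = Yc'Yc/n
    sigma2 = float(np.mean(ev[q:])) if p > q else SIGMA2_FLOOR
    sigma2 = max(sigma2, SIGMA2_FLOOR)
    scale = np.sqrt(np.maximum(ev[:q] - sigma2, 0.0))
    W0 = Vt[:q].T * scale
    return W0, sigma2


def fit_ppcca(Y: ExpressionMatrix, X: DesignMatrix, q: int,
              opts: FitOptions = FitOptions()) -> PPCCAFit:
    """Fit the PPCCA model with q components by EM.

    Returns ML estimates of (W, mu, beta, sigma2) together with posterior
    score means ``E[u_i | y_i, x_i] = M^{-1} (W'(y_i - mu) + sigma2 beta x_i)``
    where ``M = W'W + sigma2 I``. ``mu`` is fixed at the column means of Y
    (its MLE: the design's intercept absorbs any latent-space offset).
    The log-likelihood is non-decreasing across iterations.
    """
    yv, xv = Y.values, X.values
    n, p = yv.shape
    l = xv.shape[1]
    if xv.shape[0] != n:
        raise ValueError("design matrix rows do not align with expression rows")
    if not (1 <= q < min(n, p)):
        raise ValueError(f"q must satisfy 1 <= q < min(n, p) = {min(n, p)}; got {q}")

    mu = yv.mean(axis=0)
    Yc = yv - mu
    XtX = xv.T @ xv
    yss = float(np.einsum("ij,ij->", Yc, Yc))

    if isinstance(opts.init, str):
        if opts.init != "eigen":
            raise ValueError(f"unknown init strategy {opts.init!r}")
        W, sigma2 = _eigen_init(Yc, q)
        # beta0: OLS of the initial posterior-style scores on X
        M = W.T @ W + sigma2 * np.eye(q)
        U0 = linalg.solve(M, (Yc @ W).T, assume_a="pos").T
        beta = linalg.solve(XtX, xv.T @ U0, assume_a="pos").T
    else:
        W0, beta0, s20 = opts.init
        W = np.array(W0, dtype=float, copy=True)
        beta = np.array(beta0, dtype=float, copy=True)
        sigma2 = float(s20)
        if W.shape != (p, q) or beta.shape[1] != l:
            raise ValueError("warm-start parameter shapes do not match the data")

    Iq = np.eye(q)
    trace = [_marginal_loglik(yv, xv, W, mu, beta, sigma2)]
    converged = False
    floored = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        # E-step
        M = W.T @ W + sigma2 * Iq
        Minv = linalg.inv(M)
        U = (Yc @ W + sigma2 * (xv @ beta.T)) @ Minv          # n x q posterior means
        Suu = n * sigma2 * Minv + U.T @ U                     # sum_i E[u_i u_i']
        # M-step
        CyU = Yc.T @ U                                        # p x q
        W = linalg.solve(Suu, CyU.T, assume_a="pos").T
        sigma2 = (yss - float(np.einsum("ij,ij->", CyU, W))) / (n * p)
        if sigma2 < SIGMA2_FLOOR:
            sigma2 = SIGMA2_FLOOR
            floored = True
        beta = linalg.solve(XtX, xv.T @ U, assume_a="pos").T
        trace.append(_marginal_loglik(yv, xv, W, mu, beta, sigma2))
        if len(trace) >= 3:
            step, prev = trace[-1] - trace[-2], trace[-2] - trace[-3]
            if prev > 0:
                c = step / prev
                gap = step / (1.0 - c) if 0.0 < c < 1.0 else step
            else:
                gap = step
            if abs(gap) < opts.tol * (1.0 + abs(trace[-1])):
                converged = True
                break

    if floored:
        warnings.warn("residual variance hit its numerical floor; the data may be "
                      "degenerate (rank-deficient or noiseless)", RuntimeWarning)
    if not converged:
        warnings.warn(f"EM did not converge within {opts.max_iter} iterations",
                      RuntimeWarning)

    # Pin the rotational gauge: (W, beta) are identified only up to W -> WR,
    # beta -> R'beta, which leaves the likelihood untouched. Report the
    # principal-axes representative so per-component coefficients are
    # well-defined quantities a Wald test can address.
    W, beta = _canonicalize(W, beta)
    M = W.T @ W + sigma2 * Iq
    scores = (Yc @ W + sigma2 * (xv @ beta.T)) @ linalg.inv(M)
    loglik = trace[-1]
    k = n_parameters(p, q, l)
    return PPCCAFit(
        W=W, mu=mu, beta=beta, sigma2=float(sigma2), scores=scores, q=q,
        loglik=float(loglik), bic=float(bic_score(loglik, k, n)), n_params=k,
        converged=converged, n_iter=it, loglik_trace=np.asarray(trace),
    )


def select_q(Y: ExpressionMatrix, X: DesignMatrix,
             q_range: Sequence[int] | None = None,
             opts: FitOptions = FitOptions(),
             keep_fits: bool = True) -> ModelSelectionResult:
    """Fit every candidate q and select the BIC maximiser.

    Candidates default to ``1..min(10, n-2, p-1)``. Each candidate is fitted
    independently, so the result does not depend on evaluation order. Exact
    BIC ties resolve to the smaller q (parsimony).
    """
    n, p = Y.values.shape
    if q_range is None:
        q_range = range(1, min(10, n - 2, p - 1) + 1)
    qs = sorted(set(int(q) for q in q_range))
    if not qs:
        raise ValueError("q_range is empty")
    if qs[0] < 1 or qs[-1] >= min(n, p):
        raise ValueError(f"q_range must lie within [1, {min(n, p) - 1}]")

    fits = {q: fit_ppcca(Y, X, q, opts) for q in qs}
    bics = np.array([fits[q].bic for q in qs])
    logliks = np.array([fits[q].loglik for q in qs])
    q_opt = qs[int(np.argmax(bics))]         # first max -> smallest q on ties
    return ModelSelectionResult(
        q_candidates=tuple(qs), bics=bics, logliks=logliks, q_opt=q_opt,
        fits=fits if keep_fits else None,
    )


def _canonicalize(W: np.ndarray, beta: np.ndarray):
    """Rotate (W, beta) to the principal-axes gauge.

    With ``W = P S Q'`` (thin SVD), right-multiplying W by Q gives orthogonal
    loading columns ordered by decreasing strength; beta transforms
    contragradiently so that ``W beta`` (the gene-space covariate shift) and
    ``W W'`` are unchanged. Column signs are fixed by making each column's
    largest-magnitude loading positive, so the representative is
    deterministic.
    """
    P, s, Qt = linalg.svd(W, full_matrices=False)
    Wc = P * s
    bc = Qt @ beta
    flip = np.sign(Wc[np.argmax(np.abs(Wc), axis=0), np.arange(Wc.shape[1])])
    flip[flip == 0] = 1.0
    return Wc * flip, bc * flip[:, None]


# ---------------------------------------------------------------------------
# Component alignment (used by resampling SEs and simulation oracles)
# ---------------------------------------------------------------------------

def align_components(W_ref: np.ndarray, W: np.ndarray):
    """Match the columns of ``W`` to those of ``W_ref``.

    Components of two fits (or a fit and a generating truth) are identified
    only up to order and sign; this resolves both by maximising absolute
    Pearson correlation between loading columns via optimal assignment.

    Returns ``(perm, signs)`` such that ``W[:, perm] * signs`` aligns with
    ``W_ref``. A coefficient matrix realigns as ``beta[perm] * signs[:, None]``
    and scores as ``U[:, perm] * signs``.
    """
    A = W_ref - W_ref.mean(axis=0)
    B = W - W.mean(axis=0)
    A = A / np.maximum(np.linalg.norm(A, axis=0), 1e-300)
    B = B / np.maximum(np.linalg.norm(B, axis=0), 1e-300)
    C = A.T @ B                                   # q_ref x q correlations
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.empty_like(cols)
    perm[rows] = cols
    signs = np.sign(C[rows, cols])[np.argsort(rows)]
    signs[signs == 0] = 1.0
    return perm, signs
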