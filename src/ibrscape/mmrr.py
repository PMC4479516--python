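"""Multiple matrix regression with randomization (MMRR).

A genetic-distance matrix is regressed on one or more predictor distance
matrices after unfolding each to its lower triangle and z-scoring the
vectors, so coefficients are standardized and comparable across
predictors measured on wildly different scales.  Because matrix entries
are not independent, parametric t/F inference is invalid; significance
comes from jointly permuting the rows and columns of the response matrix
(the predictors stay fixed) and recomputing t and F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix, unfold


@dataclass
class MMRRResult:
    """Standardized coefficients with permutation significance."""

    r_squared: float
    coefficients: dict[str, float]
    tstats: dict[str, float]
    pvalues: dict[str, float]
    intercept: float
    f_stat: float
    f_pvalue: float
    n_perm: int
    seed: int | None = None
    df_resid: int = 0
    predictor_names: list[str] = field(default_factory=list)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant vector cannot be standardized")
    return (v - v.mean()) / sd


def _ols_t_f(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float, np.ndarray, float]:
    """OLS of y on [1, x]: (betas, r2, tstats, F)."""
    m, k = x.shape
    design = np.column_stack([np.ones(m), x])
    xtx = design.T @ design
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ design.T @ y
    resid = y - design @ beta
    ssr = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    dfr = m - k - 1
    sigma2 = ssr / dfr if dfr > 0 else np.nan
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 1e-300))
    t = beta / se
    f = (r2 / k) / ((1 - r2) / dfr) if (1 - r2) > 0 else np.inf
    return beta, r2, t, f


def mmrr_fit(
    Y: DistanceMatrix,
    Xs: list[DistanceMatrix],
    n_perm: int = 10_000,
    seed: int | None = None,
    names: list[str] | None = None,
) -> MMRRResult:
    """Fit MMRR of a response distance matrix on predictor matrices.

    All matrices must share labels; pairs with non-finite values in any
    matrix (e.g. disconnected resistance pairs) are dropped.  With a
    single predictor, R² is exactly the squared Pearson correlation of
    the unfolded vectors.
    """
    if not Xs:
        raise ValueError("need at least one predictor matrix")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = Y.labels
    if names is None:
        names = [f"X{i + 1}" if x.kind is None else x.kind for i, x in enumerate(Xs)]
        if len(set(names)) != len(names):
            names = [f"X{i + 1}" for i in range(len(Xs))]
    y_vec = unfold(Y)
    if not np.isfinite(y_vec).all():
        raise ValueError("response matrix must be finite")
    x_vecs = [unfold(x, labels) for x in Xs]
    finite = np.isfinite(y_vec)
    for v in x_vecs:
        finite &= np.isfinite(v)
    if not finite.all():
        import warnings

        warnings.warn(
            f"{int((~finite).sum())} pairs with non-finite distances dropped"
        )
    x = np.column_stack([_zscore(v[finite]) for v in x_vecs])
    # collinearity guard before fitting
    if x.shape[1] > 1:
        corr = np.corrcoef(x, rowvar=False)
        cond = np.linalg.cond(x.T @ x)
        if cond > 1e10:
            iu = np.triu_indices(x.shape[1], k=1)
            worst = np.argmax(np.abs(corr[iu]))
            i, j = iu[0][worst], iu[1][worst]
            raise ValueError(
                f"collinear predictors: {names[i]!r} and {names[j]!r} "
                f"(condition number {cond:.3g})"
            )
    y = _zscore(y_vec[finite])
    beta, r2, t, f = _ols_t_f(y, x)
    rng = np.random.default_rng(seed)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    exceed_t = np.zeros(len(Xs))
    exceed_f = 0
    yv = Y.values
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = yv[np.ix_(perm, perm)][iu][finite]
        ypz = _zscore(yp)
        _, _, t_p, f_p = _ols_t_f(ypz, x)
        exceed_t += np.abs(t_p[1:]) >= np.abs(t[1:]) - 1e-12
        if f_p >= f - 1e-12:
            exceed_f += 1
    pvals = (1 + exceed_t) / (n_perm + 1)
    return MMRRResult(
        r_squared=r2,
        coefficients=dict(zip(names, beta[1:].tolist())),
        tstats=dict(zip(names, t[1:].tolist())),
        pvalues=dict(zip(names, pvals.tolist())),
        intercept=float(beta[0]),
        f_stat=float(f),
        f_pvalue=(1 + exceed_f) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
        df_resid=int(finite.sum()) - len(Xs) - 1,
        predictor_names=list(names),
    )
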