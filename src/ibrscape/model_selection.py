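"""Weighted GLMs, AICc ranking and model averaging of diversity predictors.

Genetic-diversity responses (allelic richness, gene diversity) are
modelled as normal-error GLMs of up to four site-level predictors:
proportion of suitable habitat around the site, mean pairwise F_ST with
all other populations (isolation), latitude and longitude.  All 2^4
predictor subsets (including intercept-only) are fitted, ranked by the
small-sample information criterion AICc, and the near-best set
(ΔAICc <= 2) is model-averaged: natural averaging of estimates,
unconditional standard errors and summed Akaike weights (Σωi) as
relative variable importance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

LOGLIK_CAP = 1e6


@dataclass
class ModelFit:
    """One fitted predictor subset."""

    predictors: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    loglik: float
    k: int  # parameters counted: intercept + slopes + error variance
    n: int
    aicc: float
    delta: float = np.nan
    weight: float = np.nan


@dataclass
class AveragedModel:
    """Model-averaged estimates over an equivalent-model set."""

    table: pd.DataFrame  # per term: estimate, se, ci_lower, ci_upper, sum_weight
    n_models: int
    delta_max: float
    ci_z: float = 1.96


def weighted_glm(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    weights: np.ndarray | None = None,
) -> ModelFit:
    """Normal-error GLM by weighted least squares.

    The log-likelihood uses per-observation variance σ²/wᵢ with σ² at
    its maximum-likelihood value; doubling all weights therefore leaves
    estimates unchanged.  A perfect fit (σ̂² = 0) caps the log-likelihood
    with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(np.asarray(design, dtype=float)) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.WLS(y, design, weights=w).fit()
    resid = y - res.fittedvalues
    sigma2 = float((w * resid**2).sum() / n)
    if sigma2 <= 1e-12 * max(float(np.var(y)), 1e-12):
        warnings.warn("perfect fit: sigma^2 = 0; log-likelihood capped")
        loglik = LOGLIK_CAP
    else:
        loglik = float(
            0.5 * np.log(w).sum() - 0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * n
        )
    k = design.shape[1] + 1  # + sigma^2
    return ModelFit(
        predictors=tuple(X.columns),
        params=res.params,
        bse=res.bse,
        loglik=loglik,
        k=k,
        n=n,
        aicc=aicc(loglik, k, n),
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def rank_models(
    y: pd.Series | np.ndarray,
    candidates: pd.DataFrame,
    weights: np.ndarray | None = None,
) -> list[ModelFit]:
    """Fit every predictor subset and rank by AICc.

    Returns fits sorted by AICc with ΔAICc against the minimum and
    Akaike weights normalized over the whole candidate set.
    """
    names = list(candidates.columns)
    if not names:
        raise ValueError("need at least one candidate predictor")
    fits = []
    for r in range(len(names) + 1):
        for subset in itertools.combinations(names, r):
            fits.append(weighted_glm(y, candidates[list(subset)], weights))
    best = min(f.aicc for f in fits)
    for f in fits:
        f.delta = f.aicc - best
    rel = np.array([np.exp(-0.5 * f.delta) for f in fits])
    wsum = rel.sum()
    for f, w in zip(fits, rel / wsum):
        f.weight = float(w)
    return sorted(fits, key=lambda f: f.aicc)


def model_average(
    fits: list[ModelFit],
    delta_max: float = 2.0,
    ci_z: float = 1.96,
) -> AveragedModel:
    """Average the equivalent-model set (ΔAICc <= delta_max).

    Weights are renormalized within the set.  Each term is averaged over
    the set models that contain it (natural averaging); the
    unconditional SE is Σ w̃ᵢ sqrt(var(θ̂ᵢ) + (θ̂ᵢ − θ̄)²) and the CI is
    estimate ± ci_z · SE.  Σωi is the summed renormalized weight of set
    models containing the term.
    """
    chosen = [f for f in fits if f.delta <= delta_max]
    if not chosen:
        raise ValueError("no model within delta_max of the best")
    wsum = sum(f.weight for f in chosen)
    wtilde = [f.weight / wsum for f in chosen]
    terms: list[str] = ["const"]
    for f in chosen:
        for t in f.predictors:
            if t not in terms:
                terms.append(t)
    rows = []
    for term in terms:
        present = [
            (w, f) for w, f in zip(wtilde, chosen) if term in f.params.index
        ]
        sum_weight = sum(w for w, _ in present)
        if not present:
            continue
        wnorm = [w / sum_weight for w, _ in present]
        est = sum(w * f.params[term] for w, (_, f) in zip(wnorm, present))
        se = sum(
            w * np.sqrt(f.bse[term] ** 2 + (f.params[term] - est) ** 2)
            for w, (_, f) in zip(wnorm, present)
        )
        rows.append(
            {
                "term": term,
                "estimate": float(est),
                "se": float(se),
                "ci_lower": float(est - ci_z * se),
                "ci_upper": float(est + ci_z * se),
                "sum_weight": float(sum_weight) if term != "const" else 1.0,
                "significant": bool(
                    (est - ci_z * se) > 0 or (est + ci_z * se) < 0
                ),
            }
        )
    table = pd.DataFrame(rows).set_index("term")
    return AveragedModel(table, len(chosen), delta_max, ci_z)
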