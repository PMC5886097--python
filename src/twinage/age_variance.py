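"""Age-dependent variance (dispersion) of expression.

The statistic: (1) conditional residuals are taken from a mixed model
removing technical covariates and the family structure — age is *not*
removed, (2) a LOESS curve of residual expression on age absorbs any age
trend in the mean, (3) the square root of the absolute LOESS residual is a
variance-stabilised distance from the age-specific mean, and (4) a
two-sided Spearman correlation between this distance and age tests for an
age effect on dispersion.  The sign of rho gives the direction (variance
increasing or decreasing with age).

Because the LOESS step removes the mean trend, a pure mean effect of age
does not trigger the test; because Spearman is rank-based, the statistic is
invariant to monotone transformations of age.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateFeatureError, ValidationError
from .io import FeatureMatrix, SampleTable
from .age_mean import design_matrix
from .lmm import conditional_residuals_batch, fit_lmm
from .permutation import N_STRATA, permute_pairs, stratified_adjust

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 0.75
DEFAULT_DEGREE = 2
ALPHA = 0.05


# ---------------------------------------------------------------------------
# LOESS (local polynomial regression, tricube weights)


def loess_smooth(x, y, span: float = DEFAULT_SPAN, degree: int = DEFAULT_DEGREE) -> np.ndarray:
    """Fitted LOESS values at the observed points.

    Local weighted polynomial of the given degree: for each point the
    nearest ``floor(span * n)`` neighbours get tricube weights on distance
    scaled by the furthest included neighbour.  No robustness iterations
    (Gaussian family).  Matches classical local regression as implemented
    in standard statistical software with ``surface="direct"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if span <= 0 or span > 1:
        raise ValidationError(f"loess_smooth: span {span} outside (0, 1]")
    q = int(np.floor(span * n))
    if q < degree + 2:
        raise ValidationError(f"loess_smooth: span {span} leaves too few points ({q})")
    D = np.abs(x[None, :] - x[:, None])                      # (n, n)
    dq = np.partition(D, q - 1, axis=1)[:, q - 1]
    dq = np.maximum(dq, 1e-300)
    W = np.clip(1.0 - (D / dq[:, None]) ** 3, 0.0, None) ** 3
    T = x[None, :] - x[:, None]                              # centred predictor
    # moment matrices from weighted power sums
    S = [np.sum(W * T**s, axis=1) for s in range(2 * degree + 1)]
    b = [np.sum(W * T**s * y[None, :], axis=1) for s in range(degree + 1)]
    A = np.empty((n, degree + 1, degree + 1))
    for a_ in range(degree + 1):
        for b_ in range(degree + 1):
            A[:, a_, b_] = S[a_ + b_]
    rhs = np.stack(b, axis=1)
    # tiny ridge guards against exactly replicated ages
    A += 1e-12 * np.eye(degree + 1)[None, :, :] * (1.0 + S[0])[:, None, None]
    coef = np.linalg.solve(A, rhs[..., None])[..., 0]
    return coef[:, 0]


# ---------------------------------------------------------------------------
# the test


def residualize_for_variance(
    fm: FeatureMatrix, samples: SampleTable, covariates: list[str] | None = None
) -> np.ndarray:
    """Conditional residuals removing technical covariates and family structure.

    Age is deliberately left in — the LOESS step handles the mean trend.
    With only the family random term the vectorised rotation path is used;
    configured random technical factors route each feature through the
    general engine.
    """
    Y = fm.values.to_numpy(dtype=float)
    X, names = design_matrix(samples, covariates)
    if samples.random_covariates:
        out = np.empty_like(Y)
        random = {"family": samples.families}
        for cov in samples.random_covariates:
            random[cov] = samples.data[cov].to_numpy()
        for i in range(Y.shape[0]):
            fit = fit_lmm(Y[i], X, random=random, method="REML", names=names)
            out[i] = fit.residuals_conditional
        return out
    return conditional_residuals_batch(Y, X, samples.families)


def dispersion_distance(
    residuals: np.ndarray, ages: np.ndarray, span: float = DEFAULT_SPAN, degree: int = DEFAULT_DEGREE
) -> np.ndarray:
    """sqrt |residual - loess(age)| per feature; rows are features."""
    R = np.atleast_2d(np.asarray(residuals, dtype=float))
    out = np.empty_like(R)
    for i in range(R.shape[0]):
        fit = loess_smooth(ages, R[i], span=span, degree=degree)
        out[i] = np.sqrt(np.abs(R[i] - fit))
    return out if residuals.ndim > 1 else out[0]


def variance_age_test(
    residuals,
    ages,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
) -> dict:
    """Spearman test of the dispersion distance against age for one feature."""
    r = np.asarray(residuals, dtype=float).ravel()
    ages = np.asarray(ages, dtype=float).ravel()
    if r.size < 30:
        raise DegenerateFeatureError(f"variance_age_test: need >= 30 samples, got {r.size}")
    if np.unique(ages).size < 10:
        raise DegenerateFeatureError("variance_age_test: need >= 10 distinct ages")
    d = dispersion_distance(r[None, :], ages, span=span, degree=degree)[0]
    if np.allclose(d, d[0]):
        return {"rho": 0.0, "p": 1.0, "direction": "none"}
    rho, p = stats.spearmanr(d, ages)
    return {
        "rho": float(rho),
        "p": float(p),
        "direction": "increasing" if rho > 0 else "decreasing",
    }


def _rank_standardise(M: np.ndarray) -> np.ndarray:
    """Row-wise ranks, centred and scaled to unit norm (for fast Spearman)."""
    R = stats.rankdata(M, axis=-1).astype(float)
    R -= R.mean(axis=-1, keepdims=True)
    norm = np.sqrt((R**2).sum(axis=-1, keepdims=True))
    return R / np.maximum(norm, 1e-300)


def run_variance_scan(
    fm: FeatureMatrix,
    samples: SampleTable,
    n_permutations: int = 100,
    seed: int = 0,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    n_strata: int = N_STRATA,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Cohort-wide variance-with-age scan with permutation adjustment.

    The dispersion distances are computed once per feature; permutations
    reassign ages (pair-preserving) against the fixed distance vectors and
    the |rho| maxima per gene are pooled within exon-count strata exactly as
    in the mean-expression analysis.
    """
    ages = samples.ages
    resid = residualize_for_variance(fm, samples)
    D = dispersion_distance(resid, ages, span=span, degree=degree)

    Rd = _rank_standardise(D)                              # (F, n)
    ra = _rank_standardise(ages[None, :])[0]
    obs_rho = Rd @ ra
    n = ages.size
    # two-sided p via the t approximation used by standard Spearman tests
    tstat = obs_rho * np.sqrt(np.maximum(n - 2, 1) / np.maximum(1.0 - obs_rho**2, 1e-12))
    nominal_p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)

    rng = np.random.default_rng(seed)
    null = np.empty((D.shape[0], n_permutations))
    for b in range(n_permutations):
        perm = permute_pairs(samples, rng)
        ra_p = _rank_standardise(ages[perm][None, :])[0]
        null[:, b] = np.abs(Rd @ ra_p)

    adj = stratified_adjust(
        pd.Series(np.abs(obs_rho), index=fm.feature_ids), null, fm.gene_ids, n_strata=n_strata
    )
    out = pd.DataFrame(
        {
            "gene_id": fm.gene_ids.to_numpy(),
            "spearman_rho": obs_rho,
            "nominal_p": nominal_p,
            "gene_adjusted_p": adj["gene_adjusted_p"].to_numpy(),
            "feature_adjusted_p": adj["feature_adjusted_p"].to_numpy(),
            "stratum": adj["stratum"].to_numpy(),
            "direction": np.where(obs_rho > 0, "increasing", "decreasing"),
        },
        index=fm.feature_ids,
    )
    out["significant"] = out["gene_adjusted_p"] < alpha
    return out
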