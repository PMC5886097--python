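"""Within-MZ-pair discordance of expression and its change with age.

Monozygotic co-twins share their genome and (by sampling design) their age,
so a within-pair expression difference must be environmental.  Per feature
the pair maximum is regressed on the pair minimum plus age,

    max_i = alpha + beta * min_i + gamma * age_i + eps_i ,

and ``gamma`` tests whether the max/min relationship is conditional on age:
a divergence that grows with age shows up as a positive age term.  Input
residuals remove only technical covariates (family structure must stay —
it *is* the signal).  Multiple testing mirrors the mean-expression
analysis: pair-level age permutations, gene maxima pooled within
exon-count strata.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io import FeatureMatrix, SampleTable
from .age_mean import design_matrix
from .permutation import N_STRATA, stratified_adjust

logger = logging.getLogger(__name__)

ALPHA = 0.05
MIN_PAIRS = 20


def residualize_technical(fm: FeatureMatrix, samples: SampleTable) -> np.ndarray:
    """OLS residuals removing technical fixed covariates only.

    Family structure is intentionally kept in the residuals; the pairwise
    max/min construction consumes it.
    """
    Y = fm.values.to_numpy(dtype=float)
    X, _ = design_matrix(samples)
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ coef).T


def build_pairs(residuals: np.ndarray, samples: SampleTable, min_pairs: int = MIN_PAIRS):
    """Per-feature (max, min) over complete MZ pairs, plus pair ages.

    Returns ``(expr_max, expr_min, pair_ages, family_ids)`` where the first
    two are (features, pairs) arrays.  DZ pairs, incomplete pairs and
    singletons are excluded.
    """
    pairs = samples.complete_pairs("MZ")
    if len(pairs) == 0:
        raise ValidationError("build_pairs: no complete MZ pairs in the cohort")
    if len(pairs) < min_pairs:
        raise ValidationError(
            f"build_pairs: need >= {min_pairs} complete MZ pairs, got {len(pairs)}"
        )
    idx = np.asarray(pairs)
    R = np.atleast_2d(np.asarray(residuals, dtype=float))
    a = R[:, idx[:, 0]]
    b = R[:, idx[:, 1]]
    expr_max = np.maximum(a, b)
    expr_min = np.minimum(a, b)
    ages = samples.ages[idx[:, 0]]
    fams = samples.families[idx[:, 0]]
    return expr_max, expr_min, ages, fams


def _gamma_tstats(expr_max: np.ndarray, expr_min: np.ndarray, ages: np.ndarray):
    """Vectorised OLS of max ~ 1 + min + age per feature; returns (gamma, t, p)."""
    F, P = expr_max.shape
    ones = np.ones(P)
    gam = np.empty(F)
    tval = np.empty(F)
    for i in range(F):
        X = np.column_stack([ones, expr_min[i], ages])
        XtX = X.T @ X
        Xty = X.T @ expr_max[i]
        try:
            beta = np.linalg.solve(XtX, Xty)
            cov = np.linalg.inv(XtX)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                "discordance_age_test: singular design (constant expr_min?)"
            ) from exc
        r = expr_max[i] - X @ beta
        dof = P - 3
        s2 = float(r @ r) / dof
        gam[i] = beta[2]
        scale = max(float(np.var(expr_max[i])), 1e-30)
        if s2 < 1e-12 * scale:
            # exact linear relationship (e.g. perfectly concordant pairs):
            # the age term carries no residual evidence
            tval[i] = 0.0
        else:
            tval[i] = beta[2] / np.sqrt(s2 * cov[2, 2])
    pvals = 2.0 * stats.t.sf(np.abs(tval), df=P - 3)
    return gam, tval, pvals


def discordance_age_test(expr_max, expr_min, ages) -> dict:
    """Single-feature version: gamma coefficient with its two-sided t-test p."""
    em = np.atleast_2d(np.asarray(expr_max, dtype=float))
    en = np.atleast_2d(np.asarray(expr_min, dtype=float))
    if np.allclose(en[0], en[0, 0]):
        raise ValidationError("discordance_age_test: expr_min constant across pairs")
    gam, tval, p = _gamma_tstats(em, en, np.asarray(ages, dtype=float))
    return {"gamma_age": float(gam[0]), "t": float(tval[0]), "p": float(p[0])}


def run_discordance_scan(
    fm: FeatureMatrix,
    samples: SampleTable,
    n_permutations: int = 100,
    seed: int = 0,
    n_strata: int = N_STRATA,
    alpha: float = ALPHA,
    min_pairs: int = MIN_PAIRS,
) -> pd.DataFrame:
    """Cohort-wide discordance-with-age scan with permutation adjustment.

    Permutations shuffle the age label across pairs — each (max, min) pair
    is an indivisible unit — and pool |t| maxima per gene within exon-count
    strata as in the mean analysis.
    """
    resid = residualize_technical(fm, samples)
    expr_max, expr_min, ages, _ = build_pairs(resid, samples, min_pairs=min_pairs)
    gam, tval, nominal_p = _gamma_tstats(expr_max, expr_min, ages)

    rng = np.random.default_rng(seed)
    null = np.empty((expr_max.shape[0], n_permutations))
    for b in range(n_permutations):
        ages_p = ages[rng.permutation(ages.size)]
        _, t_p, _ = _gamma_tstats(expr_max, expr_min, ages_p)
        null[:, b] = np.abs(t_p)

    adj = stratified_adjust(
        pd.Series(np.abs(tval), index=fm.feature_ids), null, fm.gene_ids, n_strata=n_strata
    )
    out = pd.DataFrame(
        {
            "gene_id": fm.gene_ids.to_numpy(),
            "gamma_age": gam,
            "t_statistic": tval,
            "nominal_p": nominal_p,
            "gene_adjusted_p": adj["gene_adjusted_p"].to_numpy(),
            "feature_adjusted_p": adj["feature_adjusted_p"].to_numpy(),
            "stratum": adj["stratum"].to_numpy(),
            "n_pairs": expr_max.shape[1],
        },
        index=fm.feature_ids,
    )
    out["significant"] = out["gene_adjusted_p"] < alpha
    return out
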