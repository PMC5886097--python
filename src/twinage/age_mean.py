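"""Differential mean expression with age.

Per feature, maximum-likelihood mixed-model fits with and without age are
compared by a chi-square(1) likelihood-ratio test; technical covariates
enter as fixed effects and the twin family structure as a random
intercept.  Significance is assessed against a pair-preserving permutation
null (default 100 permutations) with gene-level maxima pooled within
exon-count strata, and a gene is called age-associated when at least one of
its exons is significant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import DegenerateFeatureError
from .io import FeatureMatrix, SampleTable
from .lmm import FamilyRotation, age_scan_batch, fit_lmm, lrt_nested
from .permutation import N_STRATA, permute_pairs, stratified_adjust

logger = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 100
ALPHA = 0.05


def design_matrix(samples: SampleTable, covariates: list[str] | None = None) -> np.ndarray:
    """Fixed-effect design: intercept plus the named covariates.

    Categorical columns are one-hot encoded (first level dropped).
    Returns ``(X, column_names)``.
    """
    cols = [np.ones(len(samples.data))]
    names = ["intercept"]
    for cov in covariates if covariates is not None else samples.fixed_covariates:
        col = samples.data[cov]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols.append(dummies[name].to_numpy(dtype=float))
                names.append(name)
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols)
    return X, names


def test_feature_age(values, samples: SampleTable, covariates: list[str] | None = None):
    """Age LRT for a single feature through the general mixed-model engine.

    Returns ``(beta_age, lrt_statistic, nominal_p)``.  Random terms are the
    family structure plus any configured random technical factors; constant
    features raise :class:`DegenerateFeatureError` so scans can skip them.
    """
    y = np.asarray(values, dtype=float).ravel()
    if np.all(y == y[0]):
        raise DegenerateFeatureError("test_feature_age: constant feature")
    X_red, names = design_matrix(samples, covariates)
    X_full = np.column_stack([X_red, samples.ages])
    random = {"family": samples.families}
    for cov in samples.random_covariates:
        random[cov] = samples.data[cov].to_numpy()
    full = fit_lmm(y, X_full, random=random, method="ML", names=names + ["age"])
    red = fit_lmm(y, X_red, random=random, method="ML", names=names)
    stat, p = lrt_nested(full, red)
    return full.coef("age"), stat, p


def run_age_scan(
    fm: FeatureMatrix,
    samples: SampleTable,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    n_strata: int = N_STRATA,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Cohort-wide age association scan with permutation adjustment.

    ``fm`` must already be rank-normalised.  Returns a frame with one row
    per feature: the signed age coefficient, LRT statistic, nominal p, the
    gene-level and feature-level adjusted p (gene maxima pooled within
    exon-count strata) and the gene-level significance call.
    """
    Y = fm.values.to_numpy(dtype=float)
    ages = samples.ages
    X_red, _ = design_matrix(samples)
    rot = FamilyRotation(samples.families)

    obs = age_scan_batch(Y, X_red, ages, samples.families, rot=rot)
    rng = np.random.default_rng(seed)
    null = np.empty((Y.shape[0], n_permutations))
    for b in range(n_permutations):
        perm = permute_pairs(samples, rng)
        res = age_scan_batch(
            Y, X_red, ages[perm], samples.families, rot=rot, reduced_fit=obs["reduced"]
        )
        null[:, b] = res["lrt"]

    adj = stratified_adjust(
        pd.Series(obs["lrt"], index=fm.feature_ids),
        null,
        fm.gene_ids,
        n_strata=n_strata,
    )
    from statsmodels.stats.multitest import multipletests

    out = pd.DataFrame(
        {
            "gene_id": fm.gene_ids.to_numpy(),
            "beta_age": obs["beta_age"],
            "lrt_statistic": obs["lrt"],
            "nominal_p": obs["p"],
            "gene_adjusted_p": adj["gene_adjusted_p"].to_numpy(),
            "feature_adjusted_p": adj["feature_adjusted_p"].to_numpy(),
            "stratum": adj["stratum"].to_numpy(),
            "n_samples": Y.shape[1],
        },
        index=fm.feature_ids,
    )
    out["bh_fdr"] = multipletests(out["nominal_p"], method="fdr_bh")[1]
    out["significant"] = out["gene_adjusted_p"] < alpha
    return out


def gene_calls(results: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Gene-level rollup: a gene is age-associated if any feature is significant."""
    grp = results.groupby("gene_id")
    out = pd.DataFrame(
        {
            "n_features": grp.size(),
            "min_gene_adjusted_p": grp["gene_adjusted_p"].min(),
            "best_lrt": grp["lrt_statistic"].max(),
            "significant": grp["significant"].any(),
        }
    )
    # direction of the strongest feature
    best = results.loc[results.groupby("gene_id")["lrt_statistic"].idxmax()]
    out["direction"] = np.where(best.set_index("gene_id")["beta_age"] >= 0, "+", "-")
    return out


def direction_summary(results: pd.DataFrame) -> dict[str, float]:
    """Share of positive vs negative age effects among significant features."""
    sig = results[results["significant"]]
    n = len(sig)
    if n == 0:
        return {"n_significant": 0, "frac_positive": float("nan"), "frac_negative": float("nan")}
    pos = float((sig["beta_age"] > 0).mean())
    return {"n_significant": n, "frac_positive": pos, "frac_negative": 1.0 - pos}
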