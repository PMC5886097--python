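"""Genotype-by-age and methylation-by-age interactions on expression.

The GxAge scan asks whether the effect of a cis variant on expression
changes with age.  Per (feature, variant) pair with the variant inside a
window around the gene's TSS (default +/- 1 Mb, MAF >= 0.05) a linear
model

    y = b0 + b1 * dosage + b2 * age + b3 * dosage * age

is fitted on expression residuals that already remove technical covariates
and family structure; ``b3`` is the interaction of interest.  The null for
multiple testing follows the residual-permutation scheme: residuals of the
main-effects-only model are permuted (default 10 times) and pushed back
through the interaction model, the per-permutation interaction statistics
are pooled across the window's variants, and gene-level adjusted p-values
use the same exon-count stratification as the expression analyses.  A
final Benjamini-Hochberg FDR call (5%) is applied across features.

The methylation analogue replaces dosage by the probe beta value and calls
significance at a fixed Bonferroni-style threshold (strict inequality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io import DEFAULT_MIN_MAF, GenotypeMatrix, MethylationMatrix
from .permutation import N_STRATA, stratified_adjust

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1_000_000
DEFAULT_N_PERM = 10
METH_P_THRESHOLD = 1.0e-4
FDR_ALPHA = 0.05


@dataclass
class CisWindow:
    """Candidate cis variants for one gene: |pos - tss| <= half_width.

    The boundary is inclusive on both sides.
    """

    gene_id: str
    tss: int
    half_width: int = DEFAULT_WINDOW

    def candidates(self, gm: GenotypeMatrix, min_maf: float = DEFAULT_MIN_MAF) -> pd.Index:
        ann = gm.annotation
        dist_ok = (ann["pos"] - self.tss).abs() <= self.half_width
        maf_ok = ann["maf"] >= min_maf
        return ann.index[dist_ok & maf_ok]


def _interaction_fit(y: np.ndarray, g: np.ndarray, age: np.ndarray):
    """OLS y ~ 1 + g + age + g*age; returns (betas, t3, p3)."""
    X = np.column_stack([np.ones_like(age), g, age, g * age])
    XtX = X.T @ X
    try:
        beta = np.linalg.solve(XtX, X.T @ y)
        cov = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "interaction model is singular (constant age or monomorphic partner?)"
        ) from exc
    r = y - X @ beta
    dof = y.size - 4
    s2 = float(r @ r) / dof
    se3 = np.sqrt(max(s2 * cov[3, 3], 1e-300))
    t3 = beta[3] / se3
    p3 = 2.0 * stats.t.sf(abs(t3), df=dof)
    return beta, float(t3), float(p3)


def gxage_scan(
    residuals: np.ndarray,
    feature_ids,
    gene_ids,
    tss: pd.Series,
    gm: GenotypeMatrix,
    ages: np.ndarray,
    window: int = DEFAULT_WINDOW,
    min_maf: float = DEFAULT_MIN_MAF,
) -> pd.DataFrame:
    """Interaction scan over all (feature, cis variant) pairs.

    ``residuals`` is (features, samples) aligned with ``gm.dosages``
    columns and ``ages``.  Monomorphic variants (after sample subsetting)
    are skipped with a log entry; a constant age column is an error — the
    interaction is then undefined and the scan degenerates to a plain
    main-effect eQTL scan, which is not what this function is for.
    """
    ages = np.asarray(ages, dtype=float)
    if np.unique(ages).size < 2:
        raise ValidationError("gxage_scan: age is constant; interaction term undefined")
    R = np.atleast_2d(np.asarray(residuals, dtype=float))
    dos = gm.dosages.to_numpy(dtype=float)
    vindex = gm.dosages.index
    rows = []
    for fi, fid in enumerate(feature_ids):
        win = CisWindow(gene_id=gene_ids.iloc[fi] if hasattr(gene_ids, "iloc") else gene_ids[fi],
                        tss=int(tss.iloc[fi] if hasattr(tss, "iloc") else tss[fi]),
                        half_width=window)
        for vid in win.candidates(gm, min_maf=min_maf):
            vi = vindex.get_loc(vid)
            g = dos[vi]
            if np.allclose(g, g[0]):
                logger.info("gxage_scan: skipping monomorphic variant %s", vid)
                continue
            beta, t3, p3 = _interaction_fit(R[fi], g, ages)
            rows.append(
                (fid, win.gene_id, vid, beta[1], beta[2], beta[3], t3, p3)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "gene_id",
            "partner_id",
            "beta_main",
            "beta_age",
            "beta_interaction",
            "t_interaction",
            "nominal_p",
        ],
    )


def gxage_permutation_adjust(
    scan: pd.DataFrame,
    residuals: np.ndarray,
    feature_ids,
    gm: GenotypeMatrix,
    ages: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    n_strata: int = N_STRATA,
    fdr_alpha: float = FDR_ALPHA,
) -> pd.DataFrame:
    """Residual-permutation adjusted p-values per feature, plus an FDR call.

    For every tested (feature, variant) pair the main-effects model
    ``y ~ 1 + g + age`` is fitted, its residuals permuted ``n_perm`` times
    and refitted through the full interaction model.  The per-permutation
    maxima of |t3| across the feature's variants form the null; pooling is
    stratified by exon count with a +1 pseudocount as in the expression
    analyses.  With only 10 permutations the pooling across variants and
    genes is what gives the empirical p-values their resolution.
    """
    if scan.empty:
        return pd.DataFrame(
            columns=list(scan.columns) + ["gene_adjusted_p", "feature_adjusted_p", "fdr_significant"]
        )
    ages = np.asarray(ages, dtype=float)
    R = np.atleast_2d(np.asarray(residuals, dtype=float))
    f_list = list(feature_ids)
    rng = np.random.default_rng(seed)
    dos = gm.dosages.to_numpy(dtype=float)
    vindex = gm.dosages.index

    feats = scan["feature_id"].unique().tolist()
    obs_stat = pd.Series(index=feats, dtype=float)
    null = np.empty((len(feats), n_perm))
    gene_of = scan.groupby("feature_id")["gene_id"].first()
    # each permutation is one dataset-wide relabeling shared by every
    # feature and variant, so the null maxima carry the same within-gene and
    # cross-variant dependence as the observed maxima
    perms = [rng.permutation(ages.size) for _ in range(n_perm)]
    for k, fid in enumerate(feats):
        sub = scan[scan["feature_id"] == fid]
        obs_stat.loc[fid] = sub["t_interaction"].abs().max()
        y = R[f_list.index(fid)]
        null_ft = np.full((n_perm, len(sub)), -np.inf)
        for j, vid in enumerate(sub["partner_id"]):
            g = dos[vindex.get_loc(vid)]
            Xm = np.column_stack([np.ones_like(ages), g, ages])
            beta_m, *_ = np.linalg.lstsq(Xm, y, rcond=None)
            r_main = y - Xm @ beta_m
            for b in range(n_perm):
                _, t3, _ = _interaction_fit(r_main[perms[b]], g, ages)
                null_ft[b, j] = abs(t3)
        null[k] = null_ft.max(axis=1)

    adj = stratified_adjust(obs_stat, null, gene_of.loc[feats], n_strata=n_strata)
    out = scan.copy()
    out["gene_adjusted_p"] = adj["gene_adjusted_p"].reindex(out["feature_id"]).to_numpy()
    out["feature_adjusted_p"] = adj["feature_adjusted_p"].reindex(out["feature_id"]).to_numpy()

    from statsmodels.stats.multitest import multipletests

    best = out.loc[out.groupby("feature_id")["nominal_p"].idxmin()].set_index("feature_id")
    rej, qvals, *_ = multipletests(best["feature_adjusted_p"], alpha=fdr_alpha, method="fdr_bh")
    fdr_call = pd.Series(rej, index=best.index)
    out["fdr_significant"] = fdr_call.reindex(out["feature_id"]).to_numpy()
    return out


def meth_age_test(
    expr_residuals: np.ndarray,
    feature_ids,
    gene_ids,
    mm: MethylationMatrix,
    meth_residuals: np.ndarray,
    ages: np.ndarray,
    genes: list[str] | None = None,
    p_threshold: float = METH_P_THRESHOLD,
) -> pd.DataFrame:
    """Methylation-by-age interaction on expression for mapped probes.

    ``meth_residuals`` aligns with ``mm.betas`` rows (probes) — both
    expression and methylation are expected residualised for technical
    covariates and family structure upstream.  ``genes`` optionally
    restricts the gene set (e.g. to a variance-age prescreen).  A pair is
    significant when the interaction p is strictly below ``p_threshold``.
    """
    ages = np.asarray(ages, dtype=float)
    R = np.atleast_2d(np.asarray(expr_residuals, dtype=float))
    M = np.atleast_2d(np.asarray(meth_residuals, dtype=float))
    probe_gene = mm.annotation["gene_id"]
    rows = []
    gene_arr = gene_ids.to_numpy() if hasattr(gene_ids, "to_numpy") else np.asarray(gene_ids)
    for fi, fid in enumerate(feature_ids):
        gene = gene_arr[fi]
        if genes is not None and gene not in genes:
            continue
        probes = probe_gene.index[probe_gene == gene]
        for pid in probes:
            pi = mm.betas.index.get_loc(pid)
            meth = M[pi]
            if np.allclose(meth, meth[0]):
                logger.info("meth_age_test: skipping zero-variance probe %s", pid)
                continue
            beta, t3, p3 = _interaction_fit(R[fi], meth, ages)
            rows.append((fid, gene, pid, beta[1], beta[2], beta[3], p3, p3 < p_threshold))
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "gene_id",
            "partner_id",
            "beta_meth",
            "beta_age",
            "beta_interaction",
            "nominal_p",
            "significant",
        ],
    )
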