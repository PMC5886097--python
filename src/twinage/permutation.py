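"""Pair-preserving permutation and stratified empirical p-values.

Twin pairs are never split by a permutation: complete pairs are reassigned
as indivisible units onto other pair slots, singletons onto singleton
slots.  Operationally we permute the person-level labels (age) rather than
the expression blocks — the two are equivalent, and sample-attached
technical covariates stay with their expression values.

Multiple testing across features uses gene-level empirical p-values.  The
observed statistic of a gene is the maximum over its features, which makes
genes with more exons more significant by chance; to keep the null
calibration fair the genes are binned into (up to) 16 exon-count strata and
each gene's maximum is compared only against the pooled permutation maxima
of its own stratum, with a +1 pseudocount:

    adj_p(gene) = (1 + #{null >= observed}) / (1 + pool size)
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_STRATA = 16


def permute_pairs(samples, rng: np.random.Generator) -> np.ndarray:
    """A pair-preserving permutation of person-level labels.

    Returns an index array ``perm`` such that ``age[perm]`` is the permuted
    age assignment: complete pairs are shuffled among pair slots (with a
    random within-pair flip), remaining samples among the remaining slots.
    Co-twins therefore still share a family id and an identical age after
    permutation.
    """
    pairs = samples.complete_pairs()
    n = len(samples.data)
    in_pair = np.zeros(n, dtype=bool)
    for i, j in pairs:
        in_pair[i] = in_pair[j] = True
    singles = np.flatnonzero(~in_pair)

    perm = np.empty(n, dtype=int)
    if pairs:
        order = rng.permutation(len(pairs))
        for slot, src in zip(range(len(pairs)), order):
            ti, tj = pairs[slot]
            si, sj = pairs[src]
            if rng.random() < 0.5:
                si, sj = sj, si
            perm[ti], perm[tj] = si, sj
    if len(singles):
        perm[singles] = singles[rng.permutation(len(singles))]
    return perm


def assign_strata(exon_counts: pd.Series, n_strata: int = N_STRATA) -> pd.Series:
    """Quantile bins of exons-per-gene (gene_id -> stratum code).

    Empty/duplicate quantile boundaries are merged, so the effective number
    of strata can be below ``n_strata`` when few distinct counts exist.
    """
    counts = exon_counts.astype(float)
    if counts.nunique() == 1:
        return pd.Series(0, index=counts.index)
    binned = pd.qcut(counts.rank(method="first"), q=min(n_strata, counts.nunique()), duplicates="drop")
    return pd.Series(binned.cat.codes.astype(int), index=counts.index)


def stratified_adjust(
    feature_stats: pd.Series,
    null_stats: np.ndarray,
    gene_ids: pd.Series,
    n_strata: int = N_STRATA,
) -> pd.DataFrame:
    """Gene- and feature-level empirical adjusted p-values.

    Parameters
    ----------
    feature_stats : observed statistic per feature (larger = more
        significant), indexed by feature_id.
    null_stats : (n_features, n_permutations) permutation statistics in the
        same row order.
    gene_ids : gene id per feature, same index.

    Returns a frame indexed by feature_id with the observed statistic, the
    gene maximum, the stratum and gene-/feature-level adjusted p.
    """
    obs = feature_stats.to_numpy(dtype=float)
    null = np.asarray(null_stats, dtype=float)
    if null.ndim != 2 or null.shape[0] != obs.size:
        raise ValueError("stratified_adjust: null_stats must be (n_features, n_permutations)")
    genes = gene_ids.to_numpy()
    frame = pd.DataFrame({"gene_id": genes, "stat": obs}, index=feature_stats.index)

    gene_obs = frame.groupby("gene_id")["stat"].max()
    gene_codes, gene_index = pd.factorize(frame["gene_id"], sort=True)
    n_genes = len(gene_index)
    n_perm = null.shape[1]
    gene_null = np.full((n_genes, n_perm), -np.inf)
    np.maximum.at(gene_null, gene_codes, null)

    exon_counts = frame.groupby("gene_id").size().reindex(gene_index)
    strata = assign_strata(exon_counts, n_strata=n_strata)

    gene_adj = pd.Series(index=gene_index, dtype=float)
    feat_adj = np.empty(obs.size)
    for code in strata.unique():
        g_sel = strata[strata == code].index
        g_pos = gene_index.get_indexer(g_sel)
        pool = np.sort(gene_null[g_pos].ravel())
        counts_ge = pool.size - np.searchsorted(pool, gene_obs.loc[g_sel].to_numpy(), side="left")
        gene_adj.loc[g_sel] = (1.0 + counts_ge) / (1.0 + pool.size)
        # feature-level: each feature's statistic against the pooled
        # per-feature nulls of the stratum
        f_sel = np.isin(gene_codes, g_pos)
        f_pool = np.sort(null[f_sel].ravel())
        f_ge = f_pool.size - np.searchsorted(f_pool, obs[f_sel], side="left")
        feat_adj[f_sel] = (1.0 + f_ge) / (1.0 + f_pool.size)

    out = frame.copy()
    out["gene_stat"] = gene_obs.loc[frame["gene_id"]].to_numpy()
    out["stratum"] = strata.loc[frame["gene_id"]].to_numpy()
    out["gene_adjusted_p"] = gene_adj.loc[frame["gene_id"]].to_numpy()
    out["feature_adjusted_p"] = feat_adj
    return out
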