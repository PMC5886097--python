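"""Readers, writers, validation and pre-analysis normalisation.

On-disk formats are deliberately plain: tab-separated matrices with the
feature identifier in the first column, a BED-like feature annotation table
(0-based half-open coordinates internally; VCF positions are converted from
1-based at the boundary), VCF 4.x genotypes and a TSV sample-metadata table.

Normalisation follows the standard RNA-seq pre-processing for this kind of
cohort analysis: per-sample library scaling to a fixed read total (default
10 million) followed by a per-feature rank-based inverse-normal transform,
which makes downstream linear-model inference robust to the marginal count
distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateFeatureError, ValidationError

logger = logging.getLogger(__name__)

ZYGOSITIES = ("MZ", "DZ", "singleton")

#: default library size after scaling (reads)
DEFAULT_LIBRARY_SCALE = 10_000_000
#: genes with more than this fraction of zero counts are flagged for removal
DEFAULT_ZERO_FRACTION = 0.10
#: minimum minor-allele frequency for variants entering interaction scans
DEFAULT_MIN_MAF = 0.05

SAMPLE_COLUMNS = ("sample_id", "individual_id", "family_id", "zygosity", "age", "tissue")
ANNOTATION_COLUMNS = ("chrom", "start", "end", "feature_id", "gene_id", "strand", "tss")


# ---------------------------------------------------------------------------
# containers


@dataclass
class SampleTable:
    """Cohort metadata: one row per sample.

    ``data`` is indexed by ``sample_id`` and carries ``individual_id``,
    ``family_id``, ``zygosity`` (MZ/DZ/singleton), ``age`` in years,
    ``tissue`` and any technical covariate columns.  ``fixed_covariates``
    and ``random_covariates`` name the columns entering mixed models as
    fixed effects (e.g. insert size, mean GC content, batch for blood) and
    as random intercept factors (e.g. primer index, sequencing date).
    """

    data: pd.DataFrame
    fixed_covariates: list[str] = field(default_factory=list)
    random_covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
                self.data = df
            else:
                raise ValidationError("sample table: missing 'sample_id' column/index")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"sample table: duplicated sample_id {dups}")
        for col in ("individual_id", "family_id", "zygosity", "age", "tissue"):
            if col not in df.columns:
                raise ValidationError(f"sample table: missing column '{col}'")
        bad_zyg = set(df["zygosity"]) - set(ZYGOSITIES)
        if bad_zyg:
            raise ValidationError(f"sample table: invalid zygosity values {sorted(bad_zyg)}")
        ages = df["age"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ages)) or ages.min() < 0 or ages.max() > 120:
            raise ValidationError("sample table: field 'age' outside [0, 120] or non-numeric")
        for cov in self.fixed_covariates + self.random_covariates:
            if cov not in df.columns:
                raise ValidationError(f"sample table: covariate column '{cov}' not present")
        # family structure: at most two individuals; co-twins same zygosity & age
        for fam, grp in df.groupby("family_id"):
            n_ind = grp["individual_id"].nunique()
            if n_ind > 2:
                raise ValidationError(
                    f"sample table: family '{fam}' has {n_ind} individuals (max 2)"
                )
            if n_ind == 2:
                if grp["zygosity"].nunique() != 1:
                    raise ValidationError(
                        f"sample table: family '{fam}' co-twins differ in zygosity"
                    )
                if grp["age"].nunique() != 1:
                    raise ValidationError(
                        f"sample table: family '{fam}' co-twins differ in age "
                        "(samples are taken at the same visit)"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def ages(self) -> np.ndarray:
        return self.data["age"].to_numpy(dtype=float)

    @property
    def families(self) -> np.ndarray:
        return self.data["family_id"].to_numpy()

    def complete_pairs(self, zygosity: str | None = None) -> list[tuple[int, int]]:
        """Positional index pairs (i, j) of complete co-twin pairs.

        A complete pair means two distinct individuals of the same family
        present in the table.  ``zygosity`` optionally restricts to MZ or DZ.
        """
        df = self.data.reset_index()
        pairs: list[tuple[int, int]] = []
        for _, grp in df.groupby("family_id", sort=True):
            if grp["individual_id"].nunique() != 2:
                continue
            if zygosity is not None and grp["zygosity"].iloc[0] != zygosity:
                continue
            idx = grp.index.to_numpy()
            pairs.append((int(idx[0]), int(idx[1])))
        return pairs


@dataclass
class FeatureMatrix:
    """Expression values (features x samples) with genomic annotation.

    ``annotation`` is indexed by feature_id and carries gene_id,
    feature_kind (exon/link), chrom, start, end (0-based half-open),
    strand and tss.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"expression matrix: duplicated feature ids {dups}")
        missing = self.values.index.difference(self.annotation.index)
        if len(missing):
            raise ValidationError(
                f"expression matrix: features without annotation: {missing.tolist()[:5]}"
            )
        self.annotation = self.annotation.loc[self.values.index]
        if "tss" not in self.annotation.columns:
            ann = self.annotation
            self.annotation = ann.assign(
                tss=np.where(ann["strand"] == "-", ann["end"], ann["start"])
            )

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def gene_ids(self) -> pd.Series:
        return self.annotation["gene_id"]

    @property
    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)

    def exons_per_gene(self) -> pd.Series:
        return self.annotation.groupby("gene_id").size()

    def subset_samples(self, sample_ids) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[:, list(sample_ids)], self.annotation.copy())


@dataclass
class GenotypeMatrix:
    """Allelic dosages (variants x samples) in [0, 2] with variant annotation."""

    dosages: pd.DataFrame
    annotation: pd.DataFrame  # chrom, pos (1-based), ref, alt, maf

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        if vals.size and (vals.min() < -1e-9 or vals.max() > 2 + 1e-9):
            raise ValidationError("genotypes: dosages outside [0, 2]")
        self.annotation = self.annotation.loc[self.dosages.index]
        maf = compute_maf(vals)
        if "maf" in self.annotation.columns and len(maf):
            stored = self.annotation["maf"].to_numpy(dtype=float)
            if np.max(np.abs(stored - maf)) > 1e-6:
                raise ValidationError("genotypes: stored maf inconsistent with dosages")
        else:
            self.annotation = self.annotation.assign(maf=maf)

    @property
    def maf(self) -> pd.Series:
        return self.annotation["maf"]


@dataclass
class MethylationMatrix:
    """Methylation beta values (probes x samples) with probe-to-gene mapping."""

    betas: pd.DataFrame
    annotation: pd.DataFrame  # probe_id index; chrom, pos, gene_id

    def __post_init__(self) -> None:
        vals = self.betas.to_numpy(dtype=float)
        missing = np.isnan(vals).any(axis=1)
        if missing.any():
            # only probes observed in every sample are analysed
            dropped = self.betas.index[missing].tolist()
            logger.info("methylation: dropping %d probes with missing values", len(dropped))
            self.betas = self.betas.loc[~missing]
            vals = self.betas.to_numpy(dtype=float)
        if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise ValidationError("methylation: beta values outside [0, 1]")
        self.annotation = self.annotation.loc[self.betas.index]


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency from dosages: min(p, 1-p) with p = mean/2."""
    if dosages.size == 0:
        return np.zeros(dosages.shape[0])
    p = dosages.mean(axis=1) / 2.0
    return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# readers / writers


def read_sample_table(
    path,
    fixed_covariates: list[str] | None = None,
    random_covariates: list[str] | None = None,
) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual_id": str, "family_id": str})
    for col in SAMPLE_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column '{col}'")
    return SampleTable(
        df.set_index("sample_id"),
        fixed_covariates=list(fixed_covariates or []),
        random_covariates=list(random_covariates or []),
    )


def read_expression(
    matrix_path,
    annotation_path,
    samples: SampleTable | None = None,
    zero_fraction: float = DEFAULT_ZERO_FRACTION,
    drop_flagged: bool = True,
) -> FeatureMatrix:
    """Load an expression matrix plus annotation and apply the zero-count gene filter.

    A gene is flagged when the fraction of zero entries across all its
    features and samples exceeds ``zero_fraction`` (default 10%); all
    features of a flagged gene are removed together — the filter is a
    gene-level call.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    try:
        mat = mat.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{matrix_path}: malformed numeric value ({exc})") from exc
    if mat.index.duplicated().any():
        dups = mat.index[mat.index.duplicated()].unique().tolist()
        raise ValidationError(f"{matrix_path}: duplicated feature ids {dups}")
    if (mat.to_numpy() < 0).any():
        rows = mat.index[(mat.to_numpy() < 0).any(axis=1)].tolist()[:5]
        raise ValidationError(f"{matrix_path}: negative counts in rows {rows}")
    ann = pd.read_csv(annotation_path, sep="\t")
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            raise ValidationError(f"{annotation_path}: missing column '{col}'")
    ann = ann.set_index("feature_id")
    if samples is not None:
        unknown = [s for s in mat.columns if s not in samples.data.index]
        if unknown:
            raise ValidationError(
                f"{matrix_path}: samples absent from metadata: {unknown[:5]}"
            )
        mat = mat.loc[:, samples.sample_ids]
    fm = FeatureMatrix(mat, ann)
    flagged = flag_zero_genes(fm, zero_fraction)
    fm.annotation = fm.annotation.assign(flagged=fm.gene_ids.isin(flagged))
    if drop_flagged and len(flagged):
        keep = ~fm.annotation["flagged"]
        logger.info("dropping %d features from %d flagged genes", int((~keep).sum()), len(flagged))
        fm = FeatureMatrix(fm.values.loc[keep], fm.annotation.loc[keep])
    return fm


def flag_zero_genes(fm: FeatureMatrix, zero_fraction: float = DEFAULT_ZERO_FRACTION) -> list[str]:
    """Gene ids whose fraction of zero counts exceeds ``zero_fraction``."""
    zeros = (fm.values.to_numpy() == 0)
    df = pd.DataFrame(
        {"gene_id": fm.gene_ids.to_numpy(), "zeros": zeros.sum(axis=1), "n": zeros.shape[1]}
    )
    agg = df.groupby("gene_id").sum()
    frac = agg["zeros"] / agg["n"]
    return frac.index[frac > zero_fraction].tolist()


def scale_counts(fm: FeatureMatrix, target: float = DEFAULT_LIBRARY_SCALE) -> FeatureMatrix:
    """Scale every sample column to a common library size ``target``."""
    sums = fm.values.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValidationError(f"scale_counts: zero-sum sample column(s) {zero}")
    scaled = fm.values * (target / sums)
    return FeatureMatrix(scaled, fm.annotation.copy())


def rank_inverse_normal(values, offset: float = 0.5) -> np.ndarray:
    """Rank-based inverse-normal transform.

    Maps value with (average, for ties) rank r among n to
    ``Phi^-1((r - offset) / (n - 2*offset + 1))``; the default offset 0.5
    gives the symmetric (r - 0.5)/n variant, which avoids infinite
    quantiles.  Output order matches input order.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("rank_inverse_normal expects a 1-d vector")
    n = x.size
    if n < 3:
        raise DegenerateFeatureError(f"rank_inverse_normal: need >= 3 values, got {n}")
    if np.all(x == x[0]):
        raise DegenerateFeatureError("rank_inverse_normal: constant vector")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))


def rank_normalize_matrix(fm: FeatureMatrix, offset: float = 0.5) -> tuple[FeatureMatrix, list[str]]:
    """Row-wise rank-inverse-normal transform; degenerate features are dropped.

    Returns the transformed matrix and the list of skipped feature ids.
    """
    out = np.empty(fm.values.shape)
    skipped: list[str] = []
    keep = np.ones(fm.values.shape[0], dtype=bool)
    vals = fm.values.to_numpy(dtype=float)
    for i, fid in enumerate(fm.feature_ids):
        try:
            out[i] = rank_inverse_normal(vals[i], offset=offset)
        except DegenerateFeatureError:
            skipped.append(fid)
            keep[i] = False
    if skipped:
        logger.info("rank_normalize_matrix: skipped %d degenerate features", len(skipped))
    res = pd.DataFrame(out[keep], index=fm.feature_ids[keep], columns=fm.values.columns)
    return FeatureMatrix(res, fm.annotation.loc[keep]), skipped


def read_vcf(path, samples: list[str] | None = None, skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Load a VCF 4.x into a dosage matrix.

    Dosages come from the DS FORMAT field when present, otherwise from GT
    (count of alternate alleles).  Multi-allelic sites are skipped by
    default.  MAF is recomputed from the loaded samples.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=samples)
    loaded = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in loaded]
        if missing:
            raise ValidationError(f"{path}: samples absent from VCF: {missing[:5]}")
    rows, ann = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            if skip_multiallelic:
                logger.info("read_vcf: skipping multi-allelic site %s:%d", var.CHROM, var.POS)
                continue
            raise ValidationError(f"{path}: multi-allelic site {var.CHROM}:{var.POS}")
        ds = var.format("DS")
        if ds is not None:
            dos = np.asarray(ds, dtype=float).ravel()
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            if (gts < 0).any():
                raise ValidationError(f"{path}: missing genotype at {var.CHROM}:{var.POS}")
            dos = gts.sum(axis=1).astype(float)
        vid = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        rows.append(dos)
        ann.append((vid, var.CHROM, var.POS, var.REF, var.ALT[0]))
    annotation = pd.DataFrame(ann, columns=["variant_id", "chrom", "pos", "ref", "alt"]).set_index(
        "variant_id"
    )
    dosages = pd.DataFrame(rows, index=annotation.index, columns=loaded)
    if samples is not None:
        dosages = dosages.loc[:, samples]
    return GenotypeMatrix(dosages, annotation)


def read_methylation(matrix_path, annotation_path) -> MethylationMatrix:
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0).astype(float)
    ann = pd.read_csv(annotation_path, sep="\t").set_index("probe_id")
    for col in ("chrom", "pos", "gene_id"):
        if col not in ann.columns:
            raise ValidationError(f"{annotation_path}: missing column '{col}'")
    return MethylationMatrix(mat, ann)


# -- writers (used by the synthetic cohort and by the pipeline) -------------


def write_sample_table(samples: SampleTable, path) -> None:
    samples.data.reset_index().to_csv(path, sep="\t", index=False)


def write_expression(fm: FeatureMatrix, matrix_path, annotation_path) -> None:
    fm.values.to_csv(matrix_path, sep="\t", index_label="feature_id")
    cols = [c for c in ("chrom", "start", "end", "gene_id", "strand", "tss", "feature_kind") if c in fm.annotation.columns]
    out = fm.annotation[cols].reset_index()
    order = ["chrom", "start", "end", "feature_id", "gene_id", "strand", "tss"]
    order += [c for c in out.columns if c not in order]
    out[order].to_csv(annotation_path, sep="\t", index=False)


def write_methylation(mm: MethylationMatrix, matrix_path, annotation_path) -> None:
    mm.betas.to_csv(matrix_path, sep="\t", index_label="probe_id")
    mm.annotation.reset_index().to_csv(annotation_path, sep="\t", index=False)


def write_vcf(gm: GenotypeMatrix, path, haplotypes: np.ndarray | None = None) -> None:
    """Write genotypes as VCF 4.2 with GT (from haplotypes when available) and DS.

    ``haplotypes`` is an optional (variants, samples, 2) 0/1 array; without
    it GT is derived from rounded dosages as an unphased genotype.
    """
    samples = list(gm.dosages.columns)
    ann = gm.annotation
    dos = gm.dosages.to_numpy(dtype=float)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=twinage-synthetic\n")
        for chrom in pd.unique(ann["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for i, (vid, row) in enumerate(ann.iterrows()):
            fields = [str(row["chrom"]), str(int(row["pos"])), str(vid), row["ref"], row["alt"], ".", "PASS", ".", "GT:DS"]
            for j in range(len(samples)):
                if haplotypes is not None:
                    a, b = int(haplotypes[i, j, 0]), int(haplotypes[i, j, 1])
                    gt = f"{a}|{b}"
                else:
                    g = int(round(dos[i, j]))
                    gt = ["0/0", "0/1", "1/1"][g]
                fields.append(f"{gt}:{dos[i, j]:g}")
            fh.write("\t".join(fields) + "\n")
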