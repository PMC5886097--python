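"""End-to-end driver: simulate -> validate -> analyses -> sharing.

Every stage writes a plain TSV with a stable column order into the run
directory, plus a manifest recording the configuration hash, seed and
package version, so a rerun with the same config and seed reproduces the
outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .age_mean import gene_calls, run_age_scan
from .age_variance import run_variance_scan
from .discordance import residualize_technical, run_discordance_scan
from .exceptions import TwinageError, ValidationError
from .interactions import gxage_permutation_adjust, gxage_scan, meth_age_test
from .io import (
    DEFAULT_LIBRARY_SCALE,
    DEFAULT_MIN_MAF,
    DEFAULT_ZERO_FRACTION,
    rank_normalize_matrix,
    read_expression,
    read_methylation,
    read_sample_table,
    read_vcf,
    scale_counts,
)
from .lmm import fit_ace, whitened_residuals_batch
from .age_mean import design_matrix
from .sharing import pi1_matrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds of a run; the defaults are the analysis' standard values."""

    alpha: float = 0.05
    zero_fraction: float = DEFAULT_ZERO_FRACTION
    library_scale: float = DEFAULT_LIBRARY_SCALE
    min_maf: float = DEFAULT_MIN_MAF
    cis_window: int = 1_000_000
    meth_p_threshold: float = 1.0e-4
    variance_prescreen_p: float = 0.1
    n_permutations: int = 100
    n_gxage_permutations: int = 10
    n_strata: int = 16
    loess_span: float = 0.75
    loess_degree: int = 2
    seed: int = 0
    fixed_covariates: list = field(default_factory=lambda: ["insert_size", "gc_mean", "batch"])
    random_covariates: list = field(default_factory=list)

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError(f"RunConfig: alpha {self.alpha} outside (0, 1)")
        if not (0 <= self.zero_fraction < 1):
            raise ValidationError(f"RunConfig: zero_fraction {self.zero_fraction} invalid")
        if not (0 <= self.min_maf <= 0.5):
            raise ValidationError(f"RunConfig: min_maf {self.min_maf} outside [0, 0.5]")
        if self.cis_window <= 0 or self.n_permutations < 1 or self.n_gxage_permutations < 1:
            raise ValidationError("RunConfig: window/permutation counts must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def load_cohort(directory, config: RunConfig):
    """Read a cohort directory written by :func:`twinage.simulate.write_cohort`."""
    d = Path(directory)
    for name in ("samples.tsv", "expression.tsv", "features.tsv"):
        if not (d / name).exists():
            raise ValidationError(f"missing input file: {d / name}")
    samples = read_sample_table(
        d / "samples.tsv",
        fixed_covariates=config.fixed_covariates,
        random_covariates=config.random_covariates,
    )
    expr = read_expression(
        d / "expression.tsv", d / "features.tsv", samples=samples, zero_fraction=config.zero_fraction
    )
    genotypes = read_vcf(d / "genotypes.vcf", samples=samples.sample_ids) if (d / "genotypes.vcf").exists() else None
    meth = (
        read_methylation(d / "methylation.tsv", d / "probes.tsv")
        if (d / "methylation.tsv").exists()
        else None
    )
    return samples, expr, genotypes, meth


ALL_STAGES = ("age_mean", "age_variance", "discordance", "heritability", "gxage", "meth_age")


def run_all(cohort_dir, out_dir, config: RunConfig, stages=None) -> dict[str, Path]:
    """Run the analysis battery (or a subset of stages) on one cohort directory.

    ``stages`` limits the work to the named outputs; the interaction stages
    pull in the scans they depend on for their eligible-feature sets.
    """
    config.validate()
    stages = set(ALL_STAGES if stages is None else stages)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise ValidationError(f"run_all: unknown stage(s) {sorted(unknown)}")
    # the interaction scans condition on age-affected features
    if stages & {"gxage", "meth_age"}:
        stages |= {"age_mean", "age_variance", "discordance"}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    _stage("load")
    samples, expr, genotypes, meth = load_cohort(cohort_dir, config)

    _stage("normalise")
    scaled = scale_counts(expr, target=config.library_scale)
    normed, skipped = rank_normalize_matrix(scaled)
    ages = samples.ages

    mean_res = var_res = disc_res = None
    if "age_mean" in stages:
        _stage("age-mean")
        mean_res = run_age_scan(
        normed,
        samples,
        n_permutations=config.n_permutations,
        seed=config.seed,
            n_strata=config.n_strata,
            alpha=config.alpha,
        )
        written["age_mean"] = out / "age_mean.tsv"
        mean_res.to_csv(written["age_mean"], sep="\t", index_label="feature_id")
        gene_calls(mean_res, alpha=config.alpha).to_csv(out / "age_mean_genes.tsv", sep="\t")

    if "age_variance" in stages:
        _stage("age-variance")
        var_res = run_variance_scan(
        normed,
            samples,
            n_permutations=config.n_permutations,
            seed=config.seed,
            span=config.loess_span,
            degree=config.loess_degree,
            n_strata=config.n_strata,
            alpha=config.alpha,
        )
        written["age_variance"] = out / "age_variance.tsv"
        var_res.to_csv(written["age_variance"], sep="\t", index_label="feature_id")

    if "discordance" in stages:
        _stage("discordance")
        disc_res = run_discordance_scan(
        normed,
            samples,
            n_permutations=config.n_permutations,
            seed=config.seed,
            n_strata=config.n_strata,
            alpha=config.alpha,
        )
        written["discordance"] = out / "discordance.tsv"
        disc_res.to_csv(written["discordance"], sep="\t", index_label="feature_id")

    herit_rows = []
    if "heritability" in stages:
        _stage("heritability")
        tech_resid = residualize_technical(normed, samples)
        for i, fid in enumerate(normed.feature_ids):
            try:
                vc = fit_ace(tech_resid[i], samples)
            except TwinageError as exc:
                logger.info("heritability: skipping %s (%s)", fid, exc)
                continue
            herit_rows.append(
                {
                    "feature_id": fid,
                    "gene_id": normed.gene_ids.iloc[i],
                    "sigma2_a": vc.sigma2_a,
                    "sigma2_c": vc.sigma2_c,
                    "sigma2_e": vc.sigma2_e,
                    "sigma2_age": vc.sigma2_age,
                    "h2": vc.h2,
                    "pve_age": vc.pve_age,
                    "converged": vc.converged,
                }
            )
        herit = pd.DataFrame(herit_rows)
        written["heritability"] = out / "heritability.tsv"
        herit.to_csv(written["heritability"], sep="\t", index=False)

    if "gxage" in stages and genotypes is not None:
        _stage("gxage")
        eligible = (
            mean_res.index[mean_res["significant"]]
            .union(var_res.index[var_res["significant"]])
            .union(disc_res.index[disc_res["significant"]])
        )
        if len(eligible) == 0:
            logger.info("gxage: no eligible (age-affected) features; skipping scan")
            scan = pd.DataFrame()
        else:
            X, _ = design_matrix(samples)
            resid = whitened_residuals_batch(
                normed.values.loc[eligible].to_numpy(float), X, samples.families
            )
            ann = normed.annotation.loc[eligible]
            scan = gxage_scan(
                resid,
                list(eligible),
                ann["gene_id"],
                ann["tss"],
                genotypes,
                ages,
                window=config.cis_window,
                min_maf=config.min_maf,
            )
            if not scan.empty:
                scan = gxage_permutation_adjust(
                    scan,
                    resid,
                    list(eligible),
                    genotypes,
                    ages,
                    n_perm=config.n_gxage_permutations,
                    seed=config.seed,
                    n_strata=config.n_strata,
                )
        written["gxage"] = out / "gxage.tsv"
        scan.to_csv(written["gxage"], sep="\t", index=False)

    if "meth_age" in stages and meth is not None and len(meth.betas):
        _stage("meth-age")
        prescreen_genes = (
            var_res.loc[var_res["nominal_p"] < config.variance_prescreen_p, "gene_id"]
            .unique()
            .tolist()
        )
        X, _ = design_matrix(samples)
        expr_resid = whitened_residuals_batch(
            normed.values.to_numpy(float), X, samples.families
        )
        meth_resid = whitened_residuals_batch(
            meth.betas.loc[:, samples.sample_ids].to_numpy(float), X, samples.families
        )
        meth_res = meth_age_test(
            expr_resid,
            list(normed.feature_ids),
            normed.gene_ids,
            meth,
            meth_resid,
            ages,
            genes=prescreen_genes,
            p_threshold=config.meth_p_threshold,
        )
        written["meth_age"] = out / "meth_age.tsv"
        meth_res.to_csv(written["meth_age"], sep="\t", index=False)

    _stage("manifest")
    cfg_dict = dataclasses.asdict(config)
    manifest = {
        "version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "n_samples": len(samples.data),
        "n_features": int(len(normed.feature_ids)),
        "skipped_features": skipped,
        "outputs": {k: str(v) for k, v in written.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    written["manifest"] = out / "manifest.json"
    return written


def run_sharing(result_paths: dict[str, Path], out_path, alpha: float = 0.05) -> pd.DataFrame:
    """Directed pi1 matrix from per-tissue age-mean scan TSVs."""
    results = {
        name: pd.read_csv(path, sep="\t", index_col="feature_id")
        for name, path in result_paths.items()
    }
    mat = pi1_matrix(results, alpha=alpha)
    mat.to_csv(out_path, sep="\t", index_label="discovery")
    return mat
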