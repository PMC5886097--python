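"""Synthetic twin cohorts with known ground truth.

The generator emulates an adult female twin cohort of the kind used for
age-expression studies: MZ and DZ pairs plus singletons, ages uniform on a
configurable range (default 39-85 years, giving mean ~62... the midpoint),
co-twins sampled at the same visit and therefore at identical ages.  Every
effect the pipeline estimates has a configurable ground-truth knob:

* ``beta_age`` — linear age effect on the latent mean, in units of the
  residual sd per year (age is centred at the range midpoint);
* ACE structure — the non-age residual is split into additive genetic
  (shared by MZ co-twins, correlation 1/2 in DZ), common-environment
  (family-shared) and unique-environment fractions summing to one;
* ``var_slope`` / ``var_slope_shared`` — multiplicative change of the
  unique- resp. common-environment sd per year of age (1.0 = homoscedastic),
  anchored at the age midpoint;
* ``discordance_slope`` — sd per year of an individual-specific divergence
  term that grows from zero at the youngest age: non-shared environment
  accumulating over the lifespan, visible as MZ-pair discordance;
* cis SNP main and SNP-by-age effects; DZ co-twins share alleles through
  simulated parental haplotype transmission (exact pedigree logic, not a
  correlation shortcut), MZ co-twins share genotypes entirely;
* methylation probes in [0, 1] with probe and probe-by-age effects.

Latent gene signals map to integer counts through ``exp()``, per-sample
library scaling and Poisson rounding — the marginal count distribution is
irrelevant after rank-inverse-normalisation downstream, but count-like
integers exercise the normalisation code.  Exons of a gene share the
gene-level signal; a configurable fraction of the unique-environment noise
is exon-specific.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import (
    FeatureMatrix,
    GenotypeMatrix,
    MethylationMatrix,
    SampleTable,
    write_expression,
    write_methylation,
    write_sample_table,
    write_vcf,
)

FIXED_COVARIATES = ["insert_size", "gc_mean", "batch"]
RANDOM_COVARIATES = ["primer_index", "seq_date"]


@dataclass
class GeneEffectProfile:
    """Ground-truth effect sizes for one gene."""

    beta_age: float = 0.0
    var_slope: float = 1.0
    var_slope_shared: float = 1.0
    discordance_slope: float = 0.0
    sigma2_a: float = 0.3
    sigma2_c: float = 0.2
    sigma2_e: float = 0.5
    gxage: tuple | None = None              # (maf, beta_main, beta_interaction)
    meth_interaction: tuple | None = None   # (beta_meth, beta_meth_x_age)

    def validate(self) -> None:
        tot = self.sigma2_a + self.sigma2_c + self.sigma2_e
        if abs(tot - 1.0) > 1e-9:
            raise ConfigurationError(
                f"GeneEffectProfile: sigma2_a + sigma2_c + sigma2_e = {tot}, must be 1"
            )
        if min(self.sigma2_a, self.sigma2_c, self.sigma2_e) < 0:
            raise ConfigurationError("GeneEffectProfile: variance fractions must be >= 0")
        if self.var_slope <= 0 or self.var_slope_shared <= 0:
            raise ConfigurationError("GeneEffectProfile: var_slope must be > 0")
        if self.gxage is not None:
            maf = self.gxage[0]
            if not (0.05 <= maf <= 0.5):
                raise ConfigurationError(f"GeneEffectProfile: gxage maf {maf} outside [0.05, 0.5]")


@dataclass
class SimulationConfig:
    n_mz_pairs: int = 50
    n_dz_pairs: int = 50
    n_singletons: int = 0
    age_range: tuple = (39.0, 85.0)
    n_genes: int = 200
    exons_per_gene_range: tuple = (1, 4)
    exon_counts: list | None = None         # explicit per-gene counts, overrides the range
    effect_profiles: list | None = None     # None = all-null; length 1 broadcasts
    library_scale: float = 10_000_000.0
    seed: int = 0
    tissue: str = "skin"
    n_variants_per_gene: int = 5
    n_probes_per_gene: int = 3
    exon_corr: float = 0.5                  # gene-shared fraction of unique-env noise
    tech_effect_sd: float = 0.1             # effect of each technical covariate (sd units)

    def validate(self) -> None:
        lo, hi = self.age_range
        if not (18 <= lo < hi <= 110):
            raise ConfigurationError(f"SimulationConfig: age_range {self.age_range} invalid")
        for f in ("n_mz_pairs", "n_dz_pairs", "n_singletons", "n_genes"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"SimulationConfig: {f} must be >= 0")
        if self.n_mz_pairs + self.n_dz_pairs == 0:
            raise ConfigurationError("SimulationConfig: at least one pair type must be nonzero")
        e_lo, e_hi = self.exons_per_gene_range
        if not (1 <= e_lo <= e_hi):
            raise ConfigurationError(
                f"SimulationConfig: exons_per_gene_range {self.exons_per_gene_range} invalid"
            )
        if self.exon_counts is not None:
            if len(self.exon_counts) != self.n_genes or min(self.exon_counts) < 1:
                raise ConfigurationError(
                    "SimulationConfig: exon_counts must list one positive count per gene"
                )
        if not (0.0 <= self.exon_corr <= 1.0):
            raise ConfigurationError("SimulationConfig: exon_corr outside [0, 1]")
        if self.library_scale <= 0:
            raise ConfigurationError("SimulationConfig: library_scale must be > 0")

    def profiles(self) -> list[GeneEffectProfile]:
        if self.effect_profiles is None:
            profs = [GeneEffectProfile() for _ in range(self.n_genes)]
        elif len(self.effect_profiles) == 1:
            profs = [self.effect_profiles[0]] * self.n_genes
        elif len(self.effect_profiles) == self.n_genes:
            profs = list(self.effect_profiles)
        else:
            raise ConfigurationError(
                "SimulationConfig: effect_profiles must be None, length 1 or length n_genes "
                f"(got {len(self.effect_profiles)} for {self.n_genes} genes)"
            )
        for p in profs:
            p.validate()
        return profs


@dataclass
class CohortDataset:
    samples: SampleTable
    expression: FeatureMatrix
    genotypes: GenotypeMatrix
    methylation: MethylationMatrix
    truth: pd.DataFrame                 # per-gene ground-truth parameters
    latent: pd.DataFrame                # noise-free mechanism, features x samples
    haplotypes: np.ndarray              # (variants, samples, 2)
    config: SimulationConfig


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Draw one cohort; the seed fully determines the output."""
    config.validate()
    profiles = config.profiles()
    rng = np.random.default_rng(config.seed)
    lo, hi = map(float, config.age_range)
    age_mid = 0.5 * (lo + hi)

    # ---- families and samples -------------------------------------------
    fam_types = ["MZ"] * config.n_mz_pairs + ["DZ"] * config.n_dz_pairs + [
        "singleton"
    ] * config.n_singletons
    rows = []
    fam_of_sample: list[int] = []
    twin_of: list[int] = []             # index of co-twin, -1 for singletons
    for f, ztype in enumerate(fam_types):
        age = rng.uniform(lo, hi)
        n_in_fam = 2 if ztype in ("MZ", "DZ") else 1
        first = len(rows)
        for t in range(n_in_fam):
            sid = f"S{len(rows):04d}"
            rows.append(
                {
                    "sample_id": sid,
                    "individual_id": f"I{len(rows):04d}",
                    "family_id": f"F{f:04d}",
                    "zygosity": ztype,
                    "age": age,
                    "tissue": config.tissue,
                    "sex": "F",
                }
            )
            fam_of_sample.append(f)
            twin_of.append(first + 1 - t if n_in_fam == 2 else -1)
    n = len(rows)
    meta = pd.DataFrame(rows)
    ages = meta["age"].to_numpy()
    age_c = ages - age_mid
    fam_idx = np.asarray(fam_of_sample)
    n_fam = len(fam_types)
    is_mz = np.array([fam_types[f] == "MZ" for f in fam_idx])
    is_pair = np.array([fam_types[f] != "singleton" for f in fam_idx])

    # technical covariates: fixed (insert size, GC, batch) and random
    # grouping factors (primer index, sequencing date)
    meta["insert_size"] = rng.normal(300.0, 20.0, n)
    meta["gc_mean"] = rng.normal(0.52, 0.02, n)
    meta["batch"] = rng.choice(["b1", "b2"], n)
    meta["primer_index"] = rng.choice([f"p{i}" for i in range(8)], n)
    meta["seq_date"] = rng.choice([f"d{i}" for i in range(6)], n)
    tech = (
        config.tech_effect_sd * (meta["insert_size"] - 300.0).to_numpy() / 20.0
        + config.tech_effect_sd * (meta["gc_mean"] - 0.52).to_numpy() / 0.02
        + config.tech_effect_sd * (meta["batch"] == "b2").to_numpy(dtype=float)
    )

    samples = SampleTable(
        meta.set_index("sample_id"),
        fixed_covariates=list(FIXED_COVARIATES),
        random_covariates=list(RANDOM_COVARIATES),
    )

    # ---- genotypes through parental transmission ------------------------
    n_var = config.n_genes * config.n_variants_per_gene
    var_ann_rows = []
    mafs = np.empty(n_var)
    gene_tss = {}
    vi = 0
    for g, prof in enumerate(profiles):
        gene_id = f"G{g:04d}"
        tss = 1_000_000 + g * 3_000_000
        gene_tss[gene_id] = tss
        for k in range(config.n_variants_per_gene):
            if k == 0 and prof.gxage is not None:
                maf = float(prof.gxage[0])
            else:
                maf = float(rng.uniform(0.05, 0.5))
            pos = int(tss + rng.integers(-500_000, 500_001))
            vid = f"G{g:04d}_v{k}"
            var_ann_rows.append((vid, "chr1", pos, "A", "G", gene_id, maf))
            mafs[vi] = maf
            vi += 1
    # parental haplotypes (m1 m2 | f1 f2) per family and variant; each child
    # receives one maternal and one paternal allele; MZ co-twins share the
    # transmission draw, DZ co-twins draw independently
    par = rng.random((n_var, n_fam, 4)) < mafs[:, None, None]      # (V, fam, 4)
    m_choice = rng.integers(0, 2, size=(n_var, n))
    f_choice = rng.integers(0, 2, size=(n_var, n))
    twin_arr = np.asarray(twin_of)
    mz_second = np.flatnonzero(is_mz & (twin_arr >= 0) & (twin_arr < np.arange(n)))
    m_choice[:, mz_second] = m_choice[:, twin_arr[mz_second]]
    f_choice[:, mz_second] = f_choice[:, twin_arr[mz_second]]
    vidx = np.arange(n_var)[:, None]
    hap = np.empty((n_var, n, 2), dtype=np.int8)
    hap[:, :, 0] = par[vidx, fam_idx[None, :], m_choice]
    hap[:, :, 1] = par[vidx, fam_idx[None, :], 2 + f_choice]
    var_ann = pd.DataFrame(
        var_ann_rows, columns=["variant_id", "chrom", "pos", "ref", "alt", "gene_id", "true_maf"]
    ).set_index("variant_id")
    dosages = hap.sum(axis=2).astype(float)
    genotypes = GenotypeMatrix(
        pd.DataFrame(dosages, index=var_ann.index, columns=meta["sample_id"]),
        var_ann.drop(columns=["gene_id", "true_maf"]).assign(
            gene_id=var_ann["gene_id"], true_maf=var_ann["true_maf"]
        ),
    )

    # ---- methylation probes ---------------------------------------------
    probe_rows, probe_betas = [], []
    for g, prof in enumerate(profiles):
        gene_id = f"G{g:04d}"
        for k in range(config.n_probes_per_gene):
            z = rng.normal(rng.uniform(-1.5, 1.5), 1.0, n)
            beta = 1.0 / (1.0 + np.exp(-z))
            probe_rows.append(
                (f"cg_{gene_id}_{k}", "chr1", gene_tss[gene_id] + 100 * k, gene_id)
            )
            probe_betas.append(beta)
    probe_ann = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "pos", "gene_id"]
    ).set_index("probe_id")
    beta_arr = np.array(probe_betas) if probe_betas else np.zeros((0, n))
    meth = MethylationMatrix(
        pd.DataFrame(beta_arr, index=probe_ann.index, columns=meta["sample_id"]),
        probe_ann,
    )

    # ---- latent expression ----------------------------------------------
    if config.exon_counts is not None:
        n_exons = np.asarray(config.exon_counts, dtype=int)
    else:
        n_exons = rng.integers(
            config.exons_per_gene_range[0], config.exons_per_gene_range[1] + 1, config.n_genes
        )
    feat_rows, latent_rows, count_mu_rows = [], [], []
    truth_rows = []
    for g, prof in enumerate(profiles):
        gene_id = f"G{g:04d}"
        tss = gene_tss[gene_id]
        # deterministic mechanism (gene level)
        signal = prof.beta_age * age_c + tech
        causal_variant = causal_probe = ""
        if prof.gxage is not None:
            _, beta_main, beta_int = prof.gxage
            vid = f"G{g:04d}_v0"
            gdos = genotypes.dosages.loc[vid].to_numpy()
            signal = signal + beta_main * gdos + beta_int * gdos * age_c
            causal_variant = vid
        if prof.meth_interaction is not None:
            beta_meth, beta_mx = prof.meth_interaction
            pid = f"cg_{gene_id}_0"
            mvals = meth.betas.loc[pid].to_numpy()
            signal = signal + beta_meth * mvals + beta_mx * mvals * age_c
            causal_probe = pid

        # ACE noise (gene level, shared across exons)
        sa, sc, se = prof.sigma2_a, prof.sigma2_c, prof.sigma2_e
        a_shared = rng.normal(0.0, 1.0, n_fam)[fam_idx]
        a_own = rng.normal(0.0, 1.0, n)
        a = np.where(
            is_mz | ~is_pair,
            a_shared * np.sqrt(sa),
            a_shared * np.sqrt(sa / 2.0) + a_own * np.sqrt(sa / 2.0),
        )
        c_scale = np.sqrt(sc) * prof.var_slope_shared**age_c
        c = rng.normal(0.0, 1.0, n_fam)[fam_idx] * c_scale
        d = rng.normal(0.0, 1.0, n) * prof.discordance_slope * (ages - lo)
        e_scale = np.sqrt(se) * prof.var_slope**age_c
        e_gene = rng.normal(0.0, 1.0, n) * e_scale * np.sqrt(config.exon_corr)

        base = signal + a + c + d + e_gene
        for k in range(n_exons[g]):
            e_exon = rng.normal(0.0, 1.0, n) * e_scale * np.sqrt(1.0 - config.exon_corr)
            latent = base + e_exon
            fid = f"G{g:04d}_e{k}"
            start = tss + 1000 * k
            feat_rows.append((fid, gene_id, "exon", "chr1", start, start + 200, "+", tss))
            latent_rows.append(signal)
            log_level = rng.uniform(np.log(50.0), np.log(500.0))
            count_mu_rows.append(np.exp(log_level + latent))
        truth_rows.append(
            {
                "gene_id": gene_id,
                "n_exons": int(n_exons[g]),
                "beta_age": prof.beta_age,
                "var_slope": prof.var_slope,
                "var_slope_shared": prof.var_slope_shared,
                "discordance_slope": prof.discordance_slope,
                "sigma2_a": sa,
                "sigma2_c": sc,
                "sigma2_e": se,
                "gxage_variant": causal_variant,
                "gxage_beta_main": prof.gxage[1] if prof.gxage else 0.0,
                "gxage_beta_interaction": prof.gxage[2] if prof.gxage else 0.0,
                "meth_probe": causal_probe,
                "beta_meth": prof.meth_interaction[0] if prof.meth_interaction else 0.0,
                "beta_meth_x_age": prof.meth_interaction[1] if prof.meth_interaction else 0.0,
            }
        )

    feat_ann = pd.DataFrame(
        feat_rows,
        columns=["feature_id", "gene_id", "feature_kind", "chrom", "start", "end", "strand", "tss"],
    ).set_index("feature_id")
    mu = np.array(count_mu_rows) if count_mu_rows else np.zeros((0, n))
    depth = rng.uniform(0.8, 1.2, n)                # sequencing-depth variation
    col_tot = mu.sum(axis=0)
    lam = mu * (config.library_scale * depth / np.maximum(col_tot, 1e-300))
    counts = rng.poisson(lam).astype(float)
    expression = FeatureMatrix(
        pd.DataFrame(counts, index=feat_ann.index, columns=meta["sample_id"]), feat_ann
    )
    latent_arr = np.array(latent_rows) if latent_rows else np.zeros((0, n))
    latent = pd.DataFrame(latent_arr, index=feat_ann.index, columns=meta["sample_id"])
    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "n_exons", "beta_age", "var_slope", "var_slope_shared",
        "discordance_slope", "sigma2_a", "sigma2_c", "sigma2_e",
        "gxage_variant", "gxage_beta_main", "gxage_beta_interaction",
        "meth_probe", "beta_meth", "beta_meth_x_age",
    ]).set_index("gene_id")
    return CohortDataset(
        samples=samples,
        expression=expression,
        genotypes=genotypes,
        methylation=meth,
        truth=truth,
        latent=latent,
        haplotypes=hap,
        config=config,
    )


# ---------------------------------------------------------------------------
# persistence


def write_cohort(dataset: CohortDataset, directory) -> dict[str, Path]:
    """Write all cohort files; round-trips losslessly through the readers."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": d / "samples.tsv",
        "expression": d / "expression.tsv",
        "features": d / "features.tsv",
        "vcf": d / "genotypes.vcf",
        "methylation": d / "methylation.tsv",
        "probes": d / "probes.tsv",
        "truth": d / "truth.tsv",
        "latent": d / "latent.tsv",
        "config": d / "config.json",
    }
    write_sample_table(dataset.samples, paths["samples"])
    write_expression(dataset.expression, paths["expression"], paths["features"])
    write_vcf(dataset.genotypes, paths["vcf"], haplotypes=dataset.haplotypes)
    write_methylation(dataset.methylation, paths["methylation"], paths["probes"])
    dataset.truth.reset_index().to_csv(paths["truth"], sep="\t", index=False)
    dataset.latent.to_csv(paths["latent"], sep="\t", index_label="feature_id")
    import json

    cfg = dataclasses.asdict(dataset.config)
    cfg["effect_profiles"] = (
        None
        if dataset.config.effect_profiles is None
        else [dataclasses.asdict(p) for p in dataset.config.effect_profiles]
    )
    paths["config"].write_text(json.dumps(cfg, indent=2, default=list))
    return paths
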