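import numpy as np
import pandas as pd
import pytest

from twinage.io import SampleTable
from twinage.simulate import GeneEffectProfile, SimulationConfig, simulate_cohort


def make_twin_samples(n_mz: int, n_dz: int, n_singletons: int = 0, seed: int = 0) -> SampleTable:
    """A minimal twin sample table with uniform ages on 39-85."""
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_mz + n_dz):
        zyg = "MZ" if f < n_mz else "DZ"
        age = rng.uniform(39, 85)
        for t in range(2):
            k = len(rows)
            rows.append(
                dict(sample_id=f"S{k:04d}", individual_id=f"I{k:04d}",
                     family_id=f"F{f:04d}", zygosity=zyg, age=age, tissue="skin")
            )
    for s in range(n_singletons):
        k = len(rows)
        rows.append(
            dict(sample_id=f"S{k:04d}", individual_id=f"I{k:04d}",
                 family_id=f"FS{s:04d}", zygosity="singleton",
                 age=rng.uniform(39, 85), tissue="skin")
        )
    return SampleTable(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture(scope="session")
def twin_samples() -> SampleTable:
    return make_twin_samples(60, 60, 10, seed=1)


@pytest.fixture(scope="session")
def null_cohort():
    """A small all-null synthetic cohort reused across read-only tests."""
    cfg = SimulationConfig(
        n_mz_pairs=40, n_dz_pairs=40, n_singletons=5, n_genes=30,
        exons_per_gene_range=(1, 3), n_variants_per_gene=3, n_probes_per_gene=2, seed=7,
    )
    return simulate_cohort(cfg)

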