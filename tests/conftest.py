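import numpy as np
import pandas as pd
import pytest

from ardsomics.synthetic_cohort import CohortConfig, generate_cohort


def small_config(**overrides) -> CohortConfig:
    """A scaled-down cohort: fast to generate, same structure as default."""
    base = dict(
        n_subjects_total=120,
        n_per_omic={"genetics": 100, "rnaseq": 40, "longitudinal": 60,
                    "methylation": 40, "protein": 100},
        n_snps=300,
        n_genes=80,
        n_probes=160,
        planted_module_size=6,
        seed=0,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    cfg = small_config(seed=11)
    bundle, truth = generate_cohort(cfg)
    return bundle, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def two_group_expr(rng, n_genes=50, n_per_group=10, seed_genes=()):
    """Gene x sample normal matrix with optional planted group-1 offsets."""
    cols = [f"s{j}" for j in range(2 * n_per_group)]
    x = rng.normal(0.0, 1.0, (n_genes, len(cols)))
    genes = [f"g{i}" for i in range(n_genes)]
    for gi, offset in seed_genes:
        x[gi, :n_per_group] += offset
    groups = pd.Series([1] * n_per_group + [0] * n_per_group, index=cols)
    return pd.DataFrame(x, index=genes, columns=cols), groups
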