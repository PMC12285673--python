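import numpy as np
import pandas as pd
import pytest

from amygrs import CohortDataset, SimulationConfig, simulate_study


def make_dataset(dosages, phenotype=None, cohort_name="toy", *, pos=None,
                 chrom=None, effect=None, other=None, age=None, sex=None,
                 phenotype_type="quantitative"):
    """Hand-build a CohortDataset from a dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
        "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
        "effect_allele": effect if effect is not None else ["A"] * m,
        "other_allele": other if other is not None else ["G"] * m,
    })
    rng = np.random.default_rng(0)
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "phenotype": phenotype if phenotype is not None else np.full(n, np.nan),
        "age": age if age is not None else rng.normal(70, 8, n),
        "sex": sex if sex is not None else rng.integers(0, 2, n).astype(float),
    })
    return CohortDataset(cohort_name=cohort_name, dosages=dosages,
                         variants=variants, samples=samples,
                         phenotype_type=phenotype_type)


@pytest.fixture(scope="session")
def tiny_study():
    """A small four-cohort synthetic study shared across tests."""
    config = SimulationConfig(
        seed=11, m_variants=2000,
        n_per_cohort={"discovery_a": 300, "discovery_b": 250,
                      "neuropath": 200, "plasma": 200})
    return config, simulate_study(config)
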