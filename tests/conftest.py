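import numpy as np
import pytest
from hypothesis import settings

import evcargo as ev

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


def make_matrix(counts, models=None, compartments=None, phenotypes=None, replicates=None,
                feature_ids=None):
    """Build a CountMatrix from an array plus per-sample design vectors."""
    counts = np.asarray(counts)
    n_feat, n_samp = counts.shape
    models = models or ["NSCLC"] * n_samp
    compartments = compartments or ["cell"] * n_samp
    phenotypes = phenotypes or ["sensitive"] * n_samp
    replicates = replicates or list(range(1, n_samp + 1))
    samples = [
        ev.SampleInfo(label=f"{m}_{c}_{p}_r{r}", model=m, compartment=c,
                      phenotype=p, replicate=r)
        for m, c, p, r in zip(models, compartments, phenotypes, replicates)
    ]
    return ev.CountMatrix(
        feature_ids=feature_ids or [f"F{i:03d}" for i in range(1, n_feat + 1)],
        counts=counts,
        samples=samples,
    )


def two_group_matrix(counts_a, counts_b):
    """6-sample sensitive/MDR cell matrix from two (features x 3) blocks."""
    counts = np.column_stack([counts_a, counts_b])
    return make_matrix(
        counts,
        phenotypes=["sensitive"] * 3 + ["MDR"] * 3,
        replicates=[1, 2, 3, 1, 2, 3],
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study under generator defaults."""
    return ev.generate_dataset(ev.SimConfig(rng_seed=42))


@pytest.fixture(scope="session")
def null_dataset():
    """Synthetic study with no planted MDR effects (null for the DE test)."""
    cfg = ev.SimConfig(de_fraction=0.0, ev_de_fraction=0.0, rng_seed=11)
    return ev.generate_dataset(cfg)
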