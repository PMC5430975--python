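import numpy as np
import pandas as pd
import pytest

from hepanet.datasets import CountDataset
from hepanet.simulate import ModuleSpec, SimulationConfig, generate_dataset


def make_dataset(rng: np.random.Generator, n_genes=50, n_samples=6,
                 n_batches=2) -> CountDataset:
    """Small random count bundle with no planted structure."""
    gene_ids = pd.Index([f"G{i:03d}" for i in range(n_genes)], name="gene_id")
    sample_ids = pd.Index([f"S{i:02d}" for i in range(n_samples)], name="sample_id")
    counts = pd.DataFrame(rng.poisson(50, size=(n_genes, n_samples)),
                          index=gene_ids, columns=sample_ids)
    lengths = pd.Series(rng.integers(200, 5000, size=n_genes), index=gene_ids,
                        name="length_bp")
    half = n_samples // 2
    samples = pd.DataFrame({
        "treatment": ["FBZ"] * half + ["UNT"] * (n_samples - half),
        "breed": [["D", "H", "L", "Y"][i % 4] for i in range(n_samples)],
        "sex": [["F", "CM"][i % 2] for i in range(n_samples)],
        "batch": [(i % n_batches) + 1 for i in range(n_samples)],
    }, index=sample_ids)
    return CountDataset(counts=counts, gene_lengths=lengths, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    return make_dataset(rng)


@pytest.fixture(scope="session")
def planted_arm():
    """One simulated arm with two strong planted modules, reused across tests."""
    specs = (
        ModuleSpec("M1", 60, 0.9, -0.5, 0.5, "CL"),
        ModuleSpec("M2", 40, 0.9, 0.5, 0.5, "TMAX"),
    )
    cfg = SimulationConfig(n_genes=400, module_specs=specs, seed=777)
    dataset, truth = generate_dataset(cfg)
    return cfg, dataset, truth
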