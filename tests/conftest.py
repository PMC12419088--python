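import numpy as np
import pandas as pd
import pytest

import cortexlayers as cl


@pytest.fixture(scope="session")
def manifest():
    return cl.build_manifest()


@pytest.fixture(scope="session")
def dataset(manifest):
    """Default study-condition simulation (batch effects + MNAR on)."""
    matrix, truth = cl.simulate_abundance(cl.GeneratorConfig(seed=7), manifest)
    return matrix, truth


@pytest.fixture(scope="session")
def corrected(manifest, dataset):
    """Median-normalized, two-pass batch-corrected default matrix."""
    matrix, truth = dataset
    norm = cl.normalize_median(matrix)
    refs = cl.default_reference_classes(manifest)
    out = cl.batch_correct(norm, manifest, "la_batch", references=refs)
    out = cl.batch_correct(out, manifest, "m_batch")
    return out, truth


@pytest.fixture(scope="session")
def clean_dataset(manifest):
    """Noise-free simulation without batches or missingness."""
    cfg = cl.GeneratorConfig(
        seed=7, noise_sd=0.0,
        batch_effects=cl.BatchEffectConfig(enabled=False),
        missingness=cl.MissingnessConfig(enabled=False))
    matrix, truth = cl.simulate_abundance(cfg, manifest)
    return matrix, truth


@pytest.fixture(scope="session")
def cells_data():
    return cl.simulate_cells(seed=7)


def toy_matrix(values, proteins=None, samples=None):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"prot{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=proteins, columns=samples)
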