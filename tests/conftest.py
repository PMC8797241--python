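import numpy as np
import pandas as pd
import pytest

from coexqc.simulate import SimulationConfig, generate_annotations, generate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset with modules, batch effects and annotations."""
    cfg = SimulationConfig(
        n_genes=400,
        n_samples=80,
        n_batches=4,
        n_modules=8,
        module_size=20,
        batch_loc_sd=0.6,
        seed=3,
    )
    dataset, truth = generate_dataset(cfg)
    annotations = generate_annotations(cfg, truth)
    return cfg, dataset, truth, annotations


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def log_matrix_factory():
    """Factory for log-scale ExpressionMatrix objects from an array."""
    from coexqc.data import ExpressionMatrix

    def make(values, genes=None, samples=None):
        values = np.asarray(values, dtype=float)
        genes = genes or [f"g{i:04d}" for i in range(values.shape[0])]
        samples = samples or [f"s{j:04d}" for j in range(values.shape[1])]
        frame = pd.DataFrame(values, index=genes, columns=samples)
        return ExpressionMatrix(frame, provenance=["normalize:UQ", "log2(pseudocount=1)"], is_log=True)

    return make
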