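import numpy as np
import pandas as pd
import pytest

from lvgwas.panel import GenotypePanel
from lvgwas.synthetic import SimulationConfig, simulate_genotypes


def make_panel(dosages: np.ndarray, chrom=None, pos=None, maf=None, info=None) -> GenotypePanel:
    """Construct a panel around an explicit dosage matrix for unit tests."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    af = dosages.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "maf": maf if maf is not None else np.minimum(af, 1 - af),
            "info": info if info is not None else np.ones(m),
            "call_rate": np.ones(m),
        }
    )
    return GenotypePanel(dosages=dosages, variants=variants)


@pytest.fixture(scope="session")
def small_panel() -> GenotypePanel:
    """500 samples x 120 variants with moderate within-block LD."""
    cfg = SimulationConfig(
        n_samples=500, n_variants=120, ld_block_size=10, within_block_r=0.6,
        maf_range=(0.05, 0.5), seed=7,
    )
    return simulate_genotypes(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    # fresh generator per test so tests stay order-independent
    return np.random.default_rng(2024)
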