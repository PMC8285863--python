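import numpy as np
import pandas as pd
import pytest

from eqtplot import AnalysisConfig
from eqtplot.simulate import SimulationParams, simulate_locus


@pytest.fixture(scope="session")
def shared_sim():
    """A colocalizing synthetic locus (shared causal variant), seed-fixed."""
    return simulate_locus(SimulationParams(seed=11))


@pytest.fixture(scope="session")
def distinct_sim():
    """A non-colocalizing locus: eQTL causal variant in a different block."""
    return simulate_locus(SimulationParams(seed=11, shared_causal=False))


@pytest.fixture()
def default_config():
    return AnalysisConfig(gene="GENE1", trait="TRAIT", saveplot=False)


@pytest.fixture()
def small_eqtl():
    """Hand-sized multi-tissue eQTL table for collapse tests."""
    return pd.DataFrame({
        "snp": ["rs1", "rs1", "rs2", "rs2", "rs3"],
        "gene": "G",
        "p_eqtl": [0.01, 0.2, 0.5, 0.04, 0.9],
        "nes": [0.5, -0.3, 0.1, -0.8, 0.2],
        "tissue": ["Liver", "Blood", "Liver", "Blood", "Liver"],
        "n": [100.0, 200.0, 100.0, 200.0, 100.0],
    })


@pytest.fixture()
def locus_frame():
    """Minimal joined locus table for statistics tests."""
    rng = np.random.default_rng(5)
    n = 40
    p_gwas = np.concatenate([rng.uniform(1e-12, 1e-9, 8),
                             rng.uniform(1e-4, 1, n - 8)])
    has_eqtl = np.concatenate([np.ones(6, bool), np.zeros(2, bool),
                               rng.random(n - 8) < 0.3])
    p_eqtl = np.where(has_eqtl, rng.uniform(1e-10, 0.05, n), np.nan)
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(n)],
        "bp": 1000 + np.arange(n),
        "p_gwas": p_gwas,
        "beta": rng.normal(size=n),
        "has_eqtl": has_eqtl,
        "p_eqtl": p_eqtl,
        "nes": np.where(has_eqtl, rng.normal(size=n), np.nan),
        "congruence_class": "not_applicable",
        "gwas_significant": p_gwas < 5e-8,
    })
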