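import numpy as np
import pandas as pd
import pytest

from pleioscan import gwas_io


@pytest.fixture(scope="session")
def small_panel() -> gwas_io.GenotypePanel:
    """20 samples x 12 SNPs with mild LD, generated programmatically."""
    rng = np.random.default_rng(42)
    n, m = 20, 12
    latent = rng.standard_normal((n, 3))
    dos = np.empty((n, m))
    for j in range(m):
        liability = latent[:, j % 3] + 0.8 * rng.standard_normal(n)
        dos[:, j] = np.digitize(liability, [-0.5, 0.7])
    # ensure polymorphism
    dos[0] = (dos[0] + 1) % 3
    dos[1] = (dos[1] + 2) % 3
    meta = pd.DataFrame({
        "SNP": [f"rs{i+1}" for i in range(m)],
        "CHR": "1",
        "BP": np.arange(1, m + 1) * 500,
        "A1": "A",
        "A2": "G",
    })
    return gwas_io.GenotypePanel(meta, dos)


@pytest.fixture(scope="session")
def block_ld_small() -> gwas_io.LdInfo:
    """2000 SNPs in equicorrelated blocks of 10 (rho drawn per block)."""
    return gwas_io.block_ld_info(2000, 10, (0.1, 0.8), seed=9)


def make_sumstats(z: np.ndarray, n: float = 10000.0, trait_id: str = "t") -> gwas_io.SummaryStats:
    from scipy import stats as sps
    m = len(z)
    table = pd.DataFrame({
        "SNP": [f"rs{i+1}" for i in range(m)],
        "CHR": "1",
        "BP": np.arange(1, m + 1) * 1000,
        "A1": "A",
        "A2": "G",
        "Z": np.asarray(z, dtype=float),
        "N": float(n),
        "P": 2.0 * sps.norm.sf(np.abs(z)),
    })
    return gwas_io.SummaryStats(trait_id, table)
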