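import numpy as np
import pandas as pd
import pytest

from vmrscan.core_io import BetaMatrix, ProbeManifest
from vmrscan.synthetic import SimConfig, simulate_manifest, simulate_population


@pytest.fixture
def tiny_manifest() -> ProbeManifest:
    """Hand-built manifest: two chromosomes, one 3-probe cluster each plus
    an isolated probe."""
    return ProbeManifest(pd.DataFrame({
        "probe_id": [f"cg{i}" for i in range(8)],
        "chrom": ["chr1"] * 4 + ["chr2"] * 4,
        "pos": [100, 500, 900, 2500, 1000, 1200, 1400, 9000],
    }))


@pytest.fixture
def small_sim_config() -> SimConfig:
    """Reduced study conditions for fast per-test simulation."""
    return SimConfig(n_chrom=3, probes_per_chrom=800, n_planted_vmrs=15,
                     n_trans_modules=3, vmrs_per_module=4, n_sex_clusters=5,
                     seed=11)


@pytest.fixture
def small_population(small_sim_config):
    manifest, clusters = simulate_manifest(small_sim_config)
    beta, truth = simulate_population(manifest, clusters, small_sim_config)
    return manifest, clusters, beta, truth


def make_beta(values: np.ndarray, probe_ids=None, sexes=None) -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    probe_ids = probe_ids or [f"cg{j}" for j in range(m)]
    samples = [f"S{i}" for i in range(n)]
    meta = pd.DataFrame(index=samples)
    if sexes is not None:
        meta["sex"] = sexes
    return BetaMatrix(pd.DataFrame(values, index=samples, columns=probe_ids), meta)
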