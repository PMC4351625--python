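import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from epidiff.matrix import MethylomeMatrix
from epidiff.synthetic import SimulationConfig, simulate_study

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def make_matrix(rows, samples):
    """Build a MethylomeMatrix from (chrom, pos, strand, context,
    [(meth, cov) per sample]) tuples."""
    sites = pd.DataFrame(
        [r[:4] for r in rows], columns=["chrom", "pos", "strand", "context"])
    meth = np.array([[mc[0] for mc in r[4]] for r in rows], dtype=np.int64)
    cov = np.array([[mc[1] for mc in r[4]] for r in rows], dtype=np.int64)
    order = sites.sort_values(["chrom", "pos", "strand"]).index.to_numpy()
    return MethylomeMatrix(sites.loc[order].reset_index(drop=True),
                           list(samples), meth[order], cov[order])


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(
        n_chroms=1, chrom_length=300_000, pericentromere_halfwidth=60_000,
        n_genes=30, gene_length=(1_000, 3_000), n_transposons=25,
        te_length=(800, 2_500), seed=11)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config)


@pytest.fixture(scope="session")
def default_study():
    return simulate_study(SimulationConfig(seed=7))
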