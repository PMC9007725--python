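import numpy as np
import pandas as pd
import pytest

from capmeth.simulate import SimConfig, simulate_run


@pytest.fixture(scope="session")
def small_run():
    """One shared desk-scale simulated run (500 regions, tumour groups only)."""
    cfg = SimConfig(
        n_regions=500, n_gh=6, n_nfpa=6, n_normal=2, seed=7,
        chrom_length=1_500_000, n_islands_per_chrom=20,
    )
    genome, regions, sheet, counts, truth = simulate_run(cfg)
    return {
        "config": cfg, "genome": genome, "regions": regions,
        "samplesheet": sheet, "counts": counts, "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def table1():
    from capmeth.cohort import load_table1

    return load_table1()


def make_samplesheet(n_a: int, n_b: int, group_a: str = "NFPA", group_b: str = "GH") -> pd.Series:
    ids = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    groups = [group_a] * n_a + [group_b] * n_b
    return pd.Series(groups, index=pd.Index(ids, name="sample_id"), name="group")
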