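import numpy as np
import pandas as pd
import pytest

import evoherit as ev


def small_config(seed=0, **over):
    """A reduced cross: 120 founders, 4 chromosomes, 3 QTLs."""
    base = dict(
        n_founders=120,
        chromosome_lengths=(30,) * 4,
        qtl_spec=((10, 0.09, 0.19), (45, 0.05, 0.06), (100, 0.03, 0.04)),
        focal_locus=10,
        seed=seed,
    )
    base.update(over)
    return ev.default_config(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return ev.simulate_dataset(small_config(seed=11))


@pytest.fixture(scope="session")
def small_geno(small_dataset):
    return small_dataset.genotypes


def hand_site_table():
    """10 sites × 10 populations with known filter/call outcomes.

    Site layout (depth 10 unless noted):
      0: alt majority (6/10 reads) in 6 pops          -> stage 1
      1: alt majority in 5 pops only                  -> survives stage 1;
         those 5 pops are also >10%                   -> stage 2
      2: alt at 15% (3/20) in exactly 5 pops          -> stage 2
      3: alt at 15% in 4 pops                         -> retained, no calls
      4: clean call in pop 0: 8/10 alt                -> one call
      5: 3 alt of 5 (60%) in pop 1                    -> support < 4, no call
      6: 4 alt of 8 (50%) in pop 2                    -> not > 50%, no call
      7: 4 alt of 6 (66.7%) in pop 3                  -> one call
      8: zero depth everywhere except a call in pop 4 -> one call
      9: all reference                                -> retained, no calls
    """
    n_sites, n_pops = 10, 10
    ref = np.full((n_sites, n_pops), 10, dtype=int)
    alt = np.zeros((n_sites, n_pops), dtype=int)
    for p in range(6):
        ref[0, p], alt[0, p] = 4, 6
    for p in range(5):
        ref[1, p], alt[1, p] = 4, 6
    for p in range(5):
        ref[2, p], alt[2, p] = 17, 3
    for p in range(4):
        ref[3, p], alt[3, p] = 17, 3
    ref[4, 0], alt[4, 0] = 2, 8
    ref[5, 1], alt[5, 1] = 2, 3
    ref[6, 2], alt[6, 2] = 4, 4
    ref[7, 3], alt[7, 3] = 2, 4
    ref[8, :], alt[8, :] = 0, 0
    ref[8, 4], alt[8, 4] = 1, 9
    sites = pd.DataFrame(
        {
            "chrom": "chr01",
            "pos": np.arange(1, n_sites + 1) * 100,
            "ref": "A",
            "alt": "T",
        }
    )
    pops = [f"P{i}" for i in range(n_pops)]
    return ev.SiteCountTable(sites=sites, populations=pops, ref_counts=ref,
                             alt_counts=alt)


@pytest.fixture
def site_table():
    return hand_site_table()
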