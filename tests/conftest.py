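import numpy as np
import pandas as pd
import pytest

from selboa.containers import OriginAssignment, PhasedGenotypes
from selboa.simdata import SimConfig, simulate


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A fast, fully-featured simulation for unit tests."""
    base = dict(
        n_snp=600, n_qtl=120, n_chrom=6, founders_per_breed=80,
        generations_purebred=2, n_sires_S=12, n_dams_LR=40, n_dams_LW=40,
        n_f1_dams=30, n_crossbred=150, n_major_qtl=8, seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture(scope="session")
def small_pooled(small_sim):
    return small_sim.pooled_genotypes()


def make_genotypes(haps: np.ndarray, ids=None, chrom=None) -> PhasedGenotypes:
    """Hand-built PhasedGenotypes from an (n, 2, m) allele array."""
    haps = np.asarray(haps, dtype=np.uint8)
    n, _, m = haps.shape
    if ids is None:
        ids = [f"a{i}" for i in range(n)]
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    pos = np.concatenate([np.arange(1, (chrom == c).sum() + 1)
                          for c in pd.unique(pd.Series(chrom))])
    mmap = pd.DataFrame({"chrom": chrom, "pos": pos,
                         "snp_id": [f"s{j}" for j in range(m)]})
    return PhasedGenotypes(animal_ids=list(ids), marker_map=mmap, haplotypes=haps)


def make_origins(labels: np.ndarray, ids=None, snp_ids=None) -> OriginAssignment:
    labels = np.asarray(labels, dtype=np.int8)
    n, _, m = labels.shape
    if ids is None:
        ids = [f"a{i}" for i in range(n)]
    if snp_ids is None:
        snp_ids = np.array([f"s{j}" for j in range(m)])
    return OriginAssignment(animal_ids=list(ids), snp_ids=np.asarray(snp_ids),
                           labels=labels)
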