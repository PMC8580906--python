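"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pytest

from omicpred.kernels import GenotypeMatrix, compute_grm, stabilize_kernel
from omicpred.simdata import EnvCovariance, SimConfig, TraitArchitecture, simulate_genotypes


@pytest.fixture(scope="session")
def small_panels():
    """Two panels with LD, divergence and shared lines (desk scale)."""
    cfg = SimConfig(
        n_lines_pop1=200,
        n_lines_pop2=150,
        n_shared=20,
        n_chrom=3,
        markers_per_chrom=120,
        ld_rho=0.6,
        fst=0.15,
        seed=42,
    )
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def geno(small_panels):
    return small_panels[0]


@pytest.fixture(scope="session")
def grm(geno):
    return stabilize_kernel(compute_grm(geno))


@pytest.fixture()
def toy_geno():
    """3 lines x 4 markers, hand-checkable."""
    dos = np.array(
        [
            [0.0, 1.0, 2.0, 0.0],
            [2.0, 1.0, 0.0, 0.0],
            [0.0, 2.0, 2.0, 2.0],
        ]
    )
    return GenotypeMatrix(dos, ["a", "b", "c"], ["m1", "m2", "m3", "m4"])


@pytest.fixture(scope="session")
def oligo_arch():
    """A major-QTL architecture driving module 0 of the feature simulator."""
    return TraitArchitecture(
        qtl_ids=[60],
        qtl_effects=[1.0],
        major_qtl_id=60,
        h2_target=0.6,
        polygenic_var=0.4,
        pleiotropy_map={60: [0]},
    )


@pytest.fixture(scope="session")
def env3():
    return EnvCovariance.exchangeable(3, g_cor=0.6)
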