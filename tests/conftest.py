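import numpy as np
import pytest

from hapwin.experiments import build_machinery
from hapwin.mixed_model import build_numerator_matrix
from hapwin.pipeline import base_model
from hapwin.sim import (FlankSpec, QtlSpec, SimulationConfig, WindowSpec,
                        _spread_freqs, simulate_study)


def small_test_config(seed: int = 11) -> SimulationConfig:
    """A reduced two-window study: one hidden-causal window with a null and
    a coupled flank, one typed-causal-SNP window."""
    g1 = WindowSpec(
        gene="G1", chrom="chr1", positions=(1_000_000, 1_045_000, 1_090_000),
        base_freqs=_spread_freqs(range(8)),
        flank_left=FlankSpec(positions=(850_000, 895_000, 940_000),
                             base_freqs=_spread_freqs((3, 0, 5, 1, 7, 2, 6, 4)),
                             coupling=0.0),
        flank_right=FlankSpec(positions=(1_150_000, 1_195_000, 1_240_000),
                              base_freqs=_spread_freqs((5, 2, 7, 0, 4, 6, 1, 3)),
                              coupling=0.6))
    g2 = WindowSpec(gene="G2", chrom="chr2",
                    positions=(2_000_000, 2_040_000, 2_080_000),
                    base_freqs=_spread_freqs((1, 6, 0, 4, 2, 7, 3, 5)))
    # effect sized so the focal signal clears the chance-capture level
    # (~k/n ~= 3%) at this reduced sample size
    qtls = [QtlSpec(gene="G1", mode="hidden", haplotype="h111", effect=0.8,
                    carrier_fraction=0.8),
            QtlSpec(gene="G2", mode="snp", snp_index=1, effect=0.35)]
    return SimulationConfig(
        seed=seed, breeds={"A": 80, "B": 70, "C": 60},
        crossbreds=[("AXB", "A", "B", 20)], n_sires=60, n_herds=6,
        n_measurement_days=8, h2=0.4, windows=[g1, g2], qtls=qtls)


@pytest.fixture(scope="session")
def small_config():
    return small_test_config()


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


class FittedStudy:
    """A study plus the shared model machinery the pipeline reuses."""

    def __init__(self, study):
        self.study = study
        self.amat = build_numerator_matrix(study.pedigree)
        self.phen = study.phenotypes
        self.phen_ids = self.phen["individual"].astype(str).tolist()
        self.eig = self.amat.eigen(self.phen_ids)
        self.base = base_model(self.phen, self.eig)
        breeds = study.pedigree.breeds()
        self.strata = [breeds[i] for i in study.genotypes.ids]


@pytest.fixture(scope="session")
def small_fitted(small_study):
    return FittedStudy(small_study)


@pytest.fixture(scope="session")
def machinery():
    """Full study-scale pedigree with its eigen-decomposed A matrix."""
    return build_machinery(seed=0)
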