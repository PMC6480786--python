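import numpy as np
import pandas as pd
import pytest

from panclock import (AnalysisConfig, build_design, plant, simulate_cohort)
from panclock.simulate import SurvivalParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def small_design(seed=11, n_cancers=3, tumour_n=20, normal_n=10, **kw):
    """A tiny 3-cancer design: PER1 strongly deleted+down, ARNTL2
    amplified+up, three background clock genes."""
    cancers = [f"K{i}" for i in range(1, n_cancers + 1)]
    genes = ["PER1", "ARNTL2", "CRY1", "RORC", "SKP1"]
    plantings = []
    for c in cancers:
        plantings += plant("PER1", [c], deletion_fraction=0.4, de_log2fc=-1.5)
        plantings += plant("ARNTL2", [c], amplification_fraction=0.4,
                           de_log2fc=1.5)
    params = dict(survival=SurvivalParams(beta_clock=-0.5, beta_stage=0.3,
                                          censor_rate=0.2),
                  seed=seed)
    params.update(kw)
    return build_design(cancers, genes, tumour_n, normal_n, plantings, **params)


@pytest.fixture
def tiny_bundle():
    return simulate_cohort(small_design())


@pytest.fixture
def default_config():
    return AnalysisConfig(seed=1, n_permutations=99)


@pytest.fixture
def expr_pair(rng):
    """Two 30-gene expression groups, first 5 genes shifted down by 1 log2."""
    genes = [f"G{i:02d}" for i in range(30)]
    shift = np.zeros(30)
    shift[:5] = -1.0
    g1 = pd.DataFrame(rng.normal(8.0, 0.3, (30, 12)) + shift[:, None],
                      index=genes, columns=[f"T{i}" for i in range(12)])
    g2 = pd.DataFrame(rng.normal(8.0, 0.3, (30, 12)), index=genes,
                      columns=[f"N{i}" for i in range(12)])
    return g1, g2
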