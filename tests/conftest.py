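"""Shared fixtures: a hand-built toy cross and small simulated studies."""

import numpy as np
import pandas as pd
import pytest

from ailqtl import crossio, simcross


@pytest.fixture(scope="session")
def toy_map() -> crossio.GeneticMap:
    """Six markers on two chromosomes with dual cM/Mb coordinates."""
    return crossio.GeneticMap(pd.DataFrame(
        {"chrom": ["1", "1", "1", "1", "2", "2"],
         "cm": [0.0, 10.0, 20.0, 40.0, 0.0, 30.0],
         "mb": [0.0, 1.0, 3.0, 5.0, 0.0, 2.0]},
        index=pd.Index(["m1", "m2", "m3", "m4", "m5", "m6"], name="marker")))


@pytest.fixture(scope="session")
def toy_cross(toy_map) -> crossio.Cross:
    """Five individuals, six markers, two mass phenotypes."""
    geno = pd.DataFrame(
        [[0, 0, 1, 2, 1, 1],
         [1, 1, 1, 0, 2, 2],
         [2, 2, 1, 1, 0, 0],
         [1, 3, 4, 1, 1, -1],
         [0, 1, 2, 2, 2, 1]],
        index=pd.RangeIndex(5, name="id"), columns=toy_map.markers.index,
        dtype=np.int8)
    pheno = pd.DataFrame(
        {"w8": [60.0, 55.0, np.nan, 62.0, 58.0],
         "w42": [460.0, 430.0, 480.0, 455.0, np.nan],
         "w112": [1200.0, 1100.0, 1250.0, np.nan, 1180.0],
         "w212": [1700.0, 1600.0, 1800.0, 1650.0, 1720.0]},
        index=geno.index)
    covar = pd.DataFrame(
        {"sex": ["male", "female", "male", "female", "male"],
         "batch": ["b1", "b1", "b2", "b2", "b1"]}, index=geno.index)
    return crossio.Cross(toy_map, geno, pheno, covar)


@pytest.fixture(scope="session")
def small_study() -> simcross.SimulatedStudy:
    """A compact simulated study with the default planted architecture."""
    cfg = simcross.default_config(seed=11, n_final=200, n_probesets=650,
                                  n_expr_individuals=130)
    return simcross.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_cross(small_study):
    return small_study.cross
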