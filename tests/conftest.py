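"""Shared fixtures.

The two session-scoped Monte-Carlo runs (null calibration and the
all-deleterious power scenario) are expensive and shared between the
acceptance tests and the distributional property tests; everything else
is cheap and local.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adarv import CaseControlData, DEFAULT_THRESHOLDS, WIDE_THRESHOLDS
from adarv.experiments import scenario_pvalues

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ALL_METHODS = ("ada", "sigma_midp", "t1", "t5", "ws", "vt")

# Monte-Carlo scales of the calibration/power checks: 20 haplotype pools
# with 100 (null) / 25 (power) case-control panels each, B = 1000
# permutations per test.  Seeds fixed for reproducibility.
NULL_SEED = 20140115
POWER_SEED = 20140116


def toy_data(genotypes, phenotype, ids=None) -> CaseControlData:
    g = np.asarray(genotypes, dtype=np.int8)
    ids = ids or tuple(f"v{i+1}" for i in range(g.shape[1]))
    return CaseControlData(g, np.asarray(phenotype, dtype=np.int8), ids)


@pytest.fixture(scope="session")
def null_run():
    """2000 null replicates (PAR = 0, d = 20 preset, 500/500, B = 1000),
    adjusted/permutation P-values of ADA and all five comparators."""
    return scenario_pvalues(
        80, 0.0, 20,
        n_datasets=20, n_replicates=100, B=1000, seed=NULL_SEED,
        methods=ALL_METHODS, ada_grids={"ada": DEFAULT_THRESHOLDS},
    )


@pytest.fixture(scope="session")
def power_run():
    """500 replicates of the strongest scenario (r_isk = 100%, PAR = 0.3%,
    d = 20), all methods, ADA evaluated on both threshold grids over the
    same permutations."""
    return scenario_pvalues(
        100, 0.003, 20,
        n_datasets=20, n_replicates=25, B=1000, seed=POWER_SEED,
        methods=ALL_METHODS,
        ada_grids={"ada": DEFAULT_THRESHOLDS, "ada_wide": WIDE_THRESHOLDS},
    )


@pytest.fixture(scope="session")
def power_run_r50():
    """Paired-seed companion of power_run with r_isk = 50% (ADA only)."""
    return scenario_pvalues(
        50, 0.003, 20,
        n_datasets=20, n_replicates=25, B=1000, seed=POWER_SEED,
        methods=("ada",), ada_grids={"ada": DEFAULT_THRESHOLDS},
    )


@pytest.fixture(scope="session")
def power_run_par1():
    """Paired-seed companion of power_run with PAR = 0.1%, r_isk = 100%."""
    return scenario_pvalues(
        100, 0.001, 20,
        n_datasets=20, n_replicates=25, B=1000, seed=POWER_SEED,
        methods=("ada",), ada_grids={"ada": DEFAULT_THRESHOLDS},
    )
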