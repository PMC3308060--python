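"""Shared fixtures: one small end-to-end experiment reused across test
modules (session-scoped; ~5 s)."""

import pytest

import exocap as xc
from exocap.config import RunConfig, SimulationConfig

SMALL_SEED = 1


def small_config() -> RunConfig:
    cfg = RunConfig()
    cfg.simulation = SimulationConfig(
        chrom_lengths={"chr1": 200_000}, n_targets=60, n_pairs=6000
    )
    return cfg


@pytest.fixture(scope="session")
def small_experiment() -> xc.ExperimentResult:
    return xc.run_experiment(small_config(), seed=SMALL_SEED)
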