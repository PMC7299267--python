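import numpy as np
import pandas as pd
import pytest

from phenoqtl.photothermal import EnvironmentSeries
from phenoqtl.qtl import GeneticMap, RILGenotypes
from phenoqtl.simulate import (
    SimCohortConfig,
    simulate_cohort_phenology,
    simulate_environment,
)


@pytest.fixture
def flat_env() -> EnvironmentSeries:
    """60 days of constant 13 degC, 12-h photoperiod: 5 PTU/day at base 3."""
    days = np.arange(60)
    return EnvironmentSeries(
        day=days, temp=np.full(60, 13.0), photoperiod=np.full(60, 12.0), label="flat"
    )


def random_env(rng: np.random.Generator, n_days: int = 60, start: int = 0) -> EnvironmentSeries:
    """Random daily series spanning temperatures around the base threshold."""
    return EnvironmentSeries(
        day=np.arange(start, start + n_days),
        temp=rng.uniform(-2.0, 25.0, n_days),
        photoperiod=rng.uniform(0.0, 24.0, n_days),
    )


@pytest.fixture
def sse_records() -> pd.DataFrame:
    """A deterministic (zero-noise) sequential-seeding dataset."""
    cfg = SimCohortConfig(event_noise_sd=0.0, rng_seed=11)
    env = simulate_environment(cfg)
    return simulate_cohort_phenology(cfg, env)


def toy_map(lengths=(100.0,), n_markers=(11,)) -> GeneticMap:
    rows = []
    for c, (ln, nm) in enumerate(zip(lengths, n_markers), start=1):
        for k, p in enumerate(np.linspace(0.0, ln, nm), start=1):
            rows.append({"marker": f"m{c}_{k}", "chromosome": str(c), "pos_cm": float(p)})
    return GeneticMap(pd.DataFrame(rows))


def random_genotypes(gmap: GeneticMap, n_lines: int, seed: int) -> RILGenotypes:
    from phenoqtl.simulate import SimRILConfig, simulate_ril_genotypes

    return simulate_ril_genotypes(gmap, SimRILConfig(n_lines=n_lines, rng_seed=seed))
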