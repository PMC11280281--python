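import numpy as np
import pytest

from matvar import (MODELS, ChainConfig, PedigreeTable, SimulationConfig,
                    run_chain, simulate_population)


def random_pedigree(q: int, rng: np.random.Generator,
                    n_founders: int = 20) -> PedigreeTable:
    """Random valid pedigree: founders first, later animals draw parents
    from earlier ones (possibly unknown)."""
    sire = np.zeros(q, dtype=np.int64)
    dam = np.zeros(q, dtype=np.int64)
    for i in range(n_founders, q):
        if rng.random() < 0.9:
            sire[i] = rng.integers(1, i + 1)
        if rng.random() < 0.9:
            dam[i] = rng.integers(1, i + 1)
            if dam[i] == sire[i]:
                dam[i] = 0
    return PedigreeTable(sire=sire, dam=dam, labels=list(range(1, q + 1)))


MATERNAL_TRUTH = dict(sigma2_a=30.0, sigma2_m=15.0, sigma_am=-9.0,
                      sigma2_pe=10.0, sigma2_e=45.0)


@pytest.fixture(scope="session")
def maternal_pop():
    """Small flock simulated under the full maternal model."""
    cfg = SimulationConfig(n_sires=15, mating_ratio=5, progeny_per_dam=3,
                           trait_name="bw", seed=42, **MATERNAL_TRUTH)
    ped, rec, truth = simulate_population(cfg)
    return ped, rec, truth


@pytest.fixture(scope="session")
def direct_pop():
    """Small flock simulated under the direct-additive model."""
    cfg = SimulationConfig(n_sires=15, mating_ratio=5, progeny_per_dam=2,
                           sigma2_a=40.0, sigma2_e=60.0,
                           trait_name="asm", seed=7)
    ped, rec, truth = simulate_population(cfg)
    return ped, rec, truth


@pytest.fixture(scope="session")
def m3_chain(maternal_pop):
    ped, rec, _ = maternal_pop
    cc = ChainConfig(n_iterations=6000, burn_in=1000, thin=5, seed=11)
    return run_chain(rec, ped, MODELS["M3"], cc)


@pytest.fixture(scope="session")
def m1_chain(direct_pop):
    ped, rec, _ = direct_pop
    cc = ChainConfig(n_iterations=6000, burn_in=1000, thin=5, seed=13)
    return run_chain(rec, ped, MODELS["M1"], cc)
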