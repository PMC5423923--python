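import numpy as np
import pandas as pd
import pytest

from democonv.pipeline import make_fixture
from democonv.synthetic import (
    ClusterSpec,
    MigrationRegime,
    ScenarioConfig,
    WaveSpec,
    schedule_from_spec,
)

OPEN_AGE = 100


def flat_mortality(open_age: int = OPEN_AGE) -> np.ndarray:
    """Realistic-ish mortality: low flat working ages, steep old ages."""
    return schedule_from_spec(
        {
            "form": "points",
            "points": [[0, 0.003], [1, 0.0003], [10, 0.0002], [20, 0.0006], [50, 0.0024],
                       [64, 0.0065], [75, 0.028], [85, 0.09], [95, 0.24], [100, 0.4]],
        },
        open_age,
    )


def gaussian_schedule(level, mean_age, sd_age, open_age: int = OPEN_AGE) -> np.ndarray:
    return schedule_from_spec(
        {"form": "gaussian", "level": level, "mean_age": mean_age, "sd_age": sd_age}, open_age
    )


def make_cluster(
    label="c",
    n_regions=3,
    mortality=None,
    fertility=None,
    migration=None,
    multiplier=1.0,
    waves=(),
    noise_sd=0.0,
    initial_size=1.0e5,
):
    return ClusterSpec(
        label=label,
        n_regions=n_regions,
        mortality=flat_mortality() if mortality is None else mortality,
        fertility=gaussian_schedule(0.055, 28.0, 5.5) if fertility is None else fertility,
        migration=migration or MigrationRegime(rates=np.zeros(OPEN_AGE + 1)),
        mortality_multiplier_working_age=multiplier,
        waves=tuple(waves),
        noise_sd=noise_sd,
        initial_size=initial_size,
    )


def small_config(clusters=None, seed=0, start=2003, end=2013, observed_until=2008):
    clusters = clusters if clusters is not None else (make_cluster(),)
    return ScenarioConfig(
        n_regions=sum(c.n_regions for c in clusters),
        clusters=tuple(clusters),
        start_year=start,
        end_year=end,
        observed_until=observed_until,
        open_age=OPEN_AGE,
        seed=seed,
    )


def two_cluster_config(seed=0, east_multiplier=2.5, **kwargs):
    east = make_cluster(
        label="east",
        n_regions=4,
        migration=MigrationRegime(rates=gaussian_schedule(-0.002, 26.0, 9.0), convergence_rate=0.2),
        multiplier=east_multiplier,
        waves=(WaveSpec(1950, 1962, 1.3), WaveSpec(1990, 1997, 0.6)),
        noise_sd=0.03,
    )
    west = make_cluster(
        label="west",
        n_regions=4,
        migration=MigrationRegime(rates=gaussian_schedule(0.002, 26.0, 9.0), convergence_rate=0.2),
        waves=(WaveSpec(1950, 1962, 1.1),),
        noise_sd=0.03,
    )
    return small_config(clusters=(east, west), seed=seed, **kwargs)


@pytest.fixture(scope="session")
def tiny():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def stationary():
    return make_fixture("stationary")


@pytest.fixture(scope="session")
def divergent():
    return make_fixture("divergent")


@pytest.fixture(scope="session")
def small_scenario():
    """Simulated two-cluster panels shared by decomposition/convergence tests."""
    import democonv

    config = two_cluster_config(seed=11)
    population, deaths, migration = democonv.generate_scenario(config)
    return config, population, deaths, migration


def uniform_panel(count=10.0, open_age=99, regions=("R1",), years=(2000,)) -> pd.DataFrame:
    rows = [
        (r, y, a, count) for r in regions for y in years for a in range(open_age + 1)
    ]
    return pd.DataFrame(rows, columns=["region", "year", "age", "count"])
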