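"""Synthetic multi-region age-structured panels via cohort-component projection.

A scenario is a set of labeled clusters of regions.  Each cluster carries
age schedules of mortality (death probabilities q(a)), fertility (both-sex
births per person of age a) and net migration rates, plus demographic-wave
multipliers that reshape the initial age structure (baby-boom and bust
cohorts) and a migration regime with an observed-period shock and a
projected-period convergence of rates toward the cross-region mean.
Region-level heterogeneity enters through seeded lognormal perturbations
of the cluster schedules; stocks are real valued and evolve
deterministically given the perturbed rates.

Bookkeeping conventions
-----------------------
* Stocks are January-1 counts by completed age; flows cover [t, t+1).
* Within an interval, deaths are drawn first from start-of-year stocks
  (D = q * P), net migration is added after deaths (truncated so removals
  never exceed occupancy), then survivors age one year; the terminal open
  age group pools its survivors.
* Flow panels record the age a cohort *attains* during the interval:
  deaths/migration of the cohort aged a on January 1 appear under age
  a + 1 (the open age group stays at open_age; age 0 rows are zero
  because in-year events of newborns are not modeled).  With this
  convention the demographic balance reads, for 1 <= a < open_age,

      P(t+1, a) = P(t, a-1) - D(t, a) + M(t, a)

  exactly, and sums of flows over ages [15, 65) line up exactly with the
  change in the working-age stock — so the decomposition module's
  residual-migration and residual-deaths estimates reproduce the
  simulator's true flows to floating-point precision.
* Cohorts aged a on January 1 of year y are assigned birth year y - a - 1.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

DEFAULT_OPEN_AGE = 100
WORKING_AGES = (15, 65)  # ages subject to mortality_multiplier_working_age
_MAX_Q = 0.999


class ConfigError(ValueError):
    """A scenario configuration violates its invariants."""


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def schedule_from_spec(spec: dict, open_age: int, name: str = "schedule") -> np.ndarray:
    """Build an age schedule (length open_age + 1) from a declarative spec.

    Supported forms: ``constant`` (value), ``points`` (piecewise-linear
    through (age, value) pairs that must span ages 0..open_age),
    ``gompertz`` (level * exp(shape * age), for mortality) and ``gaussian``
    (level * exp(-((age - mean_age) / sd_age)^2 / 2), for fertility or
    migration profiles).
    """
    ages = np.arange(open_age + 1, dtype=float)
    form = spec.get("form")
    if form == "constant":
        return np.full(open_age + 1, float(spec["value"]))
    if form == "points":
        pts = sorted((float(a), float(v)) for a, v in spec["points"])
        xs = [p[0] for p in pts]
        if xs[0] > 0 or xs[-1] < open_age:
            raise ConfigError(
                f"{name}: points must span ages 0..{open_age}, got {xs[0]:g}..{xs[-1]:g} "
                f"(missing ages outside that span)"
            )
        return np.interp(ages, xs, [p[1] for p in pts])
    if form == "gompertz":
        return np.minimum(float(spec["level"]) * np.exp(float(spec["shape"]) * ages), _MAX_Q)
    if form == "gaussian":
        z = (ages - float(spec["mean_age"])) / float(spec["sd_age"])
        return float(spec["level"]) * np.exp(-0.5 * z * z)
    raise ConfigError(f"{name}: unknown schedule form {form!r}")


# ---------------------------------------------------------------------------
# config types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveSpec:
    """Multiplier applied to initial cohorts born in [start, end] (inclusive)."""

    start: int
    end: int
    multiplier: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ConfigError(f"wave window [{self.start}, {self.end}] is reversed")
        if not (self.multiplier > 0 and math.isfinite(self.multiplier)):
            raise ConfigError(f"wave multiplier must be positive and finite, got {self.multiplier}")


@dataclass(frozen=True)
class MigrationRegime:
    """Age-specific net migration rates with shock and convergence dynamics.

    During [shock_year, observed_until) rates are scaled by
    (1 + shock_delta); from observed_until onward each region's rate
    profile decays geometrically toward the all-region mean profile at
    ``convergence_rate`` per year, shrinking cross-region variance.
    """

    rates: np.ndarray
    shock_year: int | None = None
    shock_delta: float = 0.0
    convergence_rate: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.rates)):
            raise ConfigError("migration rates must be finite")
        if not (0.0 <= self.convergence_rate <= 1.0):
            raise ConfigError(f"convergence_rate must be in [0, 1], got {self.convergence_rate}")


@dataclass(frozen=True)
class ClusterSpec:
    label: str
    n_regions: int
    mortality: np.ndarray
    fertility: np.ndarray
    migration: MigrationRegime
    mortality_multiplier_working_age: float = 1.0
    waves: tuple[WaveSpec, ...] = ()
    noise_sd: float = 0.0
    initial_size: float = 1.0e6

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ConfigError(f"cluster {self.label!r}: n_regions must be >= 1")
        if np.any(self.mortality < 0) or np.any(self.mortality >= 1) or not np.all(np.isfinite(self.mortality)):
            raise ConfigError(f"cluster {self.label!r}: death probabilities must lie in [0, 1)")
        if np.any(self.fertility < 0) or not np.all(np.isfinite(self.fertility)):
            raise ConfigError(f"cluster {self.label!r}: fertility rates must be finite and non-negative")
        if not (self.mortality_multiplier_working_age >= 0):
            raise ConfigError(f"cluster {self.label!r}: working-age mortality multiplier must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError(f"cluster {self.label!r}: noise_sd must be >= 0")
        if not (self.initial_size > 0):
            raise ConfigError(f"cluster {self.label!r}: initial_size must be positive")
        _check_disjoint(self.waves)

    def check_ages(self, open_age: int) -> None:
        for name, sched in (("mortality", self.mortality), ("fertility", self.fertility),
                            ("migration", self.migration.rates)):
            if len(sched) != open_age + 1:
                raise ConfigError(
                    f"cluster {self.label!r}: {name} schedule covers {len(sched)} ages, "
                    f"need 0..{open_age}"
                )


@dataclass(frozen=True)
class ScenarioConfig:
    n_regions: int
    clusters: tuple[ClusterSpec, ...]
    start_year: int
    end_year: int
    observed_until: int
    open_age: int = DEFAULT_OPEN_AGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ConfigError(f"end_year {self.end_year} must exceed start_year {self.start_year}")
        if not (self.start_year < self.observed_until <= self.end_year):
            raise ConfigError(
                f"need start_year < observed_until <= end_year, got "
                f"{self.start_year}, {self.observed_until}, {self.end_year}"
            )
        total = sum(c.n_regions for c in self.clusters)
        if total != self.n_regions:
            raise ConfigError(f"cluster region counts sum to {total}, expected n_regions={self.n_regions}")
        for cluster in self.clusters:
            cluster.check_ages(self.open_age)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)


def _check_disjoint(waves) -> None:
    spans = sorted((w.start, w.end) for w in waves)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ConfigError(f"wave windows [{s1},{e1}] and [{s2},{e2}] overlap")


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

def scenario_from_dict(raw: dict) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from parsed TOML data."""
    try:
        top = raw["scenario"]
        open_age = int(top.get("open_age", DEFAULT_OPEN_AGE))
        clusters = []
        for spec in raw.get("cluster", []):
            mig_spec = dict(spec["migration"])
            regime = MigrationRegime(
                rates=schedule_from_spec(mig_spec, open_age, f"{spec['label']}.migration"),
                shock_year=mig_spec.get("shock_year"),
                shock_delta=float(mig_spec.get("shock_delta", 0.0)),
                convergence_rate=float(mig_spec.get("convergence_rate", 0.0)),
            )
            mort_spec = dict(spec["mortality"])
            multiplier = float(mort_spec.pop("working_age_multiplier", 1.0))
            clusters.append(
                ClusterSpec(
                    label=str(spec["label"]),
                    n_regions=int(spec["n_regions"]),
                    mortality=schedule_from_spec(mort_spec, open_age, f"{spec['label']}.mortality"),
                    fertility=schedule_from_spec(spec["fertility"], open_age, f"{spec['label']}.fertility"),
                    migration=regime,
                    mortality_multiplier_working_age=multiplier,
                    waves=tuple(
                        WaveSpec(int(w["start"]), int(w["end"]), float(w["multiplier"]))
                        for w in spec.get("wave", [])
                    ),
                    noise_sd=float(spec.get("noise_sd", 0.0)),
                    initial_size=float(spec.get("initial_size", 1.0e6)),
                )
            )
    except KeyError as exc:
        raise ConfigError(f"scenario config is missing required key {exc}") from exc
    return ScenarioConfig(
        n_regions=int(top["n_regions"]),
        clusters=tuple(clusters),
        start_year=int(top["start_year"]),
        end_year=int(top["end_year"]),
        observed_until=int(top["observed_until"]),
        open_age=open_age,
        seed=int(top.get("seed", 0)),
    )


def load_scenario(path) -> ScenarioConfig:
    with open(path, "rb") as fh:
        return scenario_from_dict(tomllib.load(fh))


def default_scenario_path():
    """Path to the shipped four-cluster, two-regime scenario."""
    return resources.files("democonv.data") / "default_scenario.toml"


def load_default_scenario(seed: int | None = None) -> ScenarioConfig:
    config = load_scenario(default_scenario_path())
    if seed is not None:
        config = ScenarioConfig(
            n_regions=config.n_regions,
            clusters=config.clusters,
            start_year=config.start_year,
            end_year=config.end_year,
            observed_until=config.observed_until,
            open_age=config.open_age,
            seed=seed,
        )
    return config


# ---------------------------------------------------------------------------
# demographic primitives
# ---------------------------------------------------------------------------

def stationary_population(q: np.ndarray, size: float = 1.0) -> np.ndarray:
    """Stationary age structure implied by death probabilities ``q``.

    Uses the projection recurrence P(a+1) = P(a) * (1 - q(a)); the open
    terminal group holds its equilibrium mass P(A-1)(1 - q(A-1)) / q(A)
    when q at the open age is positive.  Scaled to total ``size``.
    """
    q = np.asarray(q, dtype=float)
    p = np.empty_like(q)
    p[0] = 1.0
    for a in range(len(q) - 1):
        p[a + 1] = p[a] * (1.0 - q[a])
    if q[-1] > 0:
        p[-1] = p[-2] * (1.0 - q[-2]) / q[-1]
    return p * (size / p.sum())


def replacement_fertility(profile: np.ndarray, population: np.ndarray) -> np.ndarray:
    """Scale a fertility profile so births exactly replace the age-0 cohort."""
    profile = np.asarray(profile, dtype=float)
    births = float(profile @ population)
    if births <= 0:
        raise ConfigError("fertility profile produces no births on this population")
    return profile * (population[0] / births)


def apply_wave(population: np.ndarray, waves, start_year: int) -> np.ndarray:
    """Scale cohorts whose birth years fall inside wave windows.

    ``population`` is an age vector of January-1 counts for ``start_year``;
    age a maps to birth year start_year - a - 1.  Windows must be disjoint;
    the result is order independent.
    """
    waves = tuple(waves)
    _check_disjoint(waves)
    out = np.array(population, dtype=float)
    ages = np.arange(len(out))
    birth_years = start_year - ages - 1
    for wave in waves:
        mask = (birth_years >= wave.start) & (birth_years <= wave.end)
        out[mask] *= wave.multiplier
    return out


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def _region_rates(config: ScenarioConfig, rng: np.random.Generator):
    """Per-region perturbed schedules and migration regime parameters."""
    A = config.open_age + 1
    R = config.n_regions
    lo, up = WORKING_AGES
    q = np.empty((R, A))
    q_base = np.empty((R, A))  # without the working-age multiplier; seeds the initial structure
    fert = np.empty((R, A))
    mig = np.empty((R, A))
    sizes = np.empty(R)
    shock_year = np.full(R, np.iinfo(np.int64).max, dtype=np.int64)
    shock_delta = np.zeros(R)
    conv = np.zeros(R)
    region_ids: list[str] = []
    cluster_labels: list[str] = []
    i = 0
    for cluster in config.clusters:
        for j in range(cluster.n_regions):
            noise = np.exp(cluster.noise_sd * rng.standard_normal(4))
            qb = cluster.mortality * noise[0]
            np.minimum(qb, _MAX_Q, out=qb)
            q_base[i] = qb
            qr = qb.copy()
            qr[lo:up] *= cluster.mortality_multiplier_working_age
            np.minimum(qr, _MAX_Q, out=qr)
            q[i] = qr
            fert[i] = cluster.fertility * noise[1]
            mig[i] = cluster.migration.rates * noise[2]
            sizes[i] = cluster.initial_size * noise[3]
            if cluster.migration.shock_year is not None:
                shock_year[i] = cluster.migration.shock_year
            shock_delta[i] = cluster.migration.shock_delta
            conv[i] = cluster.migration.convergence_rate
            region_ids.append(f"{cluster.label}_{j:03d}")
            cluster_labels.append(cluster.label)
            i += 1
    return q, q_base, fert, mig, sizes, shock_year, shock_delta, conv, region_ids, cluster_labels


def _simulate_arrays(config: ScenarioConfig):
    rng = np.random.default_rng(config.seed)
    q, q_base, fert, mig, sizes, shock_year, shock_delta, conv, region_ids, labels = _region_rates(config, rng)
    A = config.open_age + 1
    R = config.n_regions
    years = config.years
    n_steps = len(years) - 1

    pop = np.empty((len(years), R, A))
    deaths = np.zeros((n_steps, R, A))
    migration = np.zeros((n_steps, R, A))

    P = np.empty((R, A))
    i = 0
    for cluster in config.clusters:
        for _ in range(cluster.n_regions):
            # seeded from base mortality: the working-age multiplier acts on
            # flows only, so raising it strictly depresses the TSR downstream
            base = stationary_population(q_base[i], 1.0)
            base = apply_wave(base, cluster.waves, config.start_year)
            P[i] = base * (sizes[i] / base.sum())
            i += 1
    pop[0] = P

    mean_mig = mig.mean(axis=0)  # all-region mean profile, convergence target
    for k in range(n_steps):
        t = int(years[k])
        if t < config.observed_until:
            shocked = (shock_year <= t)[:, None]
            rates = np.where(shocked, mig * (1.0 + shock_delta[:, None]), mig)
        else:
            decay = (1.0 - conv) ** (t - config.observed_until + 1)
            rates = mean_mig[None, :] + (mig - mean_mig[None, :]) * decay[:, None]
        D = q * P
        M = rates * P
        np.maximum(M, -(P - D), out=M)  # removals never exceed occupancy
        survivors = P - D + M
        births = (fert * P).sum(axis=1)
        nxt = np.empty_like(P)
        nxt[:, 1:] = survivors[:, :-1]
        nxt[:, 0] = births
        # flows recorded by attained age; open group pools its own events,
        # grouped exactly as the panels record them so the balance identity
        # reproduces bit for bit from the three output frames
        deaths[k, :, 1:] = D[:, :-1]
        deaths[k, :, -1] += D[:, -1]
        migration[k, :, 1:] = M[:, :-1]
        migration[k, :, -1] += M[:, -1]
        nxt[:, -1] = (P[:, -2] + P[:, -1]) - deaths[k, :, -1] + migration[k, :, -1]
        P = nxt
        pop[k + 1] = P
    return pop, deaths, migration, region_ids, labels


def _long_frame(values: np.ndarray, years: np.ndarray, region_ids, value_col: str,
                labels=None) -> pd.DataFrame:
    n_years, n_regions, n_ages = values.shape
    regions = np.repeat(region_ids, n_years * n_ages)
    year_col = np.tile(np.repeat(years, n_ages), n_regions)
    age_col = np.tile(np.arange(n_ages), n_years * n_regions)
    # values is (year, region, age); reorder to region-major
    data = values.transpose(1, 0, 2).reshape(-1)
    frame = pd.DataFrame({"region": regions, "year": year_col, "age": age_col, value_col: data})
    if labels is not None:
        frame.insert(1, "cluster", np.repeat(labels, n_years * n_ages))
    return frame


def generate_scenario(config: ScenarioConfig):
    """Run the projection; return (population, deaths, migration) panels.

    Population holds January-1 stocks for every year in
    [start_year, end_year]; deaths and net migration cover every interval
    [t, t+1), recorded by attained age (see module docstring).  Identical
    config and seed reproduce the output bit for bit.
    """
    pop, deaths, migration, region_ids, labels = _simulate_arrays(config)
    years = config.years
    population = _long_frame(pop, years, region_ids, "count", labels=labels)
    deaths_panel = _long_frame(deaths, years[:-1], region_ids, "deaths")
    migration_panel = _long_frame(migration, years[:-1], region_ids, "net_migration")
    return population, deaths_panel, migration_panel


def check_balance(population: pd.DataFrame, deaths: pd.DataFrame, migration: pd.DataFrame) -> float:
    """Maximum absolute demographic-balance residual across all cells.

    Asserts P(t+1, a) = P(t, a-1) - D(t, a) + M(t, a) for 1 <= a < open_age
    and the pooled version at the open age; returns the worst violation
    (0.0 for exact simulator output).
    """
    from .panels import to_cube

    pop = to_cube(population, "count")
    d = to_cube(deaths, "deaths")
    m = to_cube(migration, "net_migration")
    P = pop.values  # (R, Y, A)
    flows_years = [pop.year_index(int(y)) for y in d.years]
    worst = 0.0
    for k, iy in enumerate(flows_years):
        start, end = P[:, iy, :], P[:, iy + 1, :]
        predicted = np.empty_like(start)
        predicted[:, 1:] = start[:, :-1]
        predicted[:, -1] += start[:, -1]
        predicted[:, 1:] -= d.values[:, k, 1:]
        predicted[:, 1:] += m.values[:, k, 1:]
        resid = np.abs(end[:, 1:] - predicted[:, 1:])
        worst = max(worst, float(resid.max()))
    return worst
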