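"""Pipeline orchestration: simulate -> tsr -> decompose -> converge -> report.

Also houses the deterministic CSV fixture generators used by the test
suite and documentation.  CSV is the single interchange format; schemas
are documented in the README and validated on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .convergence import temporal_decomposition
from .decomposition import decompose_yearly
from .panels import merge_events, write_csv
from .support_ratio import DEFAULT_BOUNDS, WorkingAgeBounds, compute_tsr
from .synthetic import ScenarioConfig, check_balance, generate_scenario, load_scenario

logger = logging.getLogger("democonv")

FIXTURES = ("tiny", "two_cluster", "stationary", "divergent")


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, outputs, and provenance."""

    config_sha256: str
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    created_utc: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def default_decades(config: ScenarioConfig) -> list[tuple[int, int]]:
    """Ten-year periods tiling [start_year, end_year] (last may be shorter)."""
    decades = []
    start = config.start_year
    while start < config.end_year:
        end = min(start + 10, config.end_year)
        decades.append((start, end))
        start = end
    return decades


def regime_mode(config: ScenarioConfig):
    """Interval-year -> decomposition mode for a two-regime scenario."""

    def mode(t: int) -> str:
        return "observed" if t < config.observed_until else "projected"

    return mode


def run_pipeline(
    config_path,
    outdir,
    seed: int | None = None,
    bounds: WorkingAgeBounds = DEFAULT_BOUNDS,
    weights: str | None = None,
) -> RunManifest:
    """Run the full pipeline from a scenario config; return the manifest.

    Writes population/deaths/migration, tsr, components, betas and
    cumulative-beta CSVs plus a run log and manifest.json into ``outdir``.
    Partial outputs are removed if any stage fails.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_bytes = Path(config_path).read_bytes()
    config = load_scenario(config_path)
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
    manifest = RunManifest(
        config_sha256=hashlib.sha256(config_bytes).hexdigest(),
        seed=config.seed,
        version=__version__,
    )
    written: list[Path] = []
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        write_csv(frame, path)
        written.append(path)
        manifest.outputs[name] = str(path)
        log(f"wrote {path.name}: {len(frame)} rows")

    try:
        log(f"scenario: {config.n_regions} regions, years {config.start_year}-{config.end_year}, seed {config.seed}")
        population, deaths, migration = generate_scenario(config)
        residual = check_balance(population, deaths, migration)
        log(f"simulate: demographic balance max residual {residual:.3e}")
        emit("population", population)
        emit("deaths", deaths)
        emit("migration", migration)

        tsr = compute_tsr(population, bounds)
        log(f"tsr: {tsr['tsr'].min():.3f}..{tsr['tsr'].max():.3f} across {tsr['region'].nunique()} regions")
        emit("tsr", tsr)

        events = merge_events(deaths, migration)
        components = decompose_yearly(population, events, bounds=bounds, mode=regime_mode(config))
        add_gap = (components["g"] - components["nw"] - components["w"]).abs().max()
        w_gap = (components["w"] - components[["ct", "mg", "mt"]].sum(axis=1)).abs().max()
        log(f"decompose: additivity residuals g-nw-w {add_gap:.3e}, w-ct-mg-mt {w_gap:.3e}")
        emit("components", components)

        decades = default_decades(config)
        table = temporal_decomposition(
            population, events, decades, bounds=bounds, mode=regime_mode(config), weights=weights
        )
        log(f"converge: {len(table.yearly)} yearly + {len(table.pooled)} pooled estimates over decades {decades}")
        emit("betas", table.estimates())
        emit("betas_cumulative", table.cumulative)

        manifest.created_utc = datetime.now(timezone.utc).isoformat()
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        manifest.outputs["log"] = str(outdir / "run.log")
        (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
        manifest.outputs["manifest"] = str(outdir / "manifest.json")
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return manifest


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _frame_from_grid(rows: list[tuple], value_col: str, cluster: bool = False) -> pd.DataFrame:
    cols = ["region", "year", "age", value_col]
    if cluster:
        cols = ["region", "cluster", "year", "age", value_col]
    return pd.DataFrame(rows, columns=cols)


def _tiny_fixture() -> dict[str, pd.DataFrame]:
    """3 regions x 3 years x 5 ages, hand-checkable (bounds [1, 4))."""
    stocks = {
        "A": {2000: [10, 20, 30, 40, 50], 2001: [12, 9.5, 17, 27, 88], 2002: [11, 12.5, 8.5, 13, 113]},
        "B": {2000: [40, 10, 10, 10, 40], 2001: [8, 39, 9, 9, 48], 2002: [9, 7.5, 38, 8, 54]},
        "C": {2000: [20, 20, 20, 20, 20], 2001: [20, 22, 22, 22, 42], 2002: [18, 19, 21, 21, 63]},
    }
    deaths = {
        "A": {2000: [0, 1, 2, 3, 4], 2001: [0, 0.5, 1, 2, 3]},
        "B": {2000: [0, 1, 1, 1, 2], 2001: [0, 0.5, 2, 1, 1]},
        "C": {2000: [0, 0, 0, 0, 0], 2001: [0, 1, 1, 1, 1]},
    }
    migration = {
        "A": {2000: [0, 0.5, -1, 0, 2], 2001: [0, 1, 0, -2, 1]},
        "B": {2000: [0, 0, 0, 0, 0], 2001: [0, 0, 1, 0, -2]},
        "C": {2000: [0, 2, 2, 2, 2], 2001: [0, 0, 0, 0, 0]},
    }

    def unpack(data, col):
        return _frame_from_grid(
            [(r, y, a, v) for r, by_year in data.items() for y, vals in by_year.items()
             for a, v in enumerate(vals)],
            col,
        )

    return {
        "population": unpack(stocks, "count"),
        "deaths": unpack(deaths, "deaths"),
        "migration": unpack(migration, "net_migration"),
    }


def _stationary_fixture() -> dict[str, pd.DataFrame]:
    """Six regions in time-invariant equilibrium; every TSR change is 0.

    Age profile per region: k below age 14, b through the working span,
    u above 66; flows reconcile the steps outside the working ages, so all
    balance components at working ages are exactly zero while TSR levels
    differ across regions.
    """
    params = [(140.0 + 15 * i, 100.0, 60.0) for i in range(6)]  # (k, b, u)
    years = list(range(2000, 2011))
    open_age = 100
    pop_rows, death_rows, mig_rows = [], [], []
    for i, (k, b, u) in enumerate(params):
        region = f"S{i}"
        profile = [k] * 14 + [b] * 52 + [u] * 35  # ages 0-13, 14-65, 66-100
        d = [0.0] * (open_age + 1)
        m = [0.0] * (open_age + 1)
        m[14] = b - k
        m[66] = u - b
        d[open_age] = u  # terminal pooling: inflow from age 99 balances deaths
        for year in years:
            pop_rows += [(region, year, a, profile[a]) for a in range(open_age + 1)]
            if year != years[-1]:
                death_rows += [(region, year, a, d[a]) for a in range(open_age + 1)]
                mig_rows += [(region, year, a, m[a]) for a in range(open_age + 1)]
    return {
        "population": _frame_from_grid(pop_rows, "count"),
        "deaths": _frame_from_grid(death_rows, "deaths"),
        "migration": _frame_from_grid(mig_rows, "net_migration"),
    }


def _divergent_fixture() -> dict[str, pd.DataFrame]:
    """High-TSR regions engineered to grow faster: beta(g) > 0."""
    years = list(range(2000, 2011))
    open_age = 100
    pop_rows, death_rows = [], []
    for i in range(8):
        region = f"D{i}"
        w0 = 80.0 + 10.0 * i
        growth = 1.0 + 0.002 * i
        for year in years:
            w = w0 * growth ** (year - years[0])
            for age in range(open_age + 1):
                count = 100.0 if age < 15 else (w if age < 65 else 50.0)
                pop_rows.append((region, year, age, count))
            if year != years[-1]:
                death_rows += [(region, year, a, 0.0) for a in range(open_age + 1)]
    return {
        "population": _frame_from_grid(pop_rows, "count"),
        "deaths": _frame_from_grid(death_rows, "deaths"),
    }


def _two_cluster_fixture() -> dict[str, pd.DataFrame]:
    """Small simulated two-cluster scenario (deterministic seed)."""
    from .synthetic import ClusterSpec, MigrationRegime, schedule_from_spec

    open_age = 100
    gomp = {"form": "gompertz", "level": 2.0e-4, "shape": 0.085}
    fert = {"form": "gaussian", "level": 0.055, "mean_age": 28.0, "sd_age": 5.5}
    out_mig = {"form": "gaussian", "level": -0.002, "mean_age": 26.0, "sd_age": 9.0}
    in_mig = {"form": "gaussian", "level": 0.002, "mean_age": 26.0, "sd_age": 9.0}

    def cluster(label, mult, mig_spec, waves):
        return ClusterSpec(
            label=label,
            n_regions=4,
            mortality=schedule_from_spec(gomp, open_age),
            fertility=schedule_from_spec(fert, open_age),
            migration=MigrationRegime(
                rates=schedule_from_spec(mig_spec, open_age), convergence_rate=0.2
            ),
            mortality_multiplier_working_age=mult,
            waves=waves,
            noise_sd=0.03,
            initial_size=2.0e5,
        )

    from .synthetic import WaveSpec

    config = ScenarioConfig(
        n_regions=8,
        clusters=(
            cluster("east", 2.5, out_mig, (WaveSpec(1950, 1962, 1.3), WaveSpec(1990, 1997, 0.6))),
            cluster("west", 1.0, in_mig, (WaveSpec(1950, 1962, 1.1),)),
        ),
        start_year=2003,
        end_year=2013,
        observed_until=2008,
        open_age=open_age,
        seed=7,
    )
    population, deaths, migration = generate_scenario(config)
    return {"population": population, "deaths": deaths, "migration": migration}


def make_fixture(name: str) -> dict[str, pd.DataFrame]:
    """Build one of the deterministic named fixtures as DataFrames."""
    builders = {
        "tiny": _tiny_fixture,
        "two_cluster": _two_cluster_fixture,
        "stationary": _stationary_fixture,
        "divergent": _divergent_fixture,
    }
    if name not in builders:
        raise ValueError(f"unknown fixture {name!r}; valid names: {', '.join(FIXTURES)}")
    return builders[name]()


def write_fixture(name: str, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for kind, frame in make_fixture(name).items():
        path = outdir / f"{kind}.csv"
        write_csv(frame, path)
        paths.append(path)
    return paths
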