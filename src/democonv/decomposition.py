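"""Two-step decomposition of change in the total support ratio.

Step one splits the change in TSR = W/NW over an interval into additive
effects of the non-working-age and working-age populations using the
symmetric two-factor decomposition of a ratio:

    TSR2 - TSR1 = [ (W2+W1)/2 * (1/NW2 - 1/NW1) ]   (nw effect)
                + [ (1/NW2 + 1/NW1)/2 * (W2 - W1) ] (w effect)

Step two replaces W2 - W1 by the demographic balance at working ages,

    W2 = W1 + CT + M_W - D_W,

where CT is cohort turnover (persons aged lower-1 minus persons aged
upper-1 at each interval start), M_W is net migration at working ages and
D_W deaths at working ages, yielding three additive sub-effects

    ct = h*CT,  mg = h*M_W,  mt = -h*D_W,   h = (1/NW2 + 1/NW1)/2.

One balance term is always derived as a residual: net migration in
``observed`` mode (migration records are unreliable; deaths are recorded)
or deaths in ``projected`` mode (projections publish migration).  The
residual makes the balance close exactly, so the additivity identities
hold to floating-point precision on any input.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .panels import Cube, PanelError, to_cube
from .support_ratio import DEFAULT_BOUNDS, WorkingAgeBounds

MODES = ("observed", "projected")

COMPONENTS_SCHEMA = (
    "region",
    "period_start",
    "period_end",
    "mode",
    "tsr1",
    "tsr2",
    "g",
    "nw",
    "w",
    "ct",
    "mg",
    "mt",
    "CT",
    "M_W",
    "D_W",
)


# ---------------------------------------------------------------------------
# elementary operations (scalar or ndarray; pure arithmetic)
# ---------------------------------------------------------------------------

def dasgupta_two_factor(W1, W2, NW1, NW2):
    """Split TSR2 - TSR1 into (nw_effect, w_effect).

    Both inputs and outputs broadcast; all four counts must be positive.
    The two effects sum to W2/NW2 - W1/NW1 by algebraic identity.
    """
    W1, W2, NW1, NW2 = (np.asarray(v, dtype=float) for v in (W1, W2, NW1, NW2))
    if np.any(W1 <= 0) or np.any(W2 <= 0) or np.any(NW1 <= 0) or np.any(NW2 <= 0):
        raise ValueError("dasgupta_two_factor requires strictly positive W and NW counts")
    nw_effect = 0.5 * (W2 + W1) * (1.0 / NW2 - 1.0 / NW1)
    w_effect = 0.5 * (1.0 / NW2 + 1.0 / NW1) * (W2 - W1)
    return nw_effect, w_effect


def residual_migration(W1, W2, CT, D_W):
    """Net migration at working ages implied by the demographic balance."""
    return np.asarray(W2, dtype=float) - W1 - CT + D_W


def residual_deaths(W1, W2, CT, M_W):
    """Deaths at working ages implied by the demographic balance."""
    return np.asarray(W1, dtype=float) + CT + M_W - W2


def decompose_working_age_effect(NW1, NW2, CT, M_W, D_W):
    """Split the working-age effect into (ct, mg, mt) with mt carrying its sign."""
    NW1, NW2 = np.asarray(NW1, dtype=float), np.asarray(NW2, dtype=float)
    if np.any(NW1 <= 0) or np.any(NW2 <= 0):
        raise ValueError("decompose_working_age_effect requires positive NW counts")
    h = 0.5 * (1.0 / NW2 + 1.0 / NW1)
    return h * np.asarray(CT, float), h * np.asarray(M_W, float), -h * np.asarray(D_W, float)


# ---------------------------------------------------------------------------
# panel-level operations
# ---------------------------------------------------------------------------

def _check_interval(t1: int, t2: int) -> None:
    if t2 <= t1:
        raise ValueError(f"interval end {t2} must exceed start {t1}")


def cohort_turnover(
    panel: pd.DataFrame,
    region,
    interval: tuple[int, int],
    bounds: WorkingAgeBounds = DEFAULT_BOUNDS,
) -> float:
    """Cohort turnover for one region over [t1, t2].

    Sum over interval-start years t of (persons aged lower-1) minus
    (persons aged upper-1) on January 1 of t: entries into minus exits out
    of the working ages during [t, t+1).
    """
    t1, t2 = interval
    _check_interval(t1, t2)
    sub = panel[panel["region"] == region]
    if sub.empty:
        raise PanelError(f"region {region!r} not present in panel")
    total = 0.0
    for t in range(t1, t2):
        for age, sign in ((bounds.lower - 1, 1.0), (bounds.upper - 1, -1.0)):
            rows = sub[(sub["year"] == t) & (sub["age"] == age)]
            if rows.empty:
                raise PanelError(f"region {region!r}: no count for year {t}, age {age}")
            total += sign * float(rows["count"].sum())
    return total


def _flow_sum(events: pd.DataFrame, region, interval, bounds, value_col: str) -> float:
    t1, t2 = interval
    _check_interval(t1, t2)
    sub = events[
        (events["region"] == region)
        & (events["year"] >= t1)
        & (events["year"] < t2)
        & (events["age"] >= bounds.lower)
        & (events["age"] < bounds.upper)
    ]
    years = set(int(y) for y in sub["year"].unique())
    missing = sorted(set(range(t1, t2)) - years)
    if missing:
        raise PanelError(f"region {region!r}: {value_col} missing for interval year(s) {missing}")
    return float(sub[value_col].sum())


def deaths_at_working_ages(
    events: pd.DataFrame,
    region,
    interval: tuple[int, int],
    bounds: WorkingAgeBounds = DEFAULT_BOUNDS,
) -> float:
    """Deaths at ages in [lower, upper) summed over the interval's years."""
    return _flow_sum(events, region, interval, bounds, "deaths")


def migration_at_working_ages(
    events: pd.DataFrame,
    region,
    interval: tuple[int, int],
    bounds: WorkingAgeBounds = DEFAULT_BOUNDS,
) -> float:
    """Net migration at ages in [lower, upper) summed over the interval's years."""
    return _flow_sum(events, region, interval, bounds, "net_migration")


# ---------------------------------------------------------------------------
# vectorized table builder
# ---------------------------------------------------------------------------

def _components_from_cubes(
    pop: Cube,
    flow: Cube,
    clusters: np.ndarray | None,
    t1: int,
    t2: int,
    bounds: WorkingAgeBounds,
    mode: str,
) -> pd.DataFrame:
    i1, i2 = pop.year_index(t1), pop.year_index(t2)
    lo, up = bounds.lower, bounds.upper

    counts = pop.values
    w_all = counts[:, :, lo:up].sum(axis=2)
    nw_all = counts.sum(axis=2) - w_all
    W1, W2 = w_all[:, i1], w_all[:, i2]
    NW1, NW2 = nw_all[:, i1], nw_all[:, i2]

    # cohort turnover summed over interval-start years
    year_idx = [pop.year_index(t) for t in range(t1, t2)]
    CT = (counts[:, year_idx, lo - 1] - counts[:, year_idx, up - 1]).sum(axis=1)

    flow_idx = [flow.year_index(t) for t in range(t1, t2)]
    flow_sum = flow.values[:, flow_idx, lo:up].sum(axis=(1, 2))
    if mode == "observed":
        D_W = flow_sum
        M_W = residual_migration(W1, W2, CT, D_W)
    else:
        M_W = flow_sum
        D_W = residual_deaths(W1, W2, CT, M_W)

    nw_eff, w_eff = dasgupta_two_factor(W1, W2, NW1, NW2)
    ct, mg, mt = decompose_working_age_effect(NW1, NW2, CT, M_W, D_W)
    tsr1, tsr2 = W1 / NW1, W2 / NW2

    out = pd.DataFrame(
        {
            "region": pop.regions,
            "period_start": t1,
            "period_end": t2,
            "mode": mode,
            "tsr1": tsr1,
            "tsr2": tsr2,
            "g": tsr2 - tsr1,
            "nw": nw_eff,
            "w": w_eff,
            "ct": ct,
            "mg": mg,
            "mt": mt,
            "CT": CT,
            "M_W": M_W,
            "D_W": D_W,
        }
    )
    if clusters is not None:
        out.insert(1, "cluster", clusters)
    return out


def _cluster_map(panel: pd.DataFrame, regions: np.ndarray) -> np.ndarray | None:
    if "cluster" not in panel.columns:
        return None
    lookup = panel.drop_duplicates("region").set_index("region")["cluster"]
    return lookup.reindex(regions).to_numpy()


def _prepare(panel, events, bounds, mode):
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    value_col = "deaths" if mode == "observed" else "net_migration"
    if value_col not in events.columns:
        raise PanelError(f"{mode} mode requires a {value_col!r} column in the events panel")
    pop = to_cube(panel, "count")
    bounds.check_open_age(pop.open_age)
    flow = to_cube(events, value_col)
    if list(flow.regions) != list(pop.regions):
        only_pop = sorted(set(pop.regions) - set(flow.regions))
        only_flow = sorted(set(flow.regions) - set(pop.regions))
        raise PanelError(
            f"population and events panels disagree on regions "
            f"(population-only: {only_pop[:5]}, events-only: {only_flow[:5]})"
        )
    return pop, flow, _cluster_map(panel, pop.regions)


def decompose_change(
    panel: pd.DataFrame,
    events: pd.DataFrame,
    interval: tuple[int, int],
    bounds: WorkingAgeBounds = DEFAULT_BOUNDS,
    mode: str = "observed",
) -> pd.DataFrame:
    """Full two-step decomposition for all regions over one interval.

    Multi-year intervals use endpoint stocks for the ratio terms and sum
    CT, M_W, D_W over the interval's years.  Returns one row per region
    with the :data:`COMPONENTS_SCHEMA` columns (plus ``cluster`` when the
    population panel carries one).
    """
    t1, t2 = interval
    _check_interval(t1, t2)
    pop, flow, clusters = _prepare(panel, events, bounds, mode)
    return _components_from_cubes(pop, flow, clusters, t1, t2, bounds, mode)


def decompose_yearly(
    panel: pd.DataFrame,
    events: pd.DataFrame,
    bounds: WorkingAgeBounds = DEFAULT_BOUNDS,
    mode: str | Mapping[int, str] | Callable[[int], str] = "observed",
    years: list[int] | None = None,
) -> pd.DataFrame:
    """One-year decompositions for every interval [t, t+1) in the panel.

    ``mode`` may be a single mode, a mapping from interval-start year to
    mode, or a callable year -> mode (used by the pipeline to switch from
    observed to projected at a cut-over year).  Both flow columns must be
    present when modes are mixed.
    """
    if years is None:
        years = sorted(int(y) for y in panel["year"].unique())[:-1]

    def mode_for(t: int) -> str:
        if callable(mode):
            return mode(t)
        if isinstance(mode, Mapping):
            return mode[t]
        return mode

    modes_needed = {mode_for(t) for t in years}
    pieces = []
    for m in sorted(modes_needed):
        pop, flow, clusters = _prepare(panel, events, bounds, m)
        for t in years:
            if mode_for(t) == m:
                pieces.append(_components_from_cubes(pop, flow, clusters, t, t + 1, bounds, m))
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["period_start", "region"], kind="mergesort", ignore_index=True)
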