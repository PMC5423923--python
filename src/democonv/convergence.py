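"""Beta-convergence regressions and their additive decomposition.

The cross-sectional model regresses the change in TSR over a period on its
initial level:

    TSR2 - TSR1 = alpha + beta * TSR1 + eps

A negative beta means convergence (initially less aged regions age faster).
Because OLS is linear in the response and every partial model shares the
same regressor, betas decompose additively along both axes used here:

* by component — beta(nw) + beta(w) = beta(g) and
  beta(ct) + beta(mg) + beta(mt) = beta(w);
* by time — within a decade whose initial TSR distribution serves as the
  common regressor, yearly betas sum to the decade's pooled beta.

Regressions are unit weighted by default (every region counts once);
population weights are available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

COMPONENTS = ("g", "nw", "w", "ct", "mg", "mt")

BETAS_SCHEMA = (
    "component",
    "period_start",
    "period_end",
    "regressor_year",
    "alpha",
    "beta",
    "se_beta",
    "r2",
    "n_regions",
)


@dataclass(frozen=True)
class BetaEstimate:
    """One convergence regression: slope, intercept, and fit diagnostics."""

    component: str
    alpha: float
    beta: float
    se_beta: float
    r_squared: float
    n_regions: int
    period_start: int | None = None
    period_end: int | None = None
    regressor_year: int | None = None


def ols_beta(x, y, weights=None, component: str = "g") -> BetaEstimate:
    """Fit the convergence regression y = alpha + beta * x + eps.

    ``x`` is the initial TSR across regions, ``y`` the (partial) change in
    TSR.  Unit weighted unless ``weights`` is given (then WLS).  Requires
    at least three regions and non-degenerate x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-d and equal length, got {x.shape} and {y.shape}")
    if len(x) < 3:
        raise ValueError(f"need at least 3 regions for a convergence regression, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0:
        raise ValueError("initial TSR has zero variance; slope is undefined")
    X = sm.add_constant(x)
    if weights is None:
        result = sm.OLS(y, X).fit()
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != x.shape or (weights <= 0).any():
            raise ValueError("weights must be positive and match x in length")
        result = sm.WLS(y, X, weights=weights).fit()
    alpha, beta = (float(v) for v in result.params)
    with np.errstate(invalid="ignore"):  # constant y makes r-squared 0/0
        r_squared = float(result.rsquared)
    return BetaEstimate(
        component=component,
        alpha=alpha,
        beta=beta,
        se_beta=float(result.bse[1]),
        r_squared=r_squared if np.isfinite(r_squared) else 0.0,
        n_regions=len(x),
    )


def classify(estimate: BetaEstimate, significance: bool = False):
    """'convergence' iff beta < 0, else 'divergence' (sign only, as reported).

    With ``significance=True`` also report whether 0 lies outside the 95%
    interval beta +/- 1.96 * se_beta.
    """
    label = "convergence" if estimate.beta < 0 else "divergence"
    if not significance:
        return label
    significant = abs(estimate.beta) > 1.96 * estimate.se_beta
    return label, significant


def _estimates_frame(estimates: list[BetaEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "component": e.component,
                "period_start": e.period_start,
                "period_end": e.period_end,
                "regressor_year": e.regressor_year,
                "alpha": e.alpha,
                "beta": e.beta,
                "se_beta": e.se_beta,
                "r2": e.r_squared,
                "n_regions": e.n_regions,
            }
            for e in estimates
        ]
    )


def partial_betas(
    components: pd.DataFrame,
    baseline: pd.DataFrame,
    weights=None,
    period: tuple[int, int] | None = None,
    regressor_year: int | None = None,
) -> pd.DataFrame:
    """Regress each component of TSR change on the same baseline TSR.

    ``components`` holds one row per region with the six component columns;
    ``baseline`` maps region -> tsr (columns 'region' and 'tsr').  All
    regressions share the regressor, so the additivity identities hold by
    construction.  Returns a six-row table in :data:`BETAS_SCHEMA` order.
    """
    for col in COMPONENTS:
        if col not in components.columns:
            raise ValueError(f"components table lacks column {col!r}")
    comp_regions = set(components["region"])
    base_regions = set(baseline["region"])
    if comp_regions != base_regions:
        only_comp = sorted(comp_regions - base_regions)
        only_base = sorted(base_regions - comp_regions)
        raise ValueError(
            f"region mismatch between components and baseline "
            f"(components-only: {only_comp[:10]}, baseline-only: {only_base[:10]})"
        )
    if components["region"].duplicated().any():
        raise ValueError("components table has duplicate regions; pass a single period at a time")
    merged = components.merge(baseline[["region", "tsr"]], on="region", validate="one_to_one")
    x = merged["tsr"].to_numpy(dtype=float)
    w = None
    if weights is not None:
        w = (
            merged.merge(weights.rename("weight"), left_on="region", right_index=True)["weight"].to_numpy()
            if isinstance(weights, pd.Series)
            else np.asarray(weights, dtype=float)
        )
    if period is None and {"period_start", "period_end"}.issubset(components.columns):
        period = (int(components["period_start"].iloc[0]), int(components["period_end"].iloc[0]))
    estimates = []
    for comp in COMPONENTS:
        est = ols_beta(x, merged[comp].to_numpy(dtype=float), weights=w, component=comp)
        estimates.append(
            replace(
                est,
                period_start=None if period is None else period[0],
                period_end=None if period is None else period[1],
                regressor_year=regressor_year,
            )
        )
    return _estimates_frame(estimates)


@dataclass
class BetaDecompositionTable:
    """Yearly and pooled beta estimates plus cumulative convergence curves."""

    yearly: pd.DataFrame
    pooled: pd.DataFrame
    cumulative: pd.DataFrame
    decades: list[tuple[int, int]] = field(default_factory=list)

    def estimates(self) -> pd.DataFrame:
        """Yearly and pooled rows concatenated (betas.csv payload)."""
        return pd.concat([self.yearly, self.pooled], ignore_index=True)


def _check_decades(decades: list[tuple[int, int]], years: np.ndarray) -> None:
    if not decades:
        raise ValueError("need at least one (start, end) period")
    for start, end in decades:
        if end <= start:
            raise ValueError(f"period ({start}, {end}) is empty or reversed")
        if start < years.min() or end > years.max():
            raise ValueError(
                f"period ({start}, {end}) falls outside the panel's year range "
                f"{years.min()}..{years.max()}"
            )
    for (_, e1), (s2, _) in zip(decades, decades[1:]):
        if s2 != e1:
            raise ValueError(f"periods must tile the study range contiguously; gap/overlap at {e1} vs {s2}")


def betas_from_components(
    components: pd.DataFrame,
    tsr: pd.DataFrame,
    decades: list[tuple[int, int]],
    weights: str | None = None,
) -> BetaDecompositionTable:
    """Temporal beta decomposition from pre-computed one-year components.

    ``components`` must hold one-year rows (period_end = period_start + 1)
    for every year of every decade; ``tsr`` supplies the decade-initial
    regressor (and region weights when ``weights='pop'``).  Pooled decade
    components are the sums of the yearly components, so yearly betas sum
    exactly to the pooled decade beta.
    """
    decades = sorted((int(s), int(e)) for s, e in decades)
    _check_decades(decades, tsr["year"].to_numpy())
    one_year = components[components["period_end"] == components["period_start"] + 1]
    yearly_rows, pooled_rows = [], []
    for start, end in decades:
        baseline = tsr[tsr["year"] == start]
        if baseline.empty:
            raise ValueError(f"no TSR baseline available for regressor year {start}")
        w = None
        if weights == "pop":
            w = baseline.set_index("region").eval("W + NW")
        elif weights is not None:
            raise ValueError(f"unknown weights option {weights!r} (use 'pop' or None)")
        decade_slices = []
        for t in range(start, end):
            rows = one_year[one_year["period_start"] == t]
            if rows.empty:
                raise ValueError(f"no one-year components for interval [{t}, {t + 1})")
            decade_slices.append(rows)
            yearly_rows.append(
                partial_betas(rows, baseline, weights=w, period=(t, t + 1), regressor_year=start)
            )
        stacked = pd.concat(decade_slices, ignore_index=True)
        pooled = stacked.groupby("region", as_index=False)[list(COMPONENTS)].sum()
        pooled_rows.append(
            partial_betas(pooled, baseline, weights=w, period=(start, end), regressor_year=start)
        )
    yearly = pd.concat(yearly_rows, ignore_index=True)
    pooled = pd.concat(pooled_rows, ignore_index=True)
    cumulative = (
        yearly.sort_values(["component", "period_start"], kind="mergesort")
        .assign(cumulative_beta=lambda d: d.groupby("component")["beta"].cumsum())
        .rename(columns={"period_start": "year"})[
            ["component", "year", "regressor_year", "cumulative_beta"]
        ]
        .reset_index(drop=True)
    )
    return BetaDecompositionTable(yearly=yearly, pooled=pooled, cumulative=cumulative, decades=decades)


def temporal_decomposition(
    panel: pd.DataFrame,
    events: pd.DataFrame,
    decades: list[tuple[int, int]],
    bounds=None,
    mode="observed",
    weights: str | None = None,
) -> BetaDecompositionTable:
    """End-to-end temporal beta decomposition from raw panels.

    ``mode`` is a single mode, a mapping interval-year -> mode, or a
    callable; the regressor resets at each decade boundary.
    """
    from .decomposition import decompose_yearly
    from .support_ratio import DEFAULT_BOUNDS, compute_tsr

    bounds = bounds or DEFAULT_BOUNDS
    decades = sorted((int(s), int(e)) for s, e in decades)
    years = [t for start, end in decades for t in range(start, end)]
    components = decompose_yearly(panel, events, bounds=bounds, mode=mode, years=years)
    tsr = compute_tsr(panel, bounds)
    return betas_from_components(components, tsr, decades, weights=weights)
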