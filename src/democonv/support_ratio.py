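"""Working-age aggregates and the total support ratio (TSR).

The TSR of a population is the ratio of the working-age count W (ages in the
half-open interval [lower, upper), default [15, 65)) to the non-working-age
count NW (everyone else).  It is the inverse of the total dependency ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .panels import PanelError, to_cube, validate_population


@dataclass(frozen=True)
class WorkingAgeBounds:
    """Half-open working-age interval [lower, upper) in completed years."""

    lower: int = 15
    upper: int = 65

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError(f"working-age bounds require 0 < lower < upper, got [{self.lower}, {self.upper})")

    def check_open_age(self, open_age: int) -> None:
        if self.upper > open_age:
            raise ValueError(
                f"working-age upper bound {self.upper} exceeds panel open age {open_age}"
            )

    @classmethod
    def parse(cls, text: str) -> "WorkingAgeBounds":
        """Parse a 'lower:upper' string, e.g. '15:65'."""
        try:
            lower, upper = (int(part) for part in text.split(":"))
        except ValueError as exc:
            raise ValueError(f"cannot parse bounds {text!r}; expected 'lower:upper'") from exc
        return cls(lower, upper)


DEFAULT_BOUNDS = WorkingAgeBounds()


def working_age_counts(
    panel: pd.DataFrame, bounds: WorkingAgeBounds = DEFAULT_BOUNDS
) -> pd.DataFrame:
    """Aggregate a population panel to (region, year, W, NW).

    W sums counts over ages in [lower, upper); NW is the remainder of the
    region-year total.  The panel must carry the full age grid (validated).
    """
    open_age = validate_population(panel)
    bounds.check_open_age(open_age)
    cube = to_cube(panel, "count")
    w = cube.values[:, :, bounds.lower : bounds.upper].sum(axis=2)
    total = cube.values.sum(axis=2)
    nw = total - w
    r, y = w.shape
    out = pd.DataFrame(
        {
            "region": pd.Series(cube.regions).repeat(y).to_numpy(),
            "year": list(cube.years) * r,
            "W": w.ravel(),
            "NW": nw.ravel(),
        }
    )
    return out


def compute_tsr(
    panel: pd.DataFrame, bounds: WorkingAgeBounds = DEFAULT_BOUNDS
) -> pd.DataFrame:
    """Compute the TSR series: (region, year, W, NW, tsr) with tsr = W / NW.

    Raises :class:`PanelError` when any region-year has NW = 0 (the ratio is
    undefined there, never reported as infinity).
    """
    counts = working_age_counts(panel, bounds)
    zero = counts["NW"] <= 0
    if zero.any():
        row = counts[zero].iloc[0]
        raise PanelError(
            f"TSR undefined: non-working-age population is {row['NW']} for "
            f"region {row['region']!r}, year {int(row['year'])}"
        )
    counts = counts.copy()
    counts["tsr"] = counts["W"] / counts["NW"]
    return counts
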