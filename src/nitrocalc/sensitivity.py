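"""One-factor-at-a-time sensitivity sweeps and threshold inversion.

The total nitrosamine per tablet is linear through the origin in the
nitrosamine MW, the tablet dose weight and the conversion fraction (the
other factors held fixed), so each sweep is a family of straight lines —
one per nitrite scenario (min/mean/max) — whose slopes are proportional to
the formulation's weighted nitrite load. Every grid point is computed by a
fresh full evaluation; linearity is an observed property, never an
assumed shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .errors import NoCrossingError, ParameterError
from .model import AdiLimit, Formulation, RunParameters
from .nitrite_db import NitriteDatabase
from .scenario import evaluate

SWEEPABLE = ("nitrosamine_mw", "tablet_weight_mg", "conversion_fraction")


@dataclass(frozen=True)
class SweepResult:
    parameter: str
    grid: tuple[float, ...]
    totals_ng: dict[str, tuple[float, ...]]  # scenario -> totals per grid point
    slopes: dict[str, float]  # scenario -> ng per unit of the parameter

    def tidy(self) -> pd.DataFrame:
        """Long-format table (parameter_value, scenario, total_ng)."""
        rows = [
            {"parameter": self.parameter, "parameter_value": x,
             "scenario": scen, "total_ng": tot}
            for scen, totals in self.totals_ng.items()
            for x, tot in zip(self.grid, totals)
        ]
        return pd.DataFrame(rows)

    def plot(self, path) -> None:
        """Write a PNG of total ng vs the swept parameter, one line per
        nitrite scenario."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for scen, totals in self.totals_ng.items():
            ax.plot(self.grid, totals, marker="o", label=scen)
        ax.set_xlabel(self.parameter)
        ax.set_ylabel("nitrosamine (ng per tablet)")
        ax.legend(title="nitrite scenario")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _at(
    formulation: Formulation, params: RunParameters, parameter: str, value: float
) -> tuple[Formulation, RunParameters]:
    if parameter == "tablet_weight_mg":
        return replace(formulation, tablet_weight_mg=value), params
    return formulation, replace(params, **{parameter: value})


def sweep(
    formulation: Formulation,
    db: NitriteDatabase,
    params: RunParameters,
    parameter: str,
    grid: list[float],
    scenarios: tuple[str, ...] = ("min", "mean", "max"),
) -> SweepResult:
    """Evaluate the formulation over a strictly increasing parameter grid.

    ``scenarios`` selects which nitrite statistic is applied to every
    nitrite-bearing ingredient (per-ingredient overrides in ``params`` are
    cleared for the sweep so the three lines are globally min/mean/max).
    """
    if parameter not in SWEEPABLE:
        raise ParameterError(f"cannot sweep {parameter!r}; one of {SWEEPABLE}")
    if len(grid) < 2:
        raise ParameterError("grid needs at least two points")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ParameterError(f"grid must be strictly increasing, got {grid}")
    if grid[0] <= 0 and parameter != "conversion_fraction":
        raise ParameterError(f"{parameter} grid must be positive, got {grid}")
    if parameter == "conversion_fraction" and (grid[0] < 0 or grid[-1] > 1):
        raise ParameterError(
            f"conversion_fraction grid must lie in [0, 1], got {grid}"
        )
    totals: dict[str, tuple[float, ...]] = {}
    slopes: dict[str, float] = {}
    for scen in scenarios:
        scen_params = replace(params, nitrite_statistic=scen, statistic_overrides={})
        vals = []
        for x in grid:
            f_x, p_x = _at(formulation, scen_params, parameter, x)
            vals.append(evaluate(f_x, db, p_x).total_ng_per_tablet)
        totals[scen] = tuple(vals)
        # zero-intercept line: slope from the last grid point
        slopes[scen] = vals[-1] / grid[-1] if grid[-1] != 0 else 0.0
    return SweepResult(parameter=parameter, grid=tuple(grid), totals_ng=totals,
                       slopes=slopes)


def solve_threshold(
    formulation: Formulation,
    db: NitriteDatabase,
    params: RunParameters,
    parameter: str,
    adi: AdiLimit,
    scenario: str | None = None,
) -> float:
    """Parameter value at which the daily intake exactly meets the ADI.

    Because the response is linear through the origin, the critical value
    is ``limit / slope`` with the slope taken from a single evaluation.
    The returned value may exceed the parameter's physical domain (e.g. a
    conversion fraction above 1), meaning the limit is unreachable within
    it. A zero slope (no nitrite load) raises :class:`NoCrossingError`.
    """
    if parameter not in SWEEPABLE:
        raise ParameterError(f"cannot solve over {parameter!r}; one of {SWEEPABLE}")
    scen_params = params if scenario is None else replace(
        params, nitrite_statistic=scenario, statistic_overrides={}
    )
    ref = 1.0 if parameter != "conversion_fraction" else min(
        1.0, max(scen_params.conversion_fraction, 1e-6)
    )
    f_ref, p_ref = _at(formulation, scen_params, parameter, ref)
    slope = evaluate(f_ref, db, p_ref).total_ng_per_day / ref
    if slope <= 0:
        raise NoCrossingError(
            f"{formulation.label}: zero nitrosamine slope over {parameter}; "
            f"the ADI line is never crossed"
        )
    return adi.limit_ng_per_day / slope
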