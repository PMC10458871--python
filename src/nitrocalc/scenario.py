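"""Scenario engine: evaluate formulations, compare scenarios, check ADIs.

An evaluation walks the ingredient list, resolves each ingredient's nitrite
statistic (per-ingredient overrides model supplier selection), applies the
two-step linear model and sums the per-excipient ng contributions. The API
contributes exactly zero unless explicitly flagged otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError
from .model import (
    AdiLimit,
    Formulation,
    RunParameters,
    nitrosamine_ng_per_excipient,
    nitrosamine_ppm,
)
from .nitrite_db import NitriteDatabase


@dataclass(frozen=True)
class EvaluationResult:
    """Per-excipient and total theoretical nitrosamine for one scenario."""

    formulation_label: str
    per_excipient_ng: dict[str, float]
    total_ng_per_tablet: float
    total_ng_per_day: float
    parameters: RunParameters
    statistic_used: dict[str, str | None]

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        """Display form: ng values rounded to one decimal."""
        return {k: round(v, ndigits) for k, v in self.per_excipient_ng.items()}


@dataclass(frozen=True)
class ComparisonResult:
    """Baseline-vs-alternative delta; reduction is negative."""

    baseline: EvaluationResult
    alternative: EvaluationResult
    percent_change: float | None  # None when the baseline total is zero
    per_excipient_delta_ng: dict[str, float]

    @property
    def percent_change_display(self) -> str:
        """Percent change rounded to the nearest integer, signed (e.g. '-36%');
        'n/a' when the baseline total is zero."""
        if self.percent_change is None:
            return "n/a"
        return f"{round(self.percent_change):+d}%"


def evaluate(
    formulation: Formulation, db: NitriteDatabase, params: RunParameters
) -> EvaluationResult:
    """Theoretical nitrosamine formed in one tablet of ``formulation``.

    Each nitrite-bearing ingredient contributes
    ``tablet_weight * fraction * nitrite_ppm * MW_ratio * conversion`` ng;
    ingredients with ``counts_nitrite=False`` (the API) contribute 0.
    """
    per: dict[str, float] = {}
    stat_used: dict[str, str | None] = {}
    for ing in formulation.ingredients:
        if not ing.counts_nitrite:
            per[ing.name] = 0.0
            stat_used[ing.name] = None
            continue
        statistic = params.statistic_for(ing.name)
        stats = ing.stats if ing.stats is not None else db.get(ing.key)
        ppm = nitrosamine_ppm(
            stats.statistic(statistic),
            params.nitrosamine_mw,
            params.conversion_fraction,
            params.nitrite_mw,
        )
        per[ing.name] = nitrosamine_ng_per_excipient(
            formulation.tablet_weight_mg, ing.fraction_ww, ppm
        )
        stat_used[ing.name] = statistic
    total = math.fsum(per.values())
    return EvaluationResult(
        formulation_label=formulation.label,
        per_excipient_ng=per,
        total_ng_per_tablet=total,
        total_ng_per_day=total * params.tablets_per_day,
        parameters=params,
        statistic_used=stat_used,
    )


def compare(baseline: EvaluationResult, alternative: EvaluationResult) -> ComparisonResult:
    """Relative change of the alternative scenario against the baseline.

    Requires both evaluations to share the nitrosamine MW, nitrite MW and
    dose regimen so the percent change reflects the formulation/supplier
    change alone. A zero-baseline comparison yields ``percent_change=None``
    rather than an infinity.
    """
    bp, ap = baseline.parameters, alternative.parameters
    for attr in ("nitrosamine_mw", "nitrite_mw", "tablets_per_day"):
        if getattr(bp, attr) != getattr(ap, attr):
            raise ParameterError(
                f"cannot compare scenarios with different {attr}: "
                f"{getattr(bp, attr)} vs {getattr(ap, attr)}"
            )
    names = list(baseline.per_excipient_ng)
    names += [n for n in alternative.per_excipient_ng if n not in names]
    delta = {
        n: alternative.per_excipient_ng.get(n, 0.0) - baseline.per_excipient_ng.get(n, 0.0)
        for n in names
    }
    if baseline.total_ng_per_tablet > 0:
        pct = 100.0 * (
            alternative.total_ng_per_tablet - baseline.total_ng_per_tablet
        ) / baseline.total_ng_per_tablet
    else:
        pct = None
    return ComparisonResult(baseline, alternative, pct, delta)


def percent_change(baseline_total: float, alternative_total: float) -> float:
    """Closed-form percent change between two totals (ng); baseline > 0."""
    if baseline_total <= 0:
        raise ParameterError(f"baseline total must be > 0, got {baseline_total}")
    return 100.0 * (alternative_total - baseline_total) / baseline_total


@dataclass(frozen=True)
class AdiVerdict:
    limit: AdiLimit
    total_ng_per_day: float
    compliant: bool
    margin_ng: float  # limit - total; negative when exceeded
    at_limit: bool


def classify_adi(result: EvaluationResult, limits: list[AdiLimit]) -> list[AdiVerdict]:
    """Compliance of the daily intake against each acceptable-intake limit.

    A total exactly at the limit counts as compliant (the limit is an
    acceptable intake) and is flagged ``at_limit``.
    """
    if not limits:
        raise ParameterError("ADI limit list must be non-empty")
    total = result.total_ng_per_day
    return [
        AdiVerdict(
            limit=lim,
            total_ng_per_day=total,
            compliant=total <= lim.limit_ng_per_day,
            margin_ng=lim.limit_ng_per_day - total,
            at_limit=total == lim.limit_ng_per_day,
        )
        for lim in limits
    ]


def contribution_table(result: EvaluationResult) -> pd.DataFrame:
    """Per-excipient breakdown ordered by contribution, with percent of total.

    Percentages sum to 100 for a positive total; a zero-total evaluation is
    flagged in ``df.attrs['zero_total']`` with an all-zero percent column.
    """
    total = result.total_ng_per_tablet
    rows = sorted(result.per_excipient_ng.items(), key=lambda kv: -kv[1])
    df = pd.DataFrame(rows, columns=["ingredient", "ng_per_tablet"])
    if total > 0:
        df["percent_of_total"] = 100.0 * df["ng_per_tablet"] / total
        df.attrs["zero_total"] = False
    else:
        df["percent_of_total"] = 0.0
        df.attrs["zero_total"] = True
    df.attrs["total_ng_per_tablet"] = total
    return df
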