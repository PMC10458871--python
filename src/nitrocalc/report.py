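"""Machine-readable run reports (JSON + CSV), versioned and deterministic.

Identical inputs produce byte-identical JSON: keys are sorted and floats
are serialized with a fixed 12-significant-digit format. Every report
embeds the nitrite database provenance and the nitrite MW constant used,
so a result can be audited and reproduced.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from .model import RunParameters
from .nitrite_db import NitriteDatabase
from .scenario import AdiVerdict, ComparisonResult, EvaluationResult, contribution_table
from .sensitivity import SweepResult

SCHEMA_VERSION = "1"


def _num(value: float) -> float:
    """Fixed-precision float for stable serialization."""
    return float(f"{float(value):.12g}")


def _params_dict(params: RunParameters) -> dict[str, Any]:
    return {
        "nitrosamine_mw": _num(params.nitrosamine_mw),
        "conversion_fraction": _num(params.conversion_fraction),
        "nitrite_mw": _num(params.nitrite_mw),
        "tablets_per_day": params.tablets_per_day,
        "nitrite_statistic": params.nitrite_statistic,
        "statistic_overrides": dict(sorted(params.statistic_overrides.items())),
    }


def evaluation_dict(
    result: EvaluationResult,
    db: NitriteDatabase,
    verdicts: list[AdiVerdict] | None = None,
) -> dict[str, Any]:
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "formulation": result.formulation_label,
        "parameters": _params_dict(result.parameters),
        "nitrite_db": dict(sorted(db.metadata.items())),
        "per_excipient_ng": {k: _num(v) for k, v in result.per_excipient_ng.items()},
        "statistic_used": dict(result.statistic_used),
        "total_ng_per_tablet": _num(result.total_ng_per_tablet),
        "total_ng_per_day": _num(result.total_ng_per_day),
        # display convention: ng to one decimal
        "total_ng_per_day_display": round(result.total_ng_per_day, 1),
    }
    if verdicts is not None:
        doc["adi_verdicts"] = [
            {
                "limit": v.limit.label,
                "limit_ng_per_day": _num(v.limit.limit_ng_per_day),
                "compliant": v.compliant,
                "at_limit": v.at_limit,
                "margin_ng": _num(v.margin_ng),
            }
            for v in verdicts
        ]
    return doc


def comparison_dict(
    cmp: ComparisonResult, db: NitriteDatabase
) -> dict[str, Any]:
    return {
        "schema_version": SCHEMA_VERSION,
        "baseline": evaluation_dict(cmp.baseline, db),
        "alternative": evaluation_dict(cmp.alternative, db),
        "percent_change": None if cmp.percent_change is None else _num(cmp.percent_change),
        # display convention: percent change to the nearest integer
        "percent_change_display": cmp.percent_change_display,
        "per_excipient_delta_ng": {
            k: _num(v) for k, v in cmp.per_excipient_delta_ng.items()
        },
    }


def dump_json(doc: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def write_evaluation_csv(result: EvaluationResult, path: str | Path) -> Path:
    path = Path(path)
    contribution_table(result).to_csv(path, index=False)
    return path


def write_sweep_csv(result: SweepResult, path: str | Path) -> Path:
    path = Path(path)
    result.tidy().to_csv(path, index=False)
    return path
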