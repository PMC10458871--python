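"""Formulation file I/O (YAML).

Schema::

    label: wg-200mg-crospovidone
    tablet_weight_mg: 200
    ingredients:
      - {name: API, percent_ww: 10, role: api}
      - {name: Lactose, percent_ww: 60}
      - {name: Crospovidone, percent_ww: 5, nitrite_key: crospovidone}

Percentages follow the human convention (percent w/w) and are divided by
100 at parse time. ``role: api`` excludes the ingredient from the nitrite
budget unless ``counts_nitrite: true`` overrides it.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .errors import SchemaError
from .model import Formulation, Ingredient, NitriteStats


def _ingredient_from_entry(entry: dict, idx: int) -> Ingredient:
    if not isinstance(entry, dict):
        raise SchemaError(f"ingredient {idx}: expected a mapping, got {type(entry).__name__}")
    try:
        name = str(entry["name"])
        if "fraction_ww" in entry:  # exact machine fraction, written on export
            fraction = float(entry["fraction_ww"])
        else:
            fraction = float(entry["percent_ww"]) / 100.0
    except KeyError as exc:
        raise SchemaError(f"ingredient {idx}: missing field {exc.args[0]!r}") from None
    except (TypeError, ValueError):
        raise SchemaError(
            f"ingredient {idx} ({entry.get('name')}): non-numeric percent_ww "
            f"{entry.get('percent_ww')!r}"
        ) from None
    role = str(entry.get("role", "excipient")).lower()
    if role not in ("api", "excipient"):
        raise SchemaError(f"ingredient {idx} ({name}): unknown role {role!r}")
    counts = entry.get("counts_nitrite", role != "api")
    stats = None
    if "nitrite_ppm" in entry:  # inline single-value override
        stats = NitriteStats.constant(name, float(entry["nitrite_ppm"]), source="inline")
    elif "nitrite_stats" in entry:
        s = entry["nitrite_stats"]
        stats = NitriteStats(name, float(s["min_ppm"]), float(s["mean_ppm"]),
                             float(s["max_ppm"]), source="inline")
    return Ingredient(
        name=name,
        fraction_ww=fraction,
        nitrite_key=entry.get("nitrite_key"),
        stats=stats,
        counts_nitrite=bool(counts),
    )


def load_formulation(path: str | Path, normalize: bool = False) -> Formulation:
    """Parse and validate a formulation YAML file.

    ``normalize=True`` rescales a composition whose percents do not close
    to 100; by default an off-by-more-than-0.1-point composition fails.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise SchemaError(f"{path.name}: expected a mapping at top level")
    for fld in ("label", "tablet_weight_mg", "ingredients"):
        if fld not in doc:
            raise SchemaError(f"{path.name}: missing field {fld!r}")
    ingredients = [
        _ingredient_from_entry(e, i) for i, e in enumerate(doc["ingredients"], start=1)
    ]
    if normalize:
        total = sum(i.fraction_ww for i in ingredients)
        if total <= 0:
            raise SchemaError(f"{path.name}: cannot normalize zero-total composition")
        from dataclasses import replace
        ingredients = [replace(i, fraction_ww=i.fraction_ww / total) for i in ingredients]
    return Formulation(
        label=str(doc["label"]),
        tablet_weight_mg=float(doc["tablet_weight_mg"]),
        ingredients=tuple(ingredients),
    )


def write_formulation(formulation: Formulation, path: str | Path) -> Path:
    path = Path(path)
    entries = []
    for ing in formulation.ingredients:
        entry: dict[str, object] = {
            "name": ing.name,
            "percent_ww": round(ing.fraction_ww * 100.0, 6),
            "fraction_ww": ing.fraction_ww,
        }
        if not ing.counts_nitrite:
            entry["role"] = "api"
        if ing.nitrite_key:
            entry["nitrite_key"] = ing.nitrite_key
        if ing.stats is not None:
            entry["nitrite_stats"] = {
                "min_ppm": ing.stats.min_ppm,
                "mean_ppm": ing.stats.mean_ppm,
                "max_ppm": ing.stats.max_ppm,
            }
        entries.append(entry)
    doc = {
        "label": formulation.label,
        "tablet_weight_mg": formulation.tablet_weight_mg,
        "ingredients": entries,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def packaged_formulation_path(name: str) -> Path:
    return Path(
        importlib.resources.files("nitrocalc").joinpath("data", "formulations", name)  # type: ignore[arg-type]
    )
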