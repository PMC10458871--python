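"""Core model: domain types and the two equations driving every calculation.

Nitrosamine build-up in a tablet is modeled as a two-step linear chain.
First, the nitrosamine formed *within* one excipient, expressed as a mass
fraction of that excipient (ppm, i.e. µg nitrosamine per g excipient):

    nitrosamine_ppm = nitrite_ppm * MW_nitrosamine * conversion / MW_nitrite

where ``nitrite_ppm`` is the trace nitrite impurity level of the excipient,
``conversion`` is the molar fraction of that nitrite which reacts with the
secondary amine during processing and storage (a plateau value, well below
1 in the solid state), and the molecular-weight ratio converts moles of
nitrite consumed into mass of nitrosamine formed.

Second, the absolute contribution of the excipient to one tablet:

    ng_per_tablet = tablet_weight_mg * fraction_ww * nitrosamine_ppm

The unit bookkeeping is exact: mg excipient × (µg/g == ng/mg) = ng.

Both relations are homogeneous (linear through the origin) in each factor;
that linearity is what the sensitivity module exploits.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Mapping

from .errors import ConversionLookupError, FormulationError, ParameterError

#: Molecular weight of the nitrite ion NO2−, g/mol. The mole-to-mass
#: conversion in the ppm equation is referenced to the ion, not to a
#: nitrite salt; override via RunParameters.nitrite_mw if needed.
NITRITE_MW = 46.005

#: Statistics a nitrite record can be queried for.
STATISTICS = ("min", "mean", "max")

_WS = re.compile(r"\s+")


def normalize_key(name: str) -> str:
    """Case-insensitive, whitespace-collapsed excipient key."""
    return _WS.sub(" ", name.strip()).casefold()


def _require_finite(value: float, name: str) -> float:
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class NitriteStats:
    """Min/mean/max nitrite impurity level of one excipient, in ppm w/w
    (µg nitrite per g excipient). The triple represents the best-, average-
    and worst-case supplier scenarios."""

    excipient: str
    min_ppm: float
    mean_ppm: float
    max_ppm: float
    n_samples: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        for fname in ("min_ppm", "mean_ppm", "max_ppm"):
            _require_finite(getattr(self, fname), f"{self.excipient}: {fname}")
        if not (0 <= self.min_ppm <= self.mean_ppm <= self.max_ppm):
            raise ParameterError(
                f"{self.excipient}: nitrite statistics must satisfy "
                f"0 <= min <= mean <= max, got "
                f"({self.min_ppm}, {self.mean_ppm}, {self.max_ppm})"
            )

    @classmethod
    def constant(cls, excipient: str, ppm: float, source: str = "") -> "NitriteStats":
        """Degenerate triple min = mean = max = ppm (single known value)."""
        return cls(excipient, ppm, ppm, ppm, source=source)

    def statistic(self, which: str) -> float:
        if which not in STATISTICS:
            raise ParameterError(
                f"unknown nitrite statistic {which!r}; expected one of {STATISTICS}"
            )
        return getattr(self, f"{which}_ppm")


@dataclass(frozen=True)
class Ingredient:
    """One formulation component.

    ``fraction_ww`` is the dimensionless mass fraction (percent w/w ÷ 100).
    ``counts_nitrite`` is False for the API: the drug substance's own
    nitrite contribution is not modeled, only the excipients'.
    ``nitrite_key`` names the database record to use (defaults to the
    ingredient name); ``stats`` may carry an inline override instead.
    """

    name: str
    fraction_ww: float
    nitrite_key: str | None = None
    stats: NitriteStats | None = None
    counts_nitrite: bool = True

    def __post_init__(self) -> None:
        _require_finite(self.fraction_ww, f"{self.name}: fraction_ww")
        if not 0 <= self.fraction_ww <= 1:
            raise ParameterError(
                f"{self.name}: fraction_ww must be in [0, 1], got {self.fraction_ww}"
            )

    @property
    def key(self) -> str:
        return normalize_key(self.nitrite_key or self.name)


#: Σ fraction_ww must equal 1 within this tolerance (0.1 percentage point).
COMPOSITION_TOL = 1e-3


@dataclass(frozen=True)
class Formulation:
    """A tablet: label, dose weight in mg, and its ordered ingredient list.

    Mass fractions must close to 100 % w/w within 0.1 percentage point;
    use :meth:`normalized` to rescale a slightly-off composition explicitly
    rather than silently.
    """

    label: str
    tablet_weight_mg: float
    ingredients: tuple[Ingredient, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ingredients", tuple(self.ingredients))
        _require_finite(self.tablet_weight_mg, f"{self.label}: tablet_weight_mg")
        if self.tablet_weight_mg <= 0:
            raise FormulationError(
                f"{self.label}: tablet_weight_mg must be positive, "
                f"got {self.tablet_weight_mg}"
            )
        if not self.ingredients:
            raise FormulationError(f"{self.label}: ingredient list is empty")
        names = [normalize_key(i.name) for i in self.ingredients]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FormulationError(f"{self.label}: duplicate ingredient names {dupes}")
        total = math.fsum(i.fraction_ww for i in self.ingredients)
        if abs(total - 1.0) > COMPOSITION_TOL:
            raise FormulationError(
                f"{self.label}: ingredient fractions sum to {total:.6f}, "
                f"expected 1.0 within {COMPOSITION_TOL} "
                f"(pass normalize=True at load time to rescale)"
            )

    def normalized(self) -> "Formulation":
        """Rescale fractions to close exactly to 1 (explicit opt-in)."""
        total = math.fsum(i.fraction_ww for i in self.ingredients)
        return replace(
            self,
            ingredients=tuple(
                replace(i, fraction_ww=i.fraction_ww / total) for i in self.ingredients
            ),
        )

    def replacing(self, name: str, new: Ingredient) -> "Formulation":
        """Swap one ingredient for another (e.g. crospovidone for
        croscarmellose sodium at the same fraction)."""
        key = normalize_key(name)
        if not any(normalize_key(i.name) == key for i in self.ingredients):
            raise FormulationError(f"{self.label}: no ingredient named {name!r}")
        out = tuple(
            new if normalize_key(i.name) == key else i for i in self.ingredients
        )
        return replace(self, ingredients=out)

    def ingredient(self, name: str) -> Ingredient:
        key = normalize_key(name)
        for ing in self.ingredients:
            if normalize_key(ing.name) == key:
                return ing
        raise FormulationError(f"{self.label}: no ingredient named {name!r}")


@dataclass(frozen=True)
class RunParameters:
    """Everything about a run that is not the formulation or the nitrite DB.

    nitrosamine_mw : g/mol of the nitrosamine expected to form (an NDSRI is
        typically near 400; NDEA is 102).
    conversion_fraction : molar fraction of nitrite converting, in [0, 1].
    nitrite_mw : g/mol; defaults to the NO2− ion.
    tablets_per_day : dose regimen multiplier for the ng/day total.
    nitrite_statistic : which database statistic to use ("min"/"mean"/"max").
    statistic_overrides : per-ingredient statistic, keyed by normalized
        ingredient name — e.g. {"mcc": "min"} models switching only the MCC
        supplier while everything else stays at the average.
    """

    nitrosamine_mw: float
    conversion_fraction: float
    nitrite_mw: float = NITRITE_MW
    tablets_per_day: int = 1
    nitrite_statistic: str = "mean"
    statistic_overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if _require_finite(self.nitrosamine_mw, "nitrosamine_mw") <= 0:
            raise ParameterError(f"nitrosamine_mw must be > 0, got {self.nitrosamine_mw}")
        if _require_finite(self.nitrite_mw, "nitrite_mw") <= 0:
            raise ParameterError(f"nitrite_mw must be > 0, got {self.nitrite_mw}")
        conv = _require_finite(self.conversion_fraction, "conversion_fraction")
        if not 0 <= conv <= 1:
            raise ParameterError(
                f"conversion_fraction must be in [0, 1], got {conv}"
            )
        if self.tablets_per_day < 1:
            raise ParameterError(
                f"tablets_per_day must be >= 1, got {self.tablets_per_day}"
            )
        if self.nitrite_statistic not in STATISTICS:
            raise ParameterError(
                f"nitrite_statistic must be one of {STATISTICS}, "
                f"got {self.nitrite_statistic!r}"
            )
        object.__setattr__(
            self,
            "statistic_overrides",
            {normalize_key(k): v for k, v in dict(self.statistic_overrides).items()},
        )
        for k, v in self.statistic_overrides.items():
            if v not in STATISTICS:
                raise ParameterError(
                    f"statistic override for {k!r} must be one of {STATISTICS}, got {v!r}"
                )

    def statistic_for(self, ingredient_name: str) -> str:
        return self.statistic_overrides.get(
            normalize_key(ingredient_name), self.nitrite_statistic
        )


@dataclass(frozen=True)
class AdiLimit:
    """An acceptable-intake ceiling in ng nitrosamine per day."""

    label: str
    limit_ng_per_day: float

    def __post_init__(self) -> None:
        if _require_finite(self.limit_ng_per_day, "limit_ng_per_day") <= 0:
            raise ParameterError(
                f"{self.label}: limit_ng_per_day must be > 0, "
                f"got {self.limit_ng_per_day}"
            )


# Regulatory acceptable-intake limits in common use for these assessments:
# the conservative 18 ng/day default for NDSRIs without compound data, the
# EMA interim 178 ng/day for NDSRIs, NDEA's 26.5 ng/day, and the EMA
# potency-category ceilings 1500/400/100/18 ng/day.
ADI_REGISTRY: dict[str, AdiLimit] = {
    lim.label: lim
    for lim in (
        AdiLimit("ndsri-default-18", 18.0),
        AdiLimit("ndsri-interim-ema-178", 178.0),
        AdiLimit("ndea-26.5", 26.5),
        AdiLimit("ema-category-1", 1500.0),
        AdiLimit("ema-category-2", 400.0),
        AdiLimit("ema-category-3", 100.0),
        AdiLimit("ema-category-4", 18.0),
    )
}


def adi_limit(label: str) -> AdiLimit:
    try:
        return ADI_REGISTRY[label]
    except KeyError:
        raise ConversionLookupError(
            f"no registered ADI limit {label!r}; known: {sorted(ADI_REGISTRY)}"
        ) from None


# --------------------------------------------------------------------------
# The two equations


def nitrosamine_ppm(
    nitrite_ppm: float,
    nitrosamine_mw: float,
    conversion_fraction: float,
    nitrite_mw: float = NITRITE_MW,
) -> float:
    """Nitrosamine formed within one excipient, as ppm w/w of that excipient.

    Multiplies the excipient's nitrite level (µg/g) by the molar conversion
    fraction and the nitrosamine/nitrite molecular-weight ratio. Linear in
    each argument; zero iff nitrite, MW or conversion is zero.
    """
    for val, name in (
        (nitrite_ppm, "nitrite_ppm"),
        (nitrosamine_mw, "nitrosamine_mw"),
        (conversion_fraction, "conversion_fraction"),
        (nitrite_mw, "nitrite_mw"),
    ):
        if _require_finite(val, name) < 0:
            raise ParameterError(f"{name} must be nonnegative, got {val}")
    if nitrite_mw == 0:
        raise ParameterError("nitrite_mw must be > 0")
    return nitrite_ppm * nitrosamine_mw * conversion_fraction / nitrite_mw


def nitrosamine_ng_per_excipient(
    tablet_weight_mg: float,
    fraction_ww: float,
    nitrosamine_ppm_value: float,
) -> float:
    """Absolute nitrosamine contribution of one excipient, in ng per tablet.

    ppm w/w is ng per mg, so mg of excipient in the tablet times its
    nitrosamine ppm is directly ng.
    """
    if _require_finite(tablet_weight_mg, "tablet_weight_mg") <= 0:
        raise ParameterError(f"tablet_weight_mg must be > 0, got {tablet_weight_mg}")
    if not 0 <= _require_finite(fraction_ww, "fraction_ww") <= 1:
        raise ParameterError(f"fraction_ww must be in [0, 1], got {fraction_ww}")
    if _require_finite(nitrosamine_ppm_value, "nitrosamine_ppm") < 0:
        raise ParameterError(
            f"nitrosamine_ppm must be nonnegative, got {nitrosamine_ppm_value}"
        )
    return tablet_weight_mg * fraction_ww * nitrosamine_ppm_value


# --------------------------------------------------------------------------
# Conversion-fraction registry

ConversionKey = tuple[str, str, str, str]  # amine_type, amine_form, process, amine_class


def _conversion_key(
    amine_type: str, amine_form: str, process: str, amine_class: str
) -> ConversionKey:
    return (
        normalize_key(amine_type),
        normalize_key(amine_form),
        normalize_key(process),
        normalize_key(amine_class),
    )


class ConversionRegistry:
    """Tabulated plateau conversion fractions of nitrite into nitrosamine.

    Keyed by (amine type, amine form, manufacturing process, amine class).
    The defaults are the measured plateau values for nitrite-spiked tablet
    formulations: 13 % for direct compression of a secondary-amine salt API
    (NDSRI), 29 % for wet granulation of the same, and 2.2 % for low-level
    amine impurities under wet granulation. Unknown combinations raise —
    never a silent default.
    """

    def __init__(self, entries: Mapping[ConversionKey, float] | None = None):
        self._entries: dict[ConversionKey, float] = dict(entries or {})

    def register(
        self,
        amine_type: str,
        amine_form: str,
        process: str,
        amine_class: str,
        fraction: float,
    ) -> None:
        if not 0 <= _require_finite(fraction, "conversion fraction") <= 1:
            raise ParameterError(f"conversion fraction must be in [0, 1], got {fraction}")
        self._entries[_conversion_key(amine_type, amine_form, process, amine_class)] = float(
            fraction
        )

    def lookup(
        self, amine_type: str, amine_form: str, process: str, amine_class: str
    ) -> float:
        key = _conversion_key(amine_type, amine_form, process, amine_class)
        try:
            return self._entries[key]
        except KeyError:
            raise ConversionLookupError(
                f"no conversion fraction registered for "
                f"(amine_type={key[0]!r}, amine_form={key[1]!r}, "
                f"process={key[2]!r}, amine_class={key[3]!r}); "
                f"registered combinations: {sorted(self._entries)}"
            ) from None

    def items(self):
        return self._entries.items()


DEFAULT_CONVERSIONS = ConversionRegistry(
    {
        _conversion_key("secondary", "salt", "DC", "NDSRI"): 0.13,
        _conversion_key("secondary", "salt", "WG", "NDSRI"): 0.29,
        _conversion_key("secondary", "salt", "WG", "low-level-impurity"): 0.022,
    }
)


def default_conversion(
    amine_type: str, amine_form: str, process: str, amine_class: str = "NDSRI"
) -> float:
    """Look up a conversion fraction in the default registry."""
    return DEFAULT_CONVERSIONS.lookup(amine_type, amine_form, process, amine_class)
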