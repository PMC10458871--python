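"""Seeded synthetic formulations and nitrite databases, plus the bundled
case-study compositions.

Generated objects pass exactly the same validators as user-supplied files;
there are no fixture backdoors. Generation is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .formulation_io import load_formulation, packaged_formulation_path
from .model import Formulation, Ingredient, NitriteStats
from .nitrite_db import NitriteDatabase

#: Names of the bundled case-study formulation files.
CASE_STUDY_FILES = (
    "dc_200mg.yaml",
    "wg_200mg_crospovidone.yaml",
    "wg_200mg_croscarmellose.yaml",
    "wg_1000mg_ndea.yaml",
)


def case_study_formulations() -> dict[str, Formulation]:
    """The four bundled model tablets: a 200 mg direct-compression
    formulation, the 200 mg wet-granulated formulation with either
    crospovidone or croscarmellose sodium as superdisintegrant, and the
    1000 mg wet-granulated tablet used for the small-nitrosamine (NDEA)
    case. Keyed by formulation label."""
    out = {}
    for fname in CASE_STUDY_FILES:
        form = load_formulation(packaged_formulation_path(fname))
        out[form.label] = form
    return out


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic generators.

    Defaults emulate a realistic immediate-release tablet: 4–10 ingredients,
    an API at 5–30 % w/w, a 100–1000 mg dose and nitrite levels spanning the
    0–10 ppm range over which real excipients vary.
    """

    seed: int
    n_ingredients: int = 6
    nitrite_lo_ppm: float = 0.0
    nitrite_hi_ppm: float = 10.0
    tablet_weight_lo_mg: float = 100.0
    tablet_weight_hi_mg: float = 1000.0
    api_fraction_lo: float = 0.05
    api_fraction_hi: float = 0.30

    def __post_init__(self) -> None:
        if self.n_ingredients < 1:
            raise ParameterError(f"n_ingredients must be >= 1, got {self.n_ingredients}")
        for lo, hi, what in (
            (self.nitrite_lo_ppm, self.nitrite_hi_ppm, "nitrite range"),
            (self.tablet_weight_lo_mg, self.tablet_weight_hi_mg, "tablet weight range"),
            (self.api_fraction_lo, self.api_fraction_hi, "api fraction range"),
        ):
            if not 0 <= lo <= hi:
                raise ParameterError(f"invalid {what}: ({lo}, {hi})")
        if self.tablet_weight_lo_mg <= 0:
            raise ParameterError("tablet weight must be positive")
        if self.api_fraction_hi >= 1:
            raise ParameterError("api fraction must stay below 1")


def excipient_names(n: int) -> list[str]:
    return [f"EXC-{i:02d}" for i in range(1, n + 1)]


def generate_formulation(spec: FixtureSpec) -> Formulation:
    """A random tablet whose first ingredient is the API (excluded from the
    nitrite budget) followed by synthetic excipients.

    Excipient fractions are closed to exactly 100 % w/w by largest-remainder
    rounding on 0.01-percentage-point units, so the result passes the
    composition validator without any tolerance games.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_ingredients
    if n == 1:
        return Formulation(
            label=f"synthetic-{spec.seed}",
            tablet_weight_mg=float(rng.uniform(spec.tablet_weight_lo_mg,
                                               spec.tablet_weight_hi_mg)),
            ingredients=(Ingredient("EXC-01", 1.0),),
        )
    api_fraction = float(rng.uniform(spec.api_fraction_lo, spec.api_fraction_hi))
    raw = rng.random(n - 1)
    shares = raw / raw.sum() * (1.0 - api_fraction)
    # largest-remainder closing in units of 1e-4 (0.01 % w/w)
    units_total = 10_000
    api_units = int(round(api_fraction * units_total))
    exc_target = units_total - api_units
    scaled = shares / shares.sum() * exc_target
    floors = np.floor(scaled).astype(int)
    remainder = exc_target - floors.sum()
    order = np.argsort(-(scaled - floors))
    floors[order[:remainder]] += 1
    names = excipient_names(n - 1)
    ingredients = [Ingredient("API", api_units / units_total, counts_nitrite=False)]
    ingredients += [
        Ingredient(name, int(u) / units_total) for name, u in zip(names, floors)
    ]
    return Formulation(
        label=f"synthetic-{spec.seed}",
        tablet_weight_mg=float(rng.uniform(spec.tablet_weight_lo_mg,
                                           spec.tablet_weight_hi_mg)),
        ingredients=tuple(ingredients),
    )


def generate_nitrite_db(spec: FixtureSpec, names: list[str] | None = None) -> NitriteDatabase:
    """A random database covering ``names`` (default: the excipient names
    :func:`generate_formulation` produces for the same spec). Each record's
    min/mean/max triple is three uniform draws, sorted — the ordering
    invariant holds by construction."""
    rng = np.random.default_rng(spec.seed + 1)  # decoupled from the formulation stream
    if names is None:
        names = excipient_names(max(spec.n_ingredients - 1, 1))
    db = NitriteDatabase(metadata={"source": f"synthetic (seed {spec.seed})",
                                   "units": "ppm w/w"})
    for name in names:
        triple = np.sort(rng.uniform(spec.nitrite_lo_ppm, spec.nitrite_hi_ppm, size=3))
        db.add(
            NitriteStats(
                excipient=name,
                min_ppm=float(triple[0]),
                mean_ppm=float(triple[1]),
                max_ppm=float(triple[2]),
                source="synthetic",
            )
        )
    return db
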