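"""Check a calculated daily nitrosamine intake against regulatory limits.

A product totalling 45 ng/day is screened against the conservative 18
ng/day NDSRI default, the EMA interim 178 ng/day, and the four EMA
potency-category ceilings.
"""

import nitrocalc as nc

params = nc.RunParameters(nitrosamine_mw=400.0, conversion_fraction=0.29)
result = nc.EvaluationResult("reformulated", {"all": 45.0}, 45.0, 45.0,
                             params, {"all": "min"})
limits = [nc.adi_limit(lbl) for lbl in
          ("ndsri-default-18", "ndsri-interim-ema-178",
           "ema-category-1", "ema-category-2", "ema-category-3", "ema-category-4")]

for v in nc.classify_adi(result, limits):
    state = "compliant" if v.compliant else "EXCEEDS"
    print(f"{v.limit.label:>22} ({v.limit.limit_ng_per_day:6.1f} ng/day): "
          f"{state:9} margin {v.margin_ng:+7.1f} ng")
print("-> 45 ng/day clears the interim 178 ng/day NDSRI limit comfortably "
      "but would still exceed an 18 ng/day compound-specific limit.")
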