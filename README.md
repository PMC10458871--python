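# nitrocalc

Theoretical nitrosamine formation in solid oral dosage forms, computed from
the trace nitrite impurity levels of the excipients.

Nitrosamines — probable human carcinogens — form in tablets when nitrite
impurities in excipients react with secondary amines (most often the API
itself, giving a nitrosamine drug substance-related impurity, NDSRI).
Nitrite is the rate-limiting reagent, and only a plateau fraction of it
converts in the solid state, so the expected build-up is a simple linear
function of measurable inputs. `nitrocalc` gives formulation and regulatory
scientists a tested implementation of that calculation for preliminary
risk screening and for quantifying how excipient or supplier selection
de-risks a product.

## The model

For each excipient, the nitrosamine formed within it (ppm w/w, i.e. µg per
g of excipient):

```
nitrosamine_ppm = nitrite_ppm × MW_nitrosamine × f_conv / MW_nitrite
```

and its absolute contribution to one tablet (ppm w/w ≡ ng/mg):

```
ng_per_tablet = tablet_weight_mg × fraction_ww × nitrosamine_ppm
```

where `nitrite_ppm` is the excipient's nitrite level (min, mean or max of
the supplier distribution — best, average or worst case), `f_conv` is the
molar plateau conversion fraction (registry defaults: 13 % for direct
compression of a secondary-amine salt API, 29 % for wet granulation,
2.2 % for low-level amine impurities), and `MW_nitrite` = 46.005 g/mol
(the NO₂⁻ ion). The tablet total is the sum over excipients; the API is
excluded from the nitrite budget. Totals are compared against
acceptable-intake limits (18 and 178 ng/day for NDSRIs, 26.5 ng/day for
NDEA, EMA potency categories 1500/400/100/18 ng/day). Because the model is
linear through the origin in nitrosamine MW, dose weight and conversion,
one-factor sweeps are straight lines and the parameter value that exactly
meets an ADI is `limit / slope`.

## Worked example

Swapping the superdisintegrant of the bundled 200 mg wet-granulated tablet
from crospovidone (mean nitrite 6.5 ppm) to croscarmellose sodium
(0.42 ppm) at 5 % w/w (`python examples/02_excipient_swap_comparison.py`):

```
swap effect: -153.3 ng per tablet
relative to the 422 ng original total: -36.3% (reported as -36%)
```

The 10 mg of crospovidone carries 65 ng of nitrite-equivalents; at 29 %
conversion into a 400 g/mol nitrosamine that is 163.9 ng per tablet
(`examples/01_single_tablet_evaluation.py`), and replacing it removes just
over a third of the original product's 422 ng total — a large effect from
a minor excipient, because crospovidone's nitrite level is an order of
magnitude above other disintegrants'. The other examples cover ADI
compliance verdicts, MW/dose/conversion sensitivity sweeps with threshold
inversion, and the seeded synthetic-fixture generators.

The same workflows are available from the shell:

```
nitrocalc run -f formulation.yaml -d nitrites.csv --mw 400 --process WG \
    --adi ndsri-interim-ema-178
nitrocalc compare -b original.yaml -a redesign.yaml -d nitrites.csv ...
nitrocalc sweep -f formulation.yaml -d nitrites.csv -p nitrosamine_mw \
    -g 200,400,800 ...
nitrocalc fixtures --seed 7
```

Reports are deterministic JSON/CSV and embed the nitrite-database
provenance and the nitrite MW constant used.

## Bundled data

`nitrocalc.load_packaged_db()` ships only individually documented nitrite
levels (crospovidone 6.5 ppm, croscarmellose sodium 0.42 ppm, and the
0.04–0.07 ppm lowest-filler band). A template CSV
(`nitrite_toolkit_template.csv`) lists the common excipients whose
min/mean/max values you should fill in from your supplier data or from the
published excipient nitrite survey; `import_toolkit_xlsx()` reads such a
survey sheet directly from an Excel workbook. The four model tablet
compositions (direct-compression 200 mg, wet-granulated 200 mg with either
superdisintegrant, wet-granulated 1000 mg) are available via
`case_study_formulations()`.

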