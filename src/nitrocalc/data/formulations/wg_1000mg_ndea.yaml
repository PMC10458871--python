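# 1000 mg wet-granulated tablet for the small-nitrosamine (NDEA, MW 102)
# case study; same composition as the 200 mg WG formulation.
label: wg-1000mg-ndea
tablet_weight_mg: 1000
ingredients:
  - {name: API, percent_ww: 10, role: api}
  - {name: MCC, percent_ww: 22.5, nitrite_key: microcrystalline cellulose}
  - {name: Lactose, percent_ww: 60, nitrite_key: lactose}
  - {name: Croscarmellose sodium, percent_ww: 5, nitrite_key: croscarmellose sodium}
  - {name: Povidone, percent_ww: 2, nitrite_key: povidone}
  - {name: Magnesium stearate, percent_ww: 0.5, nitrite_key: magnesium stearate}
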