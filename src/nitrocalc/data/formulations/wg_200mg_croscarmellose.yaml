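# 200 mg wet-granulated immediate-release tablet, croscarmellose sodium as
# superdisintegrant (lactose-supplier case study and the re-formulated
# "excipient selection" product).
label: wg-200mg-croscarmellose
tablet_weight_mg: 200
ingredients:
  - {name: API, percent_ww: 10, role: api}
  - {name: MCC, percent_ww: 22.5, nitrite_key: microcrystalline cellulose}
  - {name: Lactose, percent_ww: 60, nitrite_key: lactose}
  - {name: Croscarmellose sodium, percent_ww: 5, nitrite_key: croscarmellose sodium}
  - {name: Povidone, percent_ww: 2, nitrite_key: povidone}
  - {name: Magnesium stearate, percent_ww: 0.5, nitrite_key: magnesium stearate}
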