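# 200 mg direct-compression immediate-release tablet (NDSRI case study:
# MCC supplier selection). Percentages are w/w.
label: dc-200mg
tablet_weight_mg: 200
ingredients:
  - {name: API, percent_ww: 15, role: api}
  - {name: MCC, percent_ww: 50, nitrite_key: microcrystalline cellulose}
  - {name: Lactose, percent_ww: 22.5, nitrite_key: lactose}
  - {name: Croscarmellose sodium, percent_ww: 3, nitrite_key: croscarmellose sodium}
  - {name: Hypromellose, percent_ww: 5, nitrite_key: hypromellose}
  - {name: Silicon dioxide, percent_ww: 1, nitrite_key: silicon dioxide}
  - {name: Sodium stearyl fumarate, percent_ww: 3, nitrite_key: sodium stearyl fumarate}
  - {name: Magnesium stearate, percent_ww: 0.5, nitrite_key: magnesium stearate}
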