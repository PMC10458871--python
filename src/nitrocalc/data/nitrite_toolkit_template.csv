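excipient,supplier,min_ppm,mean_ppm,max_ppm,n,source
microcrystalline cellulose,,,,,,fill from your supplier data or the published excipient nitrite survey
lactose,,,,,,fill from your supplier data or the published excipient nitrite survey
povidone,,,,,,fill from your supplier data or the published excipient nitrite survey
crospovidone,,,,,,fill from your supplier data or the published excipient nitrite survey
croscarmellose sodium,,,,,,fill from your supplier data or the published excipient nitrite survey
hypromellose,,,,,,fill from your supplier data or the published excipient nitrite survey
magnesium stearate,,,,,,fill from your supplier data or the published excipient nitrite survey
silicon dioxide,,,,,,fill from your supplier data or the published excipient nitrite survey
sodium stearyl fumarate,,,,,,fill from your supplier data or the published excipient nitrite survey
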