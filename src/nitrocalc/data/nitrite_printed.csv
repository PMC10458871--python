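excipient,supplier,min_ppm,mean_ppm,max_ppm,n,source
crospovidone,,6.5,6.5,6.5,,documented supplier-average level; min/max not individually documented
croscarmellose sodium,,0.42,0.42,0.42,,documented supplier-average level; min/max not individually documented
low-nitrite filler,,0.04,0.055,0.07,,lowest filler nitrite band on the market (0.04-0.07 ppm)
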