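term,extracted,excluded
skinny,6189,5965
thin,17541,16769
fat,51988,49352
obese,7353,7059
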