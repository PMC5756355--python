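sex,deaths,incidence
male,79000,147000
female,60000,107000
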