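batch,interpolated_ug_mL
b1,156.01
b2,161.85
b3,171.61
b4a,178.50
b4b,185.21
b4c,170.72
b5,179.33
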