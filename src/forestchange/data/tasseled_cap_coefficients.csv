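index,b1,b2,b3,b4,b5,b6
TCB,0.2043,0.5524,0.4158,0.5741,0.3124,0.2303
TCG,-0.1603,-0.4934,-0.2819,0.7940,-0.0002,-0.1446
TCW,0.0315,0.3102,0.2021,0.1594,-0.6806,-0.6109
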