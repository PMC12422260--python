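species,form,a1,a2,a3,b1,b2,b3,citation
CO2,ln_k0,-58.0931,90.5069,22.2940,0.027766,-0.025888,0.0050578,"Weiss (1974) Mar. Chem. 2: 203-215, Table I (mol L-1 atm-1 fit)"
CH4,ln_bunsen,-68.8862,101.4956,28.7314,-0.076146,0.043970,-0.0068672,"Wiesenburg & Guinasso (1979) J. Chem. Eng. Data 24: 356-360, Bunsen fit"
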