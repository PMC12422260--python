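species,medium,A,B,C,D,citation
CO2,fresh,1911.1,118.11,3.4527,0.04132,"Wanninkhof (1992) J. Geophys. Res. 97: 7373-7382, Table A1 (fresh water)"
CO2,seawater35,2073.1,125.62,3.6276,0.043219,"Wanninkhof (1992) J. Geophys. Res. 97: 7373-7382, Table A1 (35 ppt seawater)"
CH4,fresh,1897.8,114.28,3.2902,0.039061,"Wanninkhof (1992) J. Geophys. Res. 97: 7373-7382, Table A1 (fresh water)"
CH4,seawater35,2039.2,120.31,3.4209,0.040437,"Wanninkhof (1992) J. Geophys. Res. 97: 7373-7382, Table A1 (35 ppt seawater)"
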