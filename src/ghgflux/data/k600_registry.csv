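code,system_class,form,a,b,c,citation
CC98,lake,power,2.07,0.215,1.7,"Cole & Caraco (1998) Limnol. Oceanogr. 43: 647-656 (SF6, low-wind lake); reconstruction"
CW03,lake,power,0.168,0.228,2.2,"Crusius & Wanninkhof (2003) Limnol. Oceanogr. 48: 1010-1017 (power-law fit); reconstruction"
RC01,estuary,exponential,1.91,0.35,,"Raymond & Cole (2001) Estuaries 24: 312-317 (estuary compilation); reconstruction"
B04,estuary,linear,1.0,2.58,,"Borges et al. (2004) Limnol. Oceanogr. 49: 1630-1641 (Scheldt, wind-only term); reconstruction"
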