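# Stepwise proton association constants (log10 K_H, descending) and metal
# association constants (log10 K) for common Ca2+ chelators.
# 25 C, 0.1 M ionic strength class (Martell & Smith compilation values).
# Empty cells mean the site does not exist.
name,log_kh1,log_kh2,log_kh3,log_kh4,log_kca,log_kmg
EGTA,9.40,8.79,2.70,2.00,10.86,5.28
EDTA,10.19,6.13,2.69,2.00,10.61,8.83
citrate,5.63,4.76,3.13,,3.48,3.43
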