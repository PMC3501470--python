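wavelength_nm,eps_hbo,eps_hbr
690,0.276,2.052
750,0.518,1.405
780,0.710,1.074
805,0.830,0.750
830,0.974,0.693
850,1.058,0.691
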