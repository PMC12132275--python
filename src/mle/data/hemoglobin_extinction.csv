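wavelength_nm,eps_hbo2,eps_hb,eps_melanin,mu_s_prime
400,26.6232,22.3296,1.9531,3.7596
410,46.6840,24.6072,1.8137,3.6408
420,48.0360,31.9134,1.6872,3.5285
430,24.6072,53.2220,1.5722,3.4222
440,10.2580,45.3440,1.4674,3.3215
450,6.2816,10.3292,1.3717,3.2258
460,4.4480,2.3388,1.2842,3.1350
470,3.3209,1.6156,1.2040,3.0485
480,2.6629,1.4550,1.1303,2.9662
490,2.3684,1.5000,1.0625,2.8878
500,2.0932,2.0862,1.0000,2.8129
510,2.0185,2.5773,0.9423,2.7414
520,2.4202,2.5000,0.8890,2.6731
530,3.9956,3.5412,0.8396,2.6077
540,5.3236,4.6592,0.7938,2.5451
550,4.3016,5.2276,0.7513,2.4851
560,3.2613,5.3412,0.7118,2.4276
570,4.4496,4.5072,0.6750,2.3724
580,5.0104,3.7020,0.6407,2.3193
590,0.7762,2.5000,0.6086,2.2683
600,0.3200,1.4677,0.5787,2.2193
610,0.1506,0.9443,0.5507,2.1721
620,0.0942,0.6510,0.5245,2.1267
630,0.0610,0.5149,0.4999,2.0829
640,0.0442,0.4346,0.4768,2.0407
650,0.0368,0.3750,0.4552,2.0000
660,0.0320,0.3227,0.4348,1.9607
670,0.0294,0.2795,0.4156,1.9227
680,0.0278,0.2407,0.3975,1.8861
690,0.0276,0.2051,0.3805,1.8506
700,0.0290,0.1794,0.3644,1.8163
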