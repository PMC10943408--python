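sex,age_band,fpl,population,pa_days_mean,pa_days_se,overweight_prev,overweight_se,obesity_prev,obesity_se
male,6-10,<100%,1968958,3.97,0.14,18.18,3.48,34.29,5.08
male,6-10,100-199%,2152037,3.90,0.13,19.97,3.34,25.17,4.02
male,6-10,200-399%,3019002,4.16,0.09,17.84,2.39,29.14,4.03
male,6-10,>=400%,3185931,4.39,0.06,18.23,2.35,16.05,2.22
male,11-13,<100%,1286059,3.26,0.18,18.76,3.23,27.71,3.22
male,11-13,100-199%,1509539,3.44,0.13,21.97,3.15,24.38,2.69
male,11-13,200-399%,1788511,3.64,0.10,19.64,2.01,18.79,1.82
male,11-13,>=400%,1837003,3.91,0.09,15.26,1.19,10.26,0.97
male,14-17,<100%,1572564,3.20,0.14,12.36,1.46,22.12,2.37
male,14-17,100-199%,1874065,3.01,0.12,19.18,2.50,25.14,2.49
male,14-17,200-399%,2532555,3.42,0.08,13.58,1.10,20.26,1.79
male,14-17,>=400%,2810412,3.70,0.06,13.38,1.55,10.77,0.83
female,6-10,<100%,1570444,3.68,0.14,21.40,6.06,28.30,5.56
female,6-10,100-199%,2084059,3.83,0.11,25.48,6.90,17.52,3.29
female,6-10,200-399%,2889740,3.95,0.08,17.05,3.03,18.41,2.98
female,6-10,>=400%,3315163,4.11,0.06,14.91,2.53,9.24,2.39
female,11-13,<100%,1071792,2.80,0.19,24.19,3.56,24.13,2.99
female,11-13,100-199%,1414506,2.70,0.13,19.95,2.91,17.33,2.55
female,11-13,200-399%,1892410,3.11,0.10,18.22,2.27,13.17,1.62
female,11-13,>=400%,1734083,3.38,0.07,13.79,1.24,6.64,0.73
female,14-17,<100%,1690081,2.64,0.15,15.03,2.44,20.59,2.49
female,14-17,100-199%,1715986,2.44,0.11,15.49,2.43,21.23,2.60
female,14-17,200-399%,2439551,2.75,0.08,14.78,1.29,12.91,1.61
female,14-17,>=400%,2524229,3.01,0.06,12.08,1.06,6.31,0.61
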