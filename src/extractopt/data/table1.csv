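ethanol_pct,time_h,temp_C,TPC,TFC,DPPH,CUPRAC,TPC_sd,TFC_sd,DPPH_sd,CUPRAC_sd
75,4,70,4.30,3.16,10.81,1.38,0.68,0.73,0.72,0.05
25,2,50,3.81,2.55,10.25,1.47,0.83,0.52,0.39,0.02
75,2,50,3.90,2.55,9.75,1.16,0.34,0.25,0.37,0.16
100,3,60,4.30,3.44,10.11,1.12,0.26,0.65,0.24,0.10
75,2,70,3.50,2.56,9.95,1.17,0.41,0.32,1.00,0.07
50,3,60,4.53,3.10,10.45,1.40,0.82,0.21,0.10,0.08
0,3,60,3.01,2.52,9.57,0.91,1.02,0.25,0.56,0.06
75,4,50,4.31,2.95,9.88,0.88,0.49,0.45,0.26,0.04
50,3,60,4.30,3.15,10.40,1.46,0.42,0.54,0.95,0.08
50,3,60,4.51,3.09,10.42,1.43,0.23,0.98,0.35,0.04
50,3,80,3.78,2.26,9.50,1.11,0.62,0.10,0.26,0.02
50,3,60,4.46,3.01,10.48,1.45,0.06,1.02,0.33,0.06
50,3,60,4.48,3.12,10.41,1.43,0.04,0.56,0.53,0.16
25,4,70,3.15,2.16,9.60,1.00,0.08,0.46,0.35,0.13
50,3,60,4.51,2.95,10.20,1.45,0.06,0.29,0.15,0.19
50,3,40,3.85,2.48,9.60,0.92,0.24,0.37,0.60,0.15
25,2,70,3.25,2.15,9.36,1.12,0.68,0.19,0.72,0.07
50,1,60,2.87,2.03,9.80,1.32,0.68,0.49,0.39,0.10
50,5,60,2.90,2.50,9.90,0.86,0.64,1.05,0.72,0.02
25,4,50,2.96,2.38,9.53,0.75,0.80,1.06,0.39,0.08
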