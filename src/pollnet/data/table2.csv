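month_from,month_to,beta_wn,beta_os,beta_st,beta_s,beta_st_l,beta_st_h,beta_st_lh
1,2,0.54,0.28,0.27,0.28,0.22,0.02,0.02
2,3,0.57,0.32,0.25,0.32,0.21,0.03,0.02
3,4,0.90,0.10,0.79,0.62,0.67,0.03,0.09
4,5,0.91,0.14,0.77,0.71,0.51,0.04,0.22
5,6,0.85,0.18,0.67,0.62,0.42,0.07,0.18
6,7,0.83,0.28,0.55,0.57,0.18,0.26,0.10
7,8,0.78,0.28,0.50,0.49,0.24,0.21,0.05
8,9,0.84,0.29,0.55,0.60,0.22,0.20,0.13
9,10,0.96,0.25,0.72,0.71,0.31,0.14,0.27
10,11,0.93,0.22,0.71,0.74,0.30,0.17,0.24
11,12,0.86,0.18,0.68,0.75,0.37,0.03,0.29
12,1,0.81,0.29,0.52,0.47,0.48,0.03,0.01
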