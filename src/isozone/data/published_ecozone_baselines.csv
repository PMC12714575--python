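ecozone,n_c3,mean_c3,median_c3,mad_c3,sd_c3,n_c4,mean_c4,median_c4,mad_c4,sd_c4,c4_policy,comment
1,140,-23.48,-23.35,1.42,1.41,8,-10.34,-10.44,0.37,0.49,general,C4 small sample size
2,511,-23.79,-23.80,1.33,1.41,10,-10.13,-10.19,0.15,0.25,general,C4 rather small sample size
3,4,-24.62,-24.69,1.25,1.07,0,,,,,general,C3 small sample size
5,294,-24.96,-25.01,1.09,1.25,20,-10.88,-10.83,0.48,0.70,measured,only Lithuania
7,338,-22.83,-22.93,1.22,1.35,0,,,,,general,
8,29,-24.18,-23.76,0.83,1.17,0,,,,,general,
12,3,-22.33,-22.10,0.37,0.62,0,,,,,general,C3 small sample size
13,86,-22.62,-22.56,0.94,0.87,0,,,,,general,
14,6,-21.32,-21.30,0.67,0.64,0,,,,,general,C3 small sample size
15,5,-20.88,-21.10,1.04,1.50,0,,,,,general,C3 small sample size
16,964,-23.15,-23.20,0.95,1.01,12,-10.32,-10.19,0.15,0.27,general,C4 rather small sample size
17,42,-24.97,-25.08,1.48,1.20,0,,,,,far_north,Norway only
18,3,-21.97,-22.10,0.15,0.32,0,,,,,general,C3 small sample size
19,1007,-23.47,-23.50,0.74,0.82,11,-10.21,-10.10,0.30,0.42,general,C4 rather small sample size
20,717,-23.03,-23.00,1.05,1.16,0,,,,,general,
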