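cluster,mean_tmp,mean_cwb,mean_dem,sd_tmp,sd_cwb,sd_dem,description
1,0.429,0.405,0.205,0.039,0.017,0.021,Mild|Moderate|Middle
2,0.362,0.343,0.06,0.019,0.01,0.013,Cool|Moderately Dry|Low
3,0.111,1,0.343,0.053,0.05,0.056,Very Cold|Extremely Humid|High
4,0.116,0.429,0.065,0.02,0.007,0.015,Cold|Humid|Low
5,0.242,0.392,0.051,0.02,0.009,0.011,Cold|Moderate|Low
6,,,,,,,unclassified|waterbody
7,0.659,0.248,0.296,0.04,0.019,0.024,Hot|Dry|High
8,0.398,0.544,0.083,0.05,0.019,0.026,Mild|Very Humid|Moderately Low
9,0.115,0.51,0.296,0.051,0.022,0.03,Cold|Humid|High
10,0.938,0.012,0.269,0.039,0.017,0.027,Very Hot|Very Dry|Middle
11,0,0.521,1,0.065,0.051,0.058,Very Cold|Very Humid|Alpine
12,0.388,0.406,0.43,0.043,0.024,0.03,Mild|Humid|Very High
13,0.633,0.184,0.479,0.053,0.026,0.03,Hot|Very Dry|Very High
14,0.329,0.318,0.718,0.051,0.025,0.043,Cool|Moderately Dry|Alpine
15,0.091,0.584,0.579,0.07,0.035,0.042,Very Cold|Very Humid|Very High
16,0.799,0.226,0.092,0.032,0.021,0.027,Hot|Dry|Moderately Low
17,0.297,0.749,0.131,0.052,0.031,0.038,Cool|Extremely Humid|Middle
18,1,0,0.078,0.031,0.018,0.023,Very Hot|Very Dry|Moderately Low
19,0.53,0.306,0.045,0.034,0.012,0.015,Warm|Dry|Very Low
20,0.473,0.395,0.046,0.032,0.011,0.015,Warm|Moderate|Very Low
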