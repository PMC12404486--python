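# Registered female breast-cancer deaths in England over 2020-2022 by 5-year
# age group, together with published model-expected deaths under pre-pandemic
# (2001-2018) trends and the published mean registered/expected ratio with its
# 95% interval. Used as the worked example for observed/expected ratios.
age_group,registered,expected,ratio,lo95,hi95
35-39,391,395.05,0.99,0.91,1.08
40-44,642,703.82,0.91,0.84,0.99
45-49,1156,1094.09,1.06,0.98,1.15
50-54,1755,1759.06,1.00,0.92,1.08
55-59,2178,2427.11,0.90,0.84,0.97
60-64,2192,2542.24,0.86,0.80,0.93
65-69,2310,2547.13,0.91,0.84,0.98
70-74,3099,3222.41,0.96,0.89,1.04
75-79,3475,3533.54,0.98,0.91,1.06
80-84,3673,3347.56,1.10,1.02,1.18
85-89,3459,3068.50,1.13,1.05,1.22
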