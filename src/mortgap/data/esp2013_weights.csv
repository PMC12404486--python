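# European Standard Population 2013: standard-population counts per 100,000
# for the 5-year age bands used in this package (35-39 .. 85-89), plus the
# combined 45-54 band (sum of 45-49 and 50-54) used for lung-cancer grids.
# Source: the published ESP 2013 revision of the European standard population.
age_group,esp_count
35-39,7000
40-44,7000
45-49,7000
50-54,7000
45-54,14000
55-59,6500
60-64,6000
65-69,5500
70-74,5000
75-79,4000
80-84,2500
85-89,1500
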