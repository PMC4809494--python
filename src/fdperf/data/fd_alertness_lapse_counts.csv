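percentile_label,a_range,no_lapses,one_or_more
0-10%,0-22.8,10,147
10-20%,22.8-42.6,21,194
20-30%,42.6-53.3,68,297
30-40%,53.3-62.8,81,325
40-50%,62.8-68.5,122,480
50-60%,68.5-73.9,166,521
60-70%,73.9-78.5,204,544
70-80%,78.5-83.4,247,569
80-90%,83.4-100,260,425
90-100%,89.4-100,196,149
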