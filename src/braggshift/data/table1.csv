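energy_mev,formula1_percent,formula2_percent
100,9.81,11.61
110,6.88,8.93
120,4.92,6.95
130,3.76,5.35
140,3.11,4.08
150,2.93,3.18
160,2.90,2.52
170,3.23,2.10
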