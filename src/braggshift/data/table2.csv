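energy_mev,field_t,simulation_mm,formula_mm
100,1.5,0.2,0.2
100,2.0,0.2,0.2
100,2.5,0.4,0.4
100,3.0,0.4,0.5
110,1.5,0.2,0.2
110,2.0,0.2,0.2
110,2.5,0.4,0.4
110,3.0,0.6,0.6
120,1.5,0.2,0.2
120,2.0,0.4,0.4
120,2.5,0.6,0.6
120,3.0,1.0,1.0
130,1.5,0.4,0.3
130,2.0,0.6,0.6
130,2.5,1.0,1.0
130,3.0,1.4,1.4
140,1.5,0.4,0.3
140,2.0,0.8,0.8
140,2.5,1.4,1.3
140,3.0,1.8,1.8
150,1.5,0.6,0.6
150,2.0,1.2,1.1
150,2.5,1.8,1.8
150,3.0,2.6,2.7
160,1.5,1.0,0.9
160,2.0,1.4,1.5
160,2.5,2.4,2.4
160,3.0,3.4,3.3
170,1.5,1.2,1.1
170,2.0,2.0,1.9
170,2.5,3.2,3.1
170,3.0,4.4,4.4
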