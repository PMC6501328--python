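run_id,ethanol_coded,time_coded,ethanol_real,time_real
1,-1.0,-1.0,40.2,34.9
2,-1.41,1.0,30.0,205.1
3,1.0,-1.0,89.8,34.9
4,1.0,1.0,89.8,205.1
5,-1.41,0.0,30.0,120.0
6,1.41,0.0,100.0,120.0
7,0.0,-1.41,65.0,0.0
8,0.0,1.41,65.0,240.0
9,0.0,0.0,65.0,120.0
10,0.0,0.0,65.0,120.0
11,0.0,0.0,65.0,120.0
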