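genotype,timepoint,experimental_mean,experimental_sd,predicted_published,error_pct_published
NT,6h,24.54,0.89,26.77,8.4
Ev.1,6h,24.55,1.42,26.19,6.3
Ev.2.2,6h,22.69,0.66,24.78,8.4
Ev.2.4,6h,23.03,0.35,23.40,1.6
Ev.3.1,6h,20.84,0.18,24.36,14.5
Ev.4,6h,20.06,0.65,23.43,14.4
NT,48h,35.66,0.93,35.41,0.7
Ev.1,48h,44.31,0.59,44.60,0.7
Ev.2.2,48h,41.33,1.23,38.04,8.7
Ev.2.4,48h,39.63,1.03,39.63,0.0
Ev.3.1,48h,29.26,0.70,35.05,16.5
Ev.4,48h,36.89,0.91,35.69,3.4
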