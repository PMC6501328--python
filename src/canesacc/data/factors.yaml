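# Factor scales for the packaged organosolv CCD dataset.
# center = coded 0; axial_low/axial_high = coded -alpha/+alpha.
factors:
  - name: ethanol
    unit: "% v/v"
    center: 65.0
    axial_low: 30.0
    axial_high: 100.0
    alpha: 1.41
  - name: time
    unit: min
    center: 120.0
    axial_low: 0.0
    axial_high: 240.0
    alpha: 1.41
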