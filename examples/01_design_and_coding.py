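"""Build a rotatable central composite design and convert coded <-> real levels.

Run: python examples/01_design_and_coding.py
"""

from canesacc import build_ccd, packaged_factor_scales, rotatability_alpha

ethanol, time = packaged_factor_scales()

print(f"rotatable axial distance for k=2: {rotatability_alpha(2):.4f} "
      "(used at the printed precision 1.41)")

design = build_ccd([ethanol, time], n_center=3)
print(f"\n{len(design.runs)}-run design (2^2 factorial + 4 axial + 3 center):")
for run_id, (c1, c2) in zip(design.run_ids, design.coded_matrix):
    print(f"  run {run_id:2d}: coded ({c1:+.2f}, {c2:+.2f}) -> "
          f"{ethanol.decode_printed(c1):5.1f} % v/v ethanol, "
          f"{time.decode_printed(c2):5.1f} min")

# Each coded unit is (axial_high - center) / alpha real units, so coded -1
# lands at 40.2% ethanol and 34.9 min — the five levels of the design.
print(f"\ncoded -1 decodes to {ethanol.decode_printed(-1.0)} % ethanol "
      f"and {time.decode_printed(-1.0)} min")
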