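"""Judge model adequacy (lack-of-fit ANOVA) and compare genotypes (Tukey HSD).

Run: python examples/03_anova_and_tukey.py
"""

from canesacc import anova_rsm, fit_quadratic, load_fixtures, tukey_hsd

fx = load_fixtures()
design = fx.design.as_standard()

fit = fit_quadratic(design, fx.responses, "NT", "48h")
anova = anova_rsm(fit, conf_level=0.90)
print("ANOVA for the NT 48-h surface (pure error from the 3 center runs):")
print(anova.to_frame().round(3).to_string())
print(f"regression significant at 90%: {anova.regression_significant}")
print(f"lack of fit significant at 90%: {anova.lack_of_fit_significant}")
# A non-significant lack of fit means the quadratic is adequate for
# prediction relative to the replicate-to-replicate noise.

sel = fx.responses.df.query("run_id == 9 and timepoint == '48h'")
res = tukey_hsd(sel["mean"], sel["sd"], sel["n"],
                groups=sel["genotype"].tolist(), alpha=0.05)
print("\nTukey HSD across genotypes, center-point run 9 at 48 h:")
print(res.to_frame().to_string())
print(f"HSD threshold at n=4: {res.hsd(4):.2f} g/L")
# Groups sharing a letter do not differ significantly (p < 0.05); at this
# run all six genotypes share 'a'.
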