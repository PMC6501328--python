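"""Relative expression by 2^-ddCt with GAPDH + EF1 reference genes.

Simulates a Ct table with known silencing levels, then recovers them.

Run: python examples/04_expression_ddct.py
"""

from canesacc import ddct, silencing_percent
from canesacc.simulate import simulate_ct_table

# three RNAi lines silenced to 5%, 15% and 30% of the nontransformed level
true_folds = {"Ev.1": 0.05, "Ev.2.2": 0.15, "Ev.2.4": 0.30}
table = simulate_ct_table(true_folds, calibrator_group="NT",
                          reference_genes=("GAPDH", "EF1"),
                          noise_sd=0.15, seed=42)

res = ddct(table, target_gene="BAHD01", calibrator_group="NT")
print("group   fold change (mean +/- SEM)   silencing")
for group, row in res.per_group.iterrows():
    print(f"{group:7s} {row['fold_mean']:.3f} +/- {row['fold_sem']:.3f}"
          f"          {silencing_percent(row['fold_mean']):5.1f}%")
# Fold change is 2^-ddCt relative to the NT calibrator; silencing percent
# is 100*(1 - fold). With 0.15-cycle noise the planted 95/85/70% levels are
# recovered closely.
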