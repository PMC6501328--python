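"""Screen an RNAi hairpin window for off-target identity stretches.

Builds a synthetic transcript family with planted shared stretches (24, 16,
15, 14, 13 and 10 bp, emulating paralog similarity), then screens the
hairpin against it.

Run: python examples/05_offtarget_screen.py
"""

from canesacc import HairpinSpec, screen_hairpin
from canesacc.simulate import simulate_offtarget_set

query, subjects, truth = simulate_offtarget_set(
    query_length=413,
    planted_lengths=(24, 16, 15, 14, 13, 10),
    snp_counts=(2, 0, 0, 0, 0, 0),  # 2 SNPs inside the 24-bp stretch
    seed=7,
)

# embed the 413-nt target window at CDS positions 825-1237
cds = "G" * 824 + query + "G" * 100
hairpin = HairpinSpec("SYN_BAHD01", cds, 825, 1237)
print(f"hairpin target window: {len(hairpin)} nt (CDS {hairpin.start}-{hairpin.end})")

hits = screen_hairpin(hairpin, subjects, k=21)
print("\nsubject      stretch  21-mers  subject coords      strand")
for h in hits:
    print(f"{h.subject_id:12s} {h.length:4d} bp {h.kmer_count:6d}   "
          f"{h.subject_start}-{h.subject_end:<12d} {h.strand}")
print("\ntruth table (post-SNP expected stretch):")
print(truth.to_string(index=False))
# Only stretches of at least the siRNA length (21 nt) can recruit silencing;
# here the SNP-broken 24-bp stretch drops below 21 nt, so no subject shares
# a full siRNA with the hairpin (21-mer counts are 0).
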