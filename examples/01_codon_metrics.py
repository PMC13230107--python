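"""Per-gene codon-usage metrics for a handful of synthetic CDSs.

Builds a synthetic host reference table, generates three genes at different
host-adaptation levels, and prints their %GC3, CAI and Nc. Higher host mixing
(alpha) should give higher CAI (closer to host-preferred codons) and lower Nc
(stronger codon bias).
"""

from phagecodon import codon, simulate
from phagecodon.io import CdsRecord

table = simulate.synthetic_host_table()
weights = codon.adaptiveness_weights(table)

print(f"{'alpha':>5} {'gc3%':>6} {'cai':>6} {'nc':>6}")
for alpha in (0.1, 0.5, 0.9):
    seq = simulate.generate_cds(
        n_codons=400, gc3_target=25.0, host_mix_alpha=alpha, table=table, seed=42
    )
    rec = CdsRecord(gene_id=f"gene_a{alpha}", genome_id="demo", sequence=seq)
    m = codon.gene_metrics(rec, weights)
    print(f"{alpha:5.1f} {m.gc3:6.1f} {m.cai:6.3f} {m.nc:6.1f}")

print()
print("functional category of 'tail-associated lysin':",
      codon.classify_functional_category("tail-associated lysin"))
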