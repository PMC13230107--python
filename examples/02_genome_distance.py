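"""Combined genomic distance over a small set of genome comparisons.

Three genomes with reciprocal hits between A and B only: the A-C and B-C
pairs carry no detectable similarity (NSS) and sit at the metric's maximum
sqrt(2) ~ 1.414. The two summary scopes differ exactly by how NSS pairs are
treated.
"""

from phagecodon.distance import pair_from_hits, summarize
from phagecodon.io import DirectionalHit

hits = [
    DirectionalHit("A", "B", pid=90.0, pcov=40.0),
    DirectionalHit("B", "A", pid=80.0, pcov=60.0),
]
pairs = pair_from_hits(hits, ["A", "B", "C"])
for p in pairs:
    label = "NSS" if p.nss else f"pid={p.pid:.1f} pcov={p.pcov:.1f}"
    print(f"{p.genome_a}-{p.genome_b}: d={p.d:.3f} ({label})")

valid = summarize(pairs, "valid_only")
allp = summarize(pairs, "all_pairs")
print(f"\nvalid-only mean d: {valid.d_stats['mean']:.3f}  (n={valid.n_valid})")
print(f"all-pairs  mean d: {allp.d_stats['mean']:.3f}  "
      f"(n={allp.n_total}, NSS fraction {allp.prop_nss:.2f})")
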