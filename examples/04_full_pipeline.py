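"""Scaled-down end-to-end run: simulate -> metrics -> distances -> statistics.

Uses 8 genomes per lifestyle and light permutation/bootstrap settings so it
finishes in seconds; the default study-scale run is simply
RunConfig(seed=..., simulate=True). Prints the lifestyle GC3/CAI medians, the
per-metric effect sizes, and the PERMANOVA separation per lifestyle pair.
"""

from phagecodon import pipeline, simulate

config = pipeline.RunConfig(
    seed=7,
    simulate=True,
    sim_config=simulate.SimConfig(seed=7, n_genomes=8),
    n_perm=199,
    bootstrap_B=100,
)
result = pipeline.run_all(config)

s = result["summaries"]
print("lifestyle medians (GC3 / CAI / Nc):")
for ls in ("virulent", "prophage", "temperate"):
    med = {m: float(s.loc[(s.metric == m) & (s.lifestyle == ls), "p50"].iloc[0])
           for m in ("gc3", "cai", "nc")}
    print(f"  {ls:9s}: {med['gc3']:5.1f} / {med['cai']:.3f} / {med['nc']:.1f}")

print("\nKruskal-Wallis effect sizes across lifestyles:")
for metric, row in result["stats"]["blocks"]["metric_kw"].items():
    print(f"  {metric:4s}: epsilon2 = {row['epsilon2']:6.3f} ({row['effect']})")

print("\nPERMANOVA per lifestyle pair:")
for pair, row in result["stats"]["blocks"]["permanova"].items():
    print(f"  {pair}: pseudo-F = {row['pseudo_f']:8.2f}, R2 = {row['r2']:.3f}, "
          f"p = {row['p']:.3f}")
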