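"""Generate a synthetic two-group experiment with known ground truth.

Default conditions: 288 panel genes x 10 samples (5 per group), 40 genes
planted with |log2FC| >= 1 shared across both platforms, NB read counts,
and one droplet well per gene and sample.
"""

from gpcrscreen import SimConfig, simulate_experiment

config = SimConfig(seed=42)
data, wells, truth = simulate_experiment(config)

print("count matrix :", data.counts.shape, "genes x samples")
print("droplet wells:", len(wells))
planted = truth.genes[truth.genes.is_de]
print("planted DE   :", len(planted),
      f"({(planted.log2fc > 0).sum()} up, {(planted.log2fc < 0).sum()} down)")
print("\nfirst planted genes:")
print(planted[["baseline_mean", "log2fc"]].head().round(3))
# 'truth' records every baseline, fold change, size factor and true
# concentration, so downstream estimates can be scored against it.
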