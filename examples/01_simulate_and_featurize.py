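"""Simulate a labelled protein family and compute its attribute census.

Builds a small synthetic dataset of Na,K-ATPase-like alpha subunits (five
organism groups, vertebrates split into four isoforms, planted dipeptide
signals) and featurizes every sequence into the 1,242-attribute census.
"""

from nkaminer import GROUPS, SimConfig, featurize_all, simulate_dataset

cfg = SimConfig(seed=42, n_per_group={g: 8 for g in GROUPS})
records, reference, truth = simulate_dataset(cfg)
table = featurize_all(records)

print(f"{len(records)} sequences, attribute table {table.data.shape}")
print(f"reference length {len(reference.sequence)} "
      f"(coordinate system for site mapping)\n")

show = ["length", "molecular_weight", "isoelectric_point", "count_GC", "count_DH"]
summary = table.data[show].groupby(table.labels["group"]).mean().round(2)
print("group means of a few attributes:")
print(summary.to_string())
print(
    "\ncount_GC is the planted Gly-Cys dipeptide count: 3 in vertebrates\n"
    "(sites 142/208/702), 2 in invertebrates (142/702), 0 elsewhere —\n"
    "the signal the organism-group classifier should rediscover.\n"
    "Prokaryotes are ~120 residues shorter, visible in length and weight."
)
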