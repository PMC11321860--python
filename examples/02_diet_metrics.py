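"""Compute diet metrics: overall RRA, FOO/%FOO, and GZP importance bands.

RRA answers "what fraction of the prey reads belong to this taxon"; FOO
answers "in how many stomachs was it detected at all"; the importance index
(GZP-fraction RRA x FOO) combines both for the gelatinous prey only.
"""

from jellydiet import (
    curate, default_config, diet_table, gzp_importance_table, simulate_dataset,
)

dataset = simulate_dataset(default_config(seed=1))
curated, _ = curate(dataset.tables["COI"], dataset.taxonomies["COI"],
                    dataset.metadata)

dt = diet_table(curated, dataset.taxonomies["COI"], dataset.metadata)
silus = dt.for_species("Argentina silus").sort_values("overall_rra_pct",
                                                      ascending=False)
print("Argentina silus, COI, top prey taxa:")
print(silus[["overall_rra_pct", "foo", "pct_foo"]].head(5).round(1))

records = gzp_importance_table(curated, dataset.taxonomies["COI"],
                               dataset.metadata)
print("\ngelatinous prey importance for A. silus:")
for r in records:
    if r.predator_species == "Argentina silus":
        print(f"  {r.taxon:20s} gzp-RRA {r.gzp_rra_pct:5.1f}% x FOO {r.foo:2d} "
              f"= {r.importance:7.1f} -> {r.category}")

# A taxon can be of high importance with a modest share of reads if it turns
# up in many stomachs, and vice versa; the bands are low <=100, medium
# 100-500, high >=500.
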