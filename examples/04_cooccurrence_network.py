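"""RMT-thresholded co-occurrence network with null-model comparison.

Plants 15 pairwise associations among 60 ASVs (latent correlation 0.85),
lets random-matrix theory pick the correlation cutoff, and compares the
resulting topology against 100 Maslov-Sneppen degree-preserving
rewirings.
"""

from spongenet import (
    build_network,
    filter_prevalence,
    generate_correlated_counts,
    keystone_species,
    null_ensemble,
    random_ground_truth,
    rmt_threshold,
    spearman_matrix,
    topology,
)

gt = random_ground_truth(60, 15, rho=0.85, seed=0)
table = generate_correlated_counts(gt, n_samples=50, depth=20_000, seed=1)

corr, dropped = spearman_matrix(filter_prevalence(table, 0.5))
s_t, diagnostics = rmt_threshold(corr)
net = build_network(corr, s_t)
topo = topology(net)

print(f"RMT-selected cutoff:  |r| >= {s_t:.2f}")
print(f"topology: N={topo.n_nodes} L={topo.n_links} "
      f"avgK={topo.avg_connectivity:.2f} M={topo.modularity:.2f} "
      f"Con={topo.connectedness:.2f}")

found = set(map(frozenset, net.graph.edges()))
tp = len(found & gt.edge_set())
print(f"planted-edge recall: {tp}/{len(gt.edges)}  "
      f"(plus {len(found) - tp} extra edges below the noise floor)")

nulls = null_ensemble(net, n=100, seed=2)
print(nulls.table.round(3))
print(f"top keystones by degree+betweenness rank: "
      f"{list(keystone_species(topo, k=3).index)}")
print()
print(
    "The eigenvalue-spacing transition picks the cutoff where the "
    "correlation matrix decorrelates; all planted pairs survive it.  "
    "A large positive modularity Z-score says the empirical network is "
    "far more modular than degree-matched random graphs."
)
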