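"""Build a similarity cluster map from two planted peptide families.

All-vs-all Smith-Waterman alignments become an undirected graph (edges:
alignment P <= 1e-06), a 2,000-round force-directed layout embeds it in
2-D, and seed-and-grow convex clustering calls the families.  The output
is a CLANS-style text file plus the cluster membership.
"""

import random

from prospect import (
    all_vs_all,
    build_graph,
    convex_clusters,
    generate_precursor,
    run_layout,
    write_cluster_file,
)
from prospect.simulate import random_spec

rng = random.Random(3)
records = []
for fam in range(2):
    spec = random_spec(rng)
    for m in range(4):
        rec, _ = generate_precursor(
            spec, rng, record_id=f"fam{fam}_m{m}|Gastropoda"
        )
        records.append(rec)

hits = all_vs_all([(r.id, r.sequence) for r in records], max_p=1e-06)
graph = build_graph(hits, p_cut=1e-06, taxa={r.id: r.taxon for r in records},
                    include_ids=[r.id for r in records])
run_layout(graph, rounds=2000, seed=3)
labels = convex_clusters(graph)
write_cluster_file(graph, "scratch_cluster_map.clans",
                   {r.id: r.sequence for r in records})

print(f"{graph.n_nodes} nodes, {len(graph.edges)} edges")
for i, (rid, _) in enumerate(graph.nodes):
    print(f"  {rid:<22} -> {labels[i]}")
print("\nMembers of the same planted family share one cluster label; the")
print("CLANS-style map was written to scratch_cluster_map.clans.")
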