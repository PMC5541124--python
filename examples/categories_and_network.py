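"""Molecular-function breakdown and interaction-network components.

Runs the offline summaries on a subset of group-1 proteins using the
packaged synthetic demo annotation and edge list (hand-made illustrations,
not database exports).
"""

from isoreg import network_components, read_annotation, read_edges, summarize_categories
from isoreg.psm_io import demo_path

proteins = [
    "Q9Z1P2", "Q9QXQ0", "P85972", "P60711", "P04692",    # structural cluster
    "P63102", "P61983", "P62260",                         # 14-3-3 adaptors
    "B5DFC8", "B0BNA7", "Q9DBZ5", "Q9EPH8",               # translation
    "P05982", "P70619",                                   # reductases
    "P19132",
]

annotation = read_annotation(demo_path("annotation"))
breakdown = summarize_categories(proteins, annotation)
print(f"{breakdown.recognized_proteins}/{breakdown.total_proteins} proteins annotated, "
      f"{breakdown.total_hits} category hits:")
for category, hits in breakdown.hits.items():
    print(f"  {category:28s} {hits:2d} hits  ({breakdown.percentages[category]:.1f}%)")

edges = read_edges(demo_path("edges"))
net = network_components(proteins, edges, score_cutoff=0.4)
print()
print(f"network: {net.n_nodes} nodes, {net.n_edges} edges (score >= 0.4)")
for component in net.components:
    if len(component) > 1:
        print(f"  component of {len(component)}: {', '.join(component)}")
singletons = [c[0] for c in net.components if len(c) == 1]
print(f"  singletons: {', '.join(singletons) if singletons else 'none'}")
print()
print("A multi-category protein contributes one hit per category; percentages")
print("are hits over total hits. Components group proteins that regulate each")
print("other directly or indirectly at the chosen confidence cutoff.")
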