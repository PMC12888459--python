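"""Prioritize consensus compounds by centrality in the tripartite network.

Builds the herb–compound–indicator graph from the packaged consensus sets,
computes degree / betweenness / closeness per compound, and flags compounds
whose centralities exceed the compound-wise medians (2-of-3 strict rule).
"""

from specscreen import (build_network, load_fixture, median_filter,
                        union_dedup)

sets = load_fixture("table8")
herb_map = load_fixture("herb_map")

union = union_dedup(sets)
print(f"{len(union)} consensus compounds across {len(sets)} indicators")

net = build_network(sets, herb_map)
print("\nper-compound centralities:")
print(net.centralities.round(4).to_string())

flagged = median_filter(net.centralities, k_of_3=2)
print(f"\nflagged ({len(flagged)} compounds above the centrality medians):")
print(" ", ", ".join(flagged))

# Flagged compounds sit centrally in the herb–constituent–indicator web:
# they serve several indicators at once and are the strongest candidates
# for quality-control markers.
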