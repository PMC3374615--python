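"""Edit-distance network over the bundled direct-repeat consensuses.

Repeat orientation is unknowable without cas context, so each pairwise
distance is the smaller of the forward and reverse-complement edit
distances; an edge joins repeats within 10 edits.
"""

from crisprforge import build_network, reference_repeats

repeats = reference_repeats()
print(f"{len(repeats)} repeat consensuses, e.g. "
      f"{repeats[0].id} = {repeats[0].seq}")

g = build_network(repeats, max_dist=10)
print(f"\nnetwork: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges")
for a, b, d in sorted(g.edges(data="distance"), key=lambda e: e[2]):
    print(f"  {a} -- {b}  distance {d}")
# Connected repeats belong to related CRISPR families (note the cluster of
# 29-bp repeats and the pair of Lactobacillus 36-bp repeats); isolated nodes
# are unrelated repeat types.
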