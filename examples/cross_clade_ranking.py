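"""Rank markers within two clades and compare the rankings.

Uses the packaged published screening counts for the Potato and Morelloid
clades of Solanum: markers are ranked by the absolute number of variable
characters including coded indels, and the two rankings are compared to see
which markers stay near the top in both clades.
"""

from plastscreen import (
    cross_clade_compare,
    load_published_counts,
    rank_markers,
    render_table,
)

potato = rank_markers(load_published_counts("Potato", nuclear=False), clade="Potato")
morelloid = rank_markers(
    load_published_counts("Morelloid", nuclear=False), clade="Morelloid"
)

print("top six per clade:")
print(f"  Potato:    {', '.join(potato.top(6))}")
print(f"  Morelloid: {', '.join(morelloid.top(6))}")

comparison = cross_clade_compare(potato, morelloid)
print(f"\nshared markers: {len(comparison.common)}")
print(f"in both top-3 sets: {sorted(comparison.top3_overlap) or 'none'}")
print(f"in both top-6 sets: {sorted(comparison.consistently_top)}")
print(f"\nlargest rank shifts (Potato rank - Morelloid rank):")
for marker, delta in sorted(
    comparison.delta_rank.items(), key=lambda kv: -abs(kv[1])
)[:3]:
    print(f"  {marker:12s} {delta:+d}")

nuclear = load_published_counts("Morelloid", nuclear=True) + load_published_counts(
    "Potato", nuclear=True
)
table = render_table(morelloid, potato, nuclear=nuclear)
print("\nfirst lines of the rendered comparison table:")
print("\n".join(table.splitlines()[:4]))
# Large rank shifts mean a marker that screens well in one clade can be
# mediocre in a close relative, so per-clade screening remains necessary.
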