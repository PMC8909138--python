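"""Overlap structure of the seven populations: private cells and Combo_CSC.

Uses the deterministic fixture that realizes the published pairwise
intersections, and decomposes it with exact set arithmetic.
"""

import cscmosaic as cm

fixture = cm.printed_overlap_fixture()
ov = cm.compute_overlap(fixture)

print("private cells per group (members of no other group):")
for name in ov.group_names:
    print(f"  {name:8s} {ov.privates[name]:2d} of {ov.sizes[name]}")

print("\nnon-zero pairwise intersections:")
for (a, b), k in sorted(ov.pairwise.items()):
    if k:
        frac = 100 * ov.pair_fraction(a, b)
        jac = 100 * ov.pair_jaccard(a, b)
        print(f"  {a}/{b}: {k} cells ({frac:.1f}% of smaller group, Jaccard {jac:.1f}%)")

markers = [g for g in fixture if g.selector["kind"] == "marker"]
combo = cm.combo_csc(markers)
print(f"\nCombo_CSC (high for >= 2 markers): {len(combo)} cells")
for cell, pairs in combo.selector["pairs"].items():
    print(f"  {cell}: {', '.join('/'.join(p) for p in pairs)}")

# SCC is fully private (22/22): slow-cycling character and marker-high
# status are largely non-overlapping cell states. Nine cells sit in two
# marker groups at once - the Combo_CSC population.
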