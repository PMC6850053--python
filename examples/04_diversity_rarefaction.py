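"""Sample-based rarefaction of richness and Hill diversity by habitat.

Composite-area replicates are pooled in random order (1000 randomizations
in the full protocol; fewer here for speed): estimated richness Sest
without replacement, exp(H') and 1/D with replacement. Comparing habitats
at an equal number of *individuals* rather than equal area changes the
story — the mosaic (intermediate) habitat stands out as most diverse.
"""

from biotope import (
    build_abundance_matrix,
    classify_tiles,
    diversity_at_effort,
    generate_survey,
    haigfras_like,
    make_composite_area,
    rarefy_groups,
)

tiles, obs, _ = generate_survey(haigfras_like(n_transects=5, tiles_per_transect=300,
                                              rng_seed=42))
tiles = classify_tiles(tiles)
units = make_composite_area(tiles, seed=0, observations=obs)
counts, _ = build_abundance_matrix(tiles, obs, units.grouping())

stratum = units.membership().drop_duplicates("sample_id").set_index("sample_id")["stratum"]
habitat = stratum.str[0].map({"H": "hard", "C": "coarse", "S": "sand"})
habitat[stratum.str.endswith("h")] = "intermediate"
habitat = habitat.reindex(counts.index)

curves = rarefy_groups(counts, habitat, n_rand=200, seed=0)

print("rarefied diversity at the end of each habitat's curve:")
end = curves.sort_values("t").groupby(["group", "index"]).tail(1)
print(end.pivot(index="group", columns="index", values="mean").round(1).to_string())

common = curves.groupby(["group", "index"])["mean_individuals"].max().min()
# clamp: a dense habitat whose single smallest composite already exceeds
# the target is evaluated at its minimum (approximately equal effort)
at = diversity_at_effort(curves, float(common), clamp=True)
print(f"\nsame indices compared at an approximately equal effort of ~{common:.0f} individuals:")
print(at.pivot(index="group", columns="index", values="mean").round(1).to_string())
print(
    "\nSest >= expH' >= 1/D everywhere (Hill ordering). At equal individuals"
    "\nthe intermediate habitat is the most diverse on every index: mixing the"
    "\nhard and sedimentary assemblages dilutes dominance."
)
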