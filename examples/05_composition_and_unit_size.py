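"""Composition analysis and autosimilarity-based sampling-unit sizing.

Bray-Curtis dissimilarity of log-transformed composite densities feeds a
2-D NMDS ordination and the ANOSIM permutation test; autosimilarity curves
then ask how large a composite must be before two independent replicates
from the same habitat agree to 0.75 similarity - the answer differs by an
order of magnitude in seabed area but only ~2-fold in individuals.
"""

import pandas as pd

from biotope import (
    anosim,
    autosimilarity,
    bray_curtis,
    build_abundance_matrix,
    classify_tiles,
    generate_survey,
    haigfras_like,
    make_composite_area,
    nmds,
    required_unit_size,
)

tiles, obs, _ = generate_survey(haigfras_like(n_transects=5, tiles_per_transect=300,
                                              rng_seed=42))
tiles = classify_tiles(tiles)
units = make_composite_area(tiles, seed=0, observations=obs)
counts, density = build_abundance_matrix(tiles, obs, units.grouping())
stratum = (
    units.membership().drop_duplicates("sample_id").set_index("sample_id")["stratum"]
).reindex(counts.index)

D = bray_curtis(density, transform="log1p")
ordination = nmds(D, seed=0)
print(f"2-D NMDS stress-1 = {ordination.stress:.3f} "
      f"(best of {len(ordination.restart_stresses)} restarts)")

# test across substratum classes that hold at least two composites
sizes = stratum.value_counts()
testable = stratum[stratum.map(sizes) >= 2]
res = anosim(D.loc[testable.index, testable.index], testable, n_perm=999, seed=0)
print(f"ANOSIM by substratum class: R = {res.R:.2f}, p = {res.p:.3f}")
print("R near 1 = assemblages almost completely separated by substratum\n")

tile_counts, _ = build_abundance_matrix(
    tiles, obs, pd.Series(tiles["tile_id"].values, index=tiles["tile_id"].values)
)
tile_areas = tiles.set_index("tile_id")["area_m2"]
habitat = tiles.set_index("tile_id")["habitat"]

rows = []
for hab in ("hard", "intermediate", "coarse", "sand"):
    ids = habitat[habitat == hab].index
    curve = autosimilarity(
        tile_counts.loc[ids], tile_areas,
        sizes=[1, 2, 4, 8, 16, 32, 64, 128, 180], n_rand=200, seed=1, stratum=hab,
    )
    try:
        req = required_unit_size(curve, target_similarity=0.75)
        rows.append({"habitat": hab, **{k: round(v, 2) for k, v in req.items()}})
    except ValueError as err:
        rows.append({"habitat": hab, "note": str(err)})

print("effort needed for 0.75 within-habitat self-similarity:")
print(pd.DataFrame(rows).to_string(index=False))
print(
    "\nAreas span an order of magnitude between habitats while individual"
    "\ncounts stay in a narrow band: sizing units by number of individuals"
    "\nstandardises the assemblage description across habitats."
)
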