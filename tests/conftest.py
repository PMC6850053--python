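import numpy as np
import pandas as pd
import pytest

from biotope import classify_tiles, generate_survey, haigfras_like


@pytest.fixture(scope="session")
def small_survey():
    """A compact mosaic-seabed survey with ground truth (750 tiles)."""
    cfg = haigfras_like(n_transects=3, tiles_per_transect=250, rng_seed=11)
    tiles, obs, truth = generate_survey(cfg)
    return cfg, tiles, obs, truth


@pytest.fixture(scope="session")
def classified_small_survey(small_survey):
    cfg, tiles, obs, truth = small_survey
    return cfg, classify_tiles(tiles), obs, truth


def make_strata_tiles(counts: dict[str, int], area: float = 7.29) -> pd.DataFrame:
    """Bare tile table with a stratum column, for composite-unit tests."""
    rows = []
    for stratum, n in counts.items():
        for i in range(n):
            rows.append(
                {
                    "tile_id": f"{stratum}-{i:04d}",
                    "transect_id": "tr1",
                    "order_index": i,
                    "area_m2": area,
                    "substratum_code": stratum,
                }
            )
    return pd.DataFrame(rows)


def observations_for_counts(tiles: pd.DataFrame, per_tile_counts) -> pd.DataFrame:
    """One-morphotype observation table with given per-tile individual counts."""
    per_tile_counts = np.asarray(per_tile_counts, dtype=int)
    return pd.DataFrame(
        {
            "tile_id": np.repeat(tiles["tile_id"].to_numpy(), per_tile_counts),
            "morphotype_id": "sp1",
            "length_cm": 2.0,
        }
    )
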