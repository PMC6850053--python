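import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from biotope import (
    INDETERMINATE_ID,
    LengthWeightTable,
    UnclassifiableTileError,
    add_biomass,
    biomass_of,
    build_abundance_matrix,
    classify_substratum,
    classify_tiles,
    habitat_of,
    read_coefficients,
    read_observations,
    read_tiles,
)


@pytest.mark.parametrize(
    "covers, code",
    [
        ((0.55, 0.35, 0.10), "Hc"),  # coarse is the larger qualifying secondary
        ((1.0, 0.0, 0.0), "H"),
        ((0.05, 0.60, 0.35), "Cs"),  # rule-producible sediment mosaic
        ((0.6, 0.1, 0.3), "Hs"),
        ((0.35, 0.55, 0.10), "Ch"),
        ((0.0, 0.05, 0.95), "S"),
        ((0.05, 0.80, 0.15), "Cs"),
        ((0.02, 0.95, 0.03), "C"),
    ],
)
def test_substratum_code_from_covers(covers, code):
    assert classify_substratum(*covers) == code


def test_half_half_tie_uses_hard_coarse_sand_precedence():
    assert classify_substratum(0.5, 0.5, 0.0) == "Hc"
    assert classify_substratum(0.5, 0.0, 0.5) == "Hs"
    assert classify_substratum(0.0, 0.5, 0.5) == "Cs"


def test_sediment_mosaic_codes_can_be_collapsed():
    assert classify_substratum(0.05, 0.60, 0.35, allow_sediment_mosaics=False) == "C"
    assert classify_substratum(0.05, 0.35, 0.60, allow_sediment_mosaics=False) == "S"


def test_no_majority_component_is_unclassifiable():
    with pytest.raises(UnclassifiableTileError):
        classify_substratum(0.4, 0.35, 0.25)


def test_covers_must_sum_to_one():
    with pytest.raises(ValueError, match="sum"):
        classify_substratum(0.5, 0.3, 0.1)


@pytest.mark.parametrize(
    "code, covers, habitat, flagged",
    [
        ("Hs", (0.6, 0.1, 0.3), "hard", False),
        ("Ch", (0.35, 0.55, 0.10), "intermediate", False),
        ("S", (0.0, 0.05, 0.95), "sand", False),
        ("C", (0.02, 0.95, 0.03), "coarse", False),
        # sub-threshold mosaic: 80% coarse, no habitat rule matches exactly
        ("Cs", (0.05, 0.80, 0.15), "coarse", True),
        ("Sc", (0.05, 0.15, 0.80), "sand", True),
    ],
)
def test_summary_habitat_rules(code, covers, habitat, flagged):
    assert habitat_of(code, *covers) == (habitat, flagged)


def test_seven_survey_archetypes_map_to_their_habitats():
    """The seven observed substratum classes reduce to the published
    habitat column: H/Hc/Hs -> hard, Ch/Sh -> intermediate, C -> coarse,
    S -> sand."""
    archetypes = {
        "H": (0.95, 0.03, 0.02),
        "Hc": (0.60, 0.30, 0.10),
        "Hs": (0.60, 0.10, 0.30),
        "Ch": (0.30, 0.60, 0.10),
        "Sh": (0.30, 0.10, 0.60),
        "C": (0.02, 0.95, 0.03),
        "S": (0.02, 0.03, 0.95),
    }
    expected = {
        "H": "hard",
        "Hc": "hard",
        "Hs": "hard",
        "Ch": "intermediate",
        "Sh": "intermediate",
        "C": "coarse",
        "S": "sand",
    }
    for code, covers in archetypes.items():
        assert classify_substratum(*covers) == code
        assert habitat_of(code, *covers)[0] == expected[code]


@pytest.mark.parametrize(
    "a, b, length, expected",
    [(1.0, 3.0, 2.0, 8.0), (0.05, 2.5, 1.0, 0.05), (0.01, 3.2, 10.0, 15.848932)],
)
def test_allometric_biomass(a, b, length, expected):
    assert biomass_of(length, a, b) == pytest.approx(expected, rel=1e-6)


@settings(max_examples=50, deadline=None)
@given(
    a=st_.floats(0.001, 10),
    b=st_.floats(0, 4),
    length=st_.floats(1, 500),
)
def test_biomass_scaling_properties(a, b, length):
    # doubling a doubles biomass; b = 0 returns a regardless of length
    assert biomass_of(length, 2 * a, b) == pytest.approx(2 * biomass_of(length, a, b))
    assert biomass_of(length, a, 0.0) == pytest.approx(a)


def test_biomass_rejects_nonpositive_length():
    with pytest.raises(ValueError):
        biomass_of(0.0, 1.0, 3.0)


def test_length_weight_table_falls_back_to_default():
    table = LengthWeightTable(coefficients={"sp1": (1.0, 3.0)}, default=(0.05, 2.8))
    assert table.resolve("sp1") == (1.0, 3.0)
    assert table.resolve("unknown") == (0.05, 2.8)
    obs = pd.DataFrame(
        {"tile_id": ["t1", "t1"], "morphotype_id": ["sp1", "unknown"], "length_cm": [2.0, 2.0]}
    )
    out = add_biomass(obs, table)
    assert out["biomass_gwwt"].iloc[0] == pytest.approx(8.0)
    assert out["biomass_gwwt"].iloc[1] == pytest.approx(0.05 * 2**2.8)


def _toy_tiles():
    return pd.DataFrame(
        {
            "tile_id": ["t1", "t2"],
            "transect_id": ["tr1", "tr1"],
            "order_index": [0, 1],
            "area_m2": [7.0, 7.0],
            "cover_hard": [1.0, 1.0],
            "cover_coarse": [0.0, 0.0],
            "cover_sand": [0.0, 0.0],
        }
    )


def test_abundance_matrix_counts_and_density():
    tiles = _toy_tiles()
    obs = pd.DataFrame(
        {
            "tile_id": ["t1", "t1", "t2", "t2"],
            "morphotype_id": ["sp1", "sp1", "sp1", "sp2"],
            "length_cm": [2.0] * 4,
        }
    )
    counts, density = build_abundance_matrix(tiles, obs, {"t1": "A", "t2": "A"})
    assert counts.loc["A", "sp1"] == 3
    assert counts.loc["A", "sp2"] == 1
    assert density.loc["A", "sp1"] == pytest.approx(3 / 14.0)
    # marginal total conserves the observation count
    assert counts.to_numpy().sum() == len(obs)


def test_abundance_matrix_empty_observations_declared_columns():
    tiles = _toy_tiles()
    obs = pd.DataFrame({"tile_id": [], "morphotype_id": [], "length_cm": []})
    counts, _ = build_abundance_matrix(
        tiles, obs, {"t1": "A", "t2": "B"}, morphotypes=["sp1", "sp2"]
    )
    assert counts.shape == (2, 2)
    assert (counts.to_numpy() == 0).all()


def test_abundance_matrix_excludes_indeterminate_and_rejects_orphans():
    tiles = _toy_tiles()
    obs = pd.DataFrame(
        {
            "tile_id": ["t1", "t1"],
            "morphotype_id": ["sp1", INDETERMINATE_ID],
            "length_cm": [2.0, 2.0],
        }
    )
    counts, _ = build_abundance_matrix(tiles, obs, {"t1": "A", "t2": "A"})
    assert counts.to_numpy().sum() == 1
    assert INDETERMINATE_ID not in counts.columns

    orphan = pd.DataFrame(
        {"tile_id": ["missing"], "morphotype_id": ["sp1"], "length_cm": [2.0]}
    )
    with pytest.raises(ValueError, match="missing"):
        build_abundance_matrix(tiles, orphan, {"t1": "A"})


def test_classify_tiles_flags_unclassifiable_rows():
    tiles = _toy_tiles()
    tiles.loc[1, ["cover_hard", "cover_coarse", "cover_sand"]] = [0.4, 0.35, 0.25]
    out = classify_tiles(tiles)
    assert out["substratum_code"].iloc[0] == "H"
    assert out["unclassifiable"].tolist() == [False, True]


def test_delimited_io_round_trip(tmp_path):
    tiles = _toy_tiles()
    obs = pd.DataFrame(
        {"tile_id": ["t1"], "morphotype_id": ["sp1"], "length_cm": [2.0]}
    )
    coeffs = pd.DataFrame(
        {"morphotype_id": ["sp1", "*"], "a": [1.0, 0.02], "b": [3.0, 2.5]}
    )
    tiles.to_csv(tmp_path / "tiles.csv", index=False)
    obs.to_csv(tmp_path / "obs.tsv", sep="\t", index=False)
    coeffs.to_csv(tmp_path / "coeffs.csv", index=False)

    tiles2 = read_tiles(tmp_path / "tiles.csv")
    obs2 = read_observations(tmp_path / "obs.tsv")
    table = read_coefficients(tmp_path / "coeffs.csv")
    assert tiles2["tile_id"].tolist() == ["t1", "t2"]
    assert obs2["morphotype_id"].tolist() == ["sp1"]
    assert table.resolve("sp1") == (1.0, 3.0)
    assert table.resolve("other") == (0.02, 2.5)


def test_read_tiles_rejects_duplicate_order(tmp_path):
    tiles = _toy_tiles()
    tiles["order_index"] = [0, 0]
    tiles.to_csv(tmp_path / "tiles.csv", index=False)
    with pytest.raises(ValueError, match="order_index"):
        read_tiles(tmp_path / "tiles.csv")
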