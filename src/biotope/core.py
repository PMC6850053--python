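"""Domain model for photo-transect biotope assessment.

The primary sampling element is a *tile*: a mosaic of consecutive seabed
photographs covering a known area (default ~7.3 m²), annotated with the
fractional seabed cover of three substratum components — hard (bedrock,
boulder, cobbles), coarse sediment (gravelly sand, granules, pebbles,
shells) and sand — plus the individuals (invertebrates and demersal fish,
>=1 cm body length) observed on it.

Substratum codes combine a primary component (majority cover, >=50%) with an
optional secondary component (>=10% cover): H, Hc, Hs, Ch, Sh, C, S, and the
rule-producible but rarely observed sediment mosaics Cs, Sc. Codes simplify
to four summary habitats:

* ``hard``          — primary hard substratum (>=50% hard cover)
* ``intermediate``  — hard substratum secondary (>=10% but <50% hard cover)
* ``coarse``        — >90% cover by coarse sediment
* ``sand``          — >90% cover by sand

Sedimentary tiles whose primary component covers (0.5, 0.9] with no
qualifying hard fraction match no summary-habitat rule exactly; they are
assigned to the primary component's habitat and flagged as sub-threshold
mosaics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "COMPONENTS",
    "HABITATS",
    "INDETERMINATE_ID",
    "TileRecord",
    "Observation",
    "LengthWeightTable",
    "UnclassifiableTileError",
    "classify_substratum",
    "habitat_of",
    "classify_tiles",
    "biomass_of",
    "add_biomass",
    "build_abundance_matrix",
    "read_tiles",
    "read_observations",
    "read_coefficients",
]

#: Substratum components in tie-break precedence order (hard > coarse > sand).
COMPONENTS = ("hard", "coarse", "sand")
_PRIMARY = {"hard": "H", "coarse": "C", "sand": "S"}
_SECONDARY = {"hard": "h", "coarse": "c", "sand": "s"}

HABITATS = ("hard", "intermediate", "coarse", "sand")

#: Reserved morphotype id for indeterminate specimens; carried in input
#: tables and excluded (audibly) when abundance matrices are built.
INDETERMINATE_ID = "indet"

_COVER_SUM_TOL = (0.999, 1.001)


class UnclassifiableTileError(ValueError):
    """No substratum component reaches 50% cover."""


@dataclass(frozen=True)
class TileRecord:
    """One annotated image tile on a transect."""

    tile_id: str
    transect_id: str
    order_index: int
    area_m2: float
    cover_hard: float
    cover_coarse: float
    cover_sand: float

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise ValueError(f"tile {self.tile_id}: area_m2 must be positive")
        total = self.cover_hard + self.cover_coarse + self.cover_sand
        if not (_COVER_SUM_TOL[0] <= total <= _COVER_SUM_TOL[1]):
            raise ValueError(
                f"tile {self.tile_id}: cover fractions sum to {total:.4f}, not 1"
            )


@dataclass(frozen=True)
class Observation:
    """One counted individual (or colony), with optional derived biomass."""

    tile_id: str
    morphotype_id: str
    length_cm: float
    biomass_gwwt: float | None = None

    def __post_init__(self) -> None:
        if self.length_cm < 1:
            raise ValueError("length_cm must be >= 1 (minimum detectable body size)")


def classify_substratum(
    cover_hard: float,
    cover_coarse: float,
    cover_sand: float,
    *,
    allow_sediment_mosaics: bool = True,
) -> str:
    """Substratum code from fractional covers.

    The primary component is the one with majority cover (>=50%; exact ties
    broken by the fixed precedence hard > coarse > sand). The largest
    remaining component with >=10% cover is recorded as a lowercase
    secondary suffix.

    Parameters
    ----------
    allow_sediment_mosaics:
        If False, the sediment-mosaic codes Cs and Sc (never observed in the
        survey this scheme was built for) are collapsed to C and S.

    Raises
    ------
    ValueError
        If the covers do not sum to 1 within tolerance.
    UnclassifiableTileError
        If no component reaches 50% cover.
    """
    covers = {"hard": cover_hard, "coarse": cover_coarse, "sand": cover_sand}
    total = sum(covers.values())
    if not (_COVER_SUM_TOL[0] <= total <= _COVER_SUM_TOL[1]):
        raise ValueError(f"cover fractions sum to {total:.4f}, not 1")
    if any(v < 0 for v in covers.values()):
        raise ValueError("cover fractions must be non-negative")

    # max with precedence tie-break: COMPONENTS is already in precedence order
    primary = max(COMPONENTS, key=lambda c: covers[c])
    if covers[primary] < 0.5:
        raise UnclassifiableTileError(
            f"no substratum component reaches 50% cover: {covers}"
        )
    rest = [c for c in COMPONENTS if c != primary and covers[c] >= 0.1]
    code = _PRIMARY[primary]
    if rest:
        secondary = max(rest, key=lambda c: covers[c])
        code += _SECONDARY[secondary]
    if not allow_sediment_mosaics and code in ("Cs", "Sc"):
        code = code[0]
    return code


def habitat_of(
    code: str,
    cover_hard: float,
    cover_coarse: float,
    cover_sand: float,
) -> tuple[str, bool]:
    """Summary habitat for a coded tile.

    Returns ``(habitat, sub_threshold_mosaic)``. The flag is True for
    sedimentary tiles whose primary cover is in (0.5, 0.9] with no
    qualifying hard fraction — they match no summary-habitat rule exactly
    and are labelled by their primary component.

    ``intermediate`` is decided on the hard-cover fraction itself (>=10%),
    not on the code suffix: when two components qualify as secondary only
    the larger is suffixed, yet any >=10% hard cover makes the tile a
    hard/sediment mosaic.
    """
    if code.startswith("H"):
        return "hard", False
    if cover_hard >= 0.1:
        return "intermediate", False
    if cover_coarse > 0.9:
        return "coarse", False
    if cover_sand > 0.9:
        return "sand", False
    primary = "coarse" if code.startswith("C") else "sand"
    return primary, True


def classify_tiles(
    tiles: pd.DataFrame, *, allow_sediment_mosaics: bool = True
) -> pd.DataFrame:
    """Classify a tile table; adds substratum_code, habitat, mosaic flags.

    Tiles where no component reaches 50% cover are kept with
    ``substratum_code = NaN`` and ``unclassifiable = True`` rather than
    dropped, so the exclusion is auditable.
    """
    out = tiles.copy()
    codes: list[str | None] = []
    habitats: list[str | None] = []
    flags: list[bool] = []
    unclassifiable: list[bool] = []
    for row in tiles.itertuples(index=False):
        try:
            code = classify_substratum(
                row.cover_hard,
                row.cover_coarse,
                row.cover_sand,
                allow_sediment_mosaics=allow_sediment_mosaics,
            )
        except UnclassifiableTileError:
            codes.append(None)
            habitats.append(None)
            flags.append(False)
            unclassifiable.append(True)
            continue
        hab, flag = habitat_of(code, row.cover_hard, row.cover_coarse, row.cover_sand)
        codes.append(code)
        habitats.append(hab)
        flags.append(flag)
        unclassifiable.append(False)
    out["substratum_code"] = codes
    out["habitat"] = habitats
    out["sub_threshold_mosaic"] = flags
    out["unclassifiable"] = unclassifiable
    n_bad = int(np.sum(unclassifiable))
    if n_bad:
        logger.warning("%d tiles unclassifiable (no component >= 50%% cover)", n_bad)
    return out


@dataclass
class LengthWeightTable:
    """Allometric length–weight coefficients per morphotype.

    Biomass is estimated as ``a * length_cm ** b`` gram wet weight. The table
    maps morphotype ids to (a, b) pairs; morphotypes without an entry fall
    back to the wildcard default (logged once per morphotype).
    """

    coefficients: dict[str, tuple[float, float]] = field(default_factory=dict)
    default: tuple[float, float] = (0.05, 2.8)

    def __post_init__(self) -> None:
        for key, (a, b) in list(self.coefficients.items()) + [("*", self.default)]:
            if a <= 0 or b < 0:
                raise ValueError(f"coefficients for {key!r}: need a > 0 and b >= 0")
        self._warned: set[str] = set()

    def resolve(self, morphotype_id: str) -> tuple[float, float]:
        try:
            return self.coefficients[morphotype_id]
        except KeyError:
            if morphotype_id not in self._warned:
                logger.info(
                    "no length-weight coefficients for %r; using default a=%g b=%g",
                    morphotype_id,
                    *self.default,
                )
                self._warned.add(morphotype_id)
            return self.default


def biomass_of(length_cm: float, a: float, b: float) -> float:
    """Wet-weight biomass (g) from body length via ``a * L**b``."""
    if length_cm <= 0:
        raise ValueError("length_cm must be positive")
    if a <= 0:
        raise ValueError("allometric coefficient a must be positive")
    return a * length_cm**b


def add_biomass(
    observations: pd.DataFrame, table: LengthWeightTable | None = None
) -> pd.DataFrame:
    """Attach a ``biomass_gwwt`` column computed from length_cm."""
    table = table or LengthWeightTable()
    out = observations.copy()
    ab = np.array(
        [table.resolve(m) for m in out["morphotype_id"].astype(str)], dtype=float
    ).reshape(-1, 2)
    lengths = out["length_cm"].to_numpy(dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("length_cm must be positive")
    out["biomass_gwwt"] = ab[:, 0] * lengths ** ab[:, 1]
    return out


def build_abundance_matrix(
    tiles: pd.DataFrame,
    observations: pd.DataFrame,
    grouping: pd.Series | dict,
    *,
    morphotypes: list[str] | None = None,
    exclude_indeterminate: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool observations into sample-level count and density matrices.

    Parameters
    ----------
    grouping:
        Mapping ``tile_id -> sample_id``. Tiles absent from the mapping are
        ignored (their observations are dropped with them).
    morphotypes:
        Optional explicit column set; useful to declare taxa that may be
        absent from this observation set.
    exclude_indeterminate:
        Drop observations with the reserved morphotype id ``indet``.

    Returns
    -------
    (counts, density):
        ``counts`` is samples x morphotypes individual counts; ``density``
        is counts divided by the summed tile area of each sample (ind/m²).

    Raises
    ------
    ValueError
        If any observation references a tile id absent from ``tiles``.
    """
    grouping = pd.Series(dict(grouping) if not isinstance(grouping, pd.Series) else grouping)
    known_tiles = set(tiles["tile_id"].astype(str))
    orphans = sorted(set(observations["tile_id"].astype(str)) - known_tiles)
    if orphans:
        raise ValueError(f"observations reference unknown tiles: {orphans[:10]}")

    obs = observations.copy()
    obs["tile_id"] = obs["tile_id"].astype(str)
    if exclude_indeterminate:
        n_indet = int((obs["morphotype_id"] == INDETERMINATE_ID).sum())
        if n_indet:
            logger.info("excluding %d indeterminate specimens", n_indet)
        obs = obs[obs["morphotype_id"] != INDETERMINATE_ID]

    grouping.index = grouping.index.astype(str)
    obs["sample_id"] = obs["tile_id"].map(grouping)
    obs = obs.dropna(subset=["sample_id"])

    sample_ids = sorted(pd.unique(grouping.dropna()))
    counts = (
        obs.groupby(["sample_id", "morphotype_id"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=sample_ids, fill_value=0)
    )
    if morphotypes is not None:
        counts = counts.reindex(
            columns=sorted(set(morphotypes) | set(counts.columns)), fill_value=0
        )
    counts = counts.astype(int)
    counts.index.name = "sample_id"
    counts.columns.name = "morphotype_id"

    areas = (
        tiles.assign(tile_id=tiles["tile_id"].astype(str))
        .assign(sample_id=lambda d: d["tile_id"].map(grouping))
        .dropna(subset=["sample_id"])
        .groupby("sample_id")["area_m2"]
        .sum()
        .reindex(counts.index)
    )
    density = counts.div(areas, axis=0)
    return counts, density


# -- delimited-text I/O -------------------------------------------------------

_TILE_COLUMNS = [
    "tile_id",
    "transect_id",
    "order_index",
    "area_m2",
    "cover_hard",
    "cover_coarse",
    "cover_sand",
]
_OBS_COLUMNS = ["tile_id", "morphotype_id", "length_cm"]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_tiles(path) -> pd.DataFrame:
    """Read a tile-annotation table (CSV/TSV with header)."""
    df = _read_table(path, _TILE_COLUMNS)
    df["tile_id"] = df["tile_id"].astype(str)
    dup = df.duplicated(subset=["transect_id", "order_index"])
    if dup.any():
        raise ValueError("order_index must be unique within each transect")
    return df


def read_observations(path) -> pd.DataFrame:
    """Read a long-format observation table (CSV/TSV with header)."""
    df = _read_table(path, _OBS_COLUMNS)
    df["tile_id"] = df["tile_id"].astype(str)
    if (df["length_cm"] < 1).any():
        warnings.warn("observations with length_cm < 1 present", stacklevel=2)
    return df


def read_coefficients(path) -> LengthWeightTable:
    """Read length-weight coefficients (CSV: morphotype_id, a, b; '*' = default)."""
    df = _read_table(path, ["morphotype_id", "a", "b"])
    coeffs = {
        str(r.morphotype_id): (float(r.a), float(r.b))
        for r in df.itertuples(index=False)
        if str(r.morphotype_id) != "*"
    }
    default = (0.05, 2.8)
    wild = df[df["morphotype_id"].astype(str) == "*"]
    if len(wild):
        default = (float(wild.iloc[0]["a"]), float(wild.iloc[0]["b"]))
    return LengthWeightTable(coefficients=coeffs, default=default)
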