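"""Composite sampling units by a posteriori stratified random pooling.

Single image tiles rarely contain enough individuals to estimate diversity
or composition, and consecutive tiles are spatially autocorrelated. Both
problems are addressed by pooling tiles *at random within a stratum*
(substratum class or summary habitat) into composite replicates of either

* fixed tile number (**composite-area** units, ~150 m² at the default
  20 x 7.3 m² tiles), or
* fixed individual count (**composite-individuals** units, tiles accumulated
  until ~150 specimens).

Every retained tile belongs to exactly one composite; strata are never
mixed; remainder tiles that cannot form an acceptable final composite are
reported, not silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng

logger = logging.getLogger(__name__)

__all__ = [
    "CompositeSample",
    "CompositeSet",
    "make_composite_area",
    "make_composite_individuals",
    "randomization_check",
    "expected_area_replicates",
]


@dataclass(frozen=True)
class CompositeSample:
    """One replicate: a set of same-stratum tiles pooled together."""

    sample_id: str
    stratum: str
    tile_ids: tuple[str, ...]
    area_m2: float
    n_individuals: int
    unit_kind: str  # "area" | "individuals"


@dataclass
class CompositeSet:
    """Composites plus the bookkeeping of discarded remainder tiles."""

    composites: list[CompositeSample]
    discarded: dict[str, list[str]] = field(default_factory=dict)

    def membership(self) -> pd.DataFrame:
        rows = [
            {"sample_id": c.sample_id, "tile_id": t, "stratum": c.stratum}
            for c in self.composites
            for t in c.tile_ids
        ]
        return pd.DataFrame(rows, columns=["sample_id", "tile_id", "stratum"])

    def grouping(self) -> pd.Series:
        """tile_id -> sample_id map for abundance-matrix construction."""
        m = self.membership()
        return pd.Series(m["sample_id"].values, index=m["tile_id"].values)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": c.sample_id,
                "stratum": c.stratum,
                "n_tiles": len(c.tile_ids),
                "area_m2": c.area_m2,
                "n_individuals": c.n_individuals,
            }
            for c in self.composites
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "stratum", "n_tiles", "area_m2", "n_individuals"]
        )


def expected_area_replicates(
    n_tiles: int, tiles_per_composite: int = 20, min_final: int = 15
) -> int:
    """Replicate count produced by the composite-area partition rule.

    ``floor(n / size) + 1`` if the remainder is at least ``min_final``, else
    ``floor(n / size)``.
    """
    full, rem = divmod(n_tiles, tiles_per_composite)
    return full + (1 if rem >= min_final else 0)


def _tile_counts(
    tiles: pd.DataFrame, observations: pd.DataFrame | None
) -> pd.Series:
    if observations is None or observations.empty:
        return pd.Series(0, index=tiles["tile_id"].astype(str))
    counts = observations.groupby(observations["tile_id"].astype(str)).size()
    return counts.reindex(tiles["tile_id"].astype(str), fill_value=0)


def make_composite_area(
    tiles: pd.DataFrame,
    stratum_col: str = "substratum_code",
    tiles_per_composite: int = 20,
    min_final: int = 15,
    seed: int = 0,
    observations: pd.DataFrame | None = None,
) -> CompositeSet:
    """Partition each stratum's tiles into random fixed-size composites.

    Within each stratum the tiles are randomly permuted (without
    replacement) and cut into consecutive groups of ``tiles_per_composite``;
    a final partial group is kept only when it holds at least ``min_final``
    tiles, otherwise its tiles are discarded (and reported). Strata with
    fewer than ``min_final`` tiles yield zero composites, with a warning.

    Per-stratum random streams are derived from the global seed, so adding
    or removing one stratum leaves the others' composites unchanged.
    """
    counts = _tile_counts(tiles, observations)
    composites: list[CompositeSample] = []
    discarded: dict[str, list[str]] = {}
    for stratum, grp in tiles.groupby(stratum_col, dropna=True, sort=True):
        stratum = str(stratum)
        ids = grp["tile_id"].astype(str).to_numpy()
        if len(ids) < min_final:
            logger.warning(
                "stratum %s: %d tiles < min_final=%d, zero composites",
                stratum,
                len(ids),
                min_final,
            )
            discarded[stratum] = list(ids)
            continue
        rng = child_rng(seed, "composite_area", stratum)
        perm = rng.permutation(len(ids))
        ids = ids[perm]
        areas = grp["area_m2"].to_numpy(dtype=float)[perm]
        n_full, rem = divmod(len(ids), tiles_per_composite)
        n_groups = n_full + (1 if rem >= min_final else 0)
        for g in range(n_groups):
            members = ids[g * tiles_per_composite : (g + 1) * tiles_per_composite]
            composites.append(
                CompositeSample(
                    sample_id=f"{stratum}-A{g + 1:03d}",
                    stratum=stratum,
                    tile_ids=tuple(members),
                    area_m2=float(
                        areas[g * tiles_per_composite : (g + 1) * tiles_per_composite].sum()
                    ),
                    n_individuals=int(counts.loc[members].sum()),
                    unit_kind="area",
                )
            )
        leftover = ids[n_groups * tiles_per_composite :] if rem < min_final else ids[:0]
        if len(leftover):
            discarded[stratum] = list(leftover)
    return CompositeSet(composites=composites, discarded=discarded)


def make_composite_individuals(
    tiles: pd.DataFrame,
    observations: pd.DataFrame,
    stratum_col: str = "substratum_code",
    target_individuals: int = 150,
    min_final_frac: float = 0.75,
    seed: int = 0,
) -> CompositeSet:
    """Accumulate randomly ordered tiles until a target individual count.

    Within each stratum, tiles are randomly ordered and accumulated without
    replacement until the cumulative individual count reaches the target;
    the composite is then closed and accumulation restarts. A trailing
    composite below ``min_final_frac * target`` individuals is discarded
    (and reported). A stratum whose total falls short of the target yields
    zero composites, with a warning.
    """
    counts = _tile_counts(tiles, observations)
    composites: list[CompositeSample] = []
    discarded: dict[str, list[str]] = {}
    for stratum, grp in tiles.groupby(stratum_col, dropna=True, sort=True):
        stratum = str(stratum)
        ids = grp["tile_id"].astype(str).to_numpy()
        if counts.loc[ids].sum() < target_individuals:
            logger.warning(
                "stratum %s: %d individuals < target=%d, zero composites",
                stratum,
                int(counts.loc[ids].sum()),
                target_individuals,
            )
            discarded[stratum] = list(ids)
            continue
        rng = child_rng(seed, "composite_individuals", stratum)
        perm = rng.permutation(len(ids))
        ids = ids[perm]
        areas = grp["area_m2"].to_numpy(dtype=float)[perm]
        cnt = counts.loc[ids].to_numpy()

        g, start, acc = 0, 0, 0
        for i in range(len(ids)):
            acc += int(cnt[i])
            if acc >= target_individuals:
                g += 1
                composites.append(
                    CompositeSample(
                        sample_id=f"{stratum}-I{g:03d}",
                        stratum=stratum,
                        tile_ids=tuple(ids[start : i + 1]),
                        area_m2=float(areas[start : i + 1].sum()),
                        n_individuals=acc,
                        unit_kind="individuals",
                    )
                )
                start, acc = i + 1, 0
        if start < len(ids):
            if acc >= min_final_frac * target_individuals:
                g += 1
                composites.append(
                    CompositeSample(
                        sample_id=f"{stratum}-I{g:03d}",
                        stratum=stratum,
                        tile_ids=tuple(ids[start:]),
                        area_m2=float(areas[start:].sum()),
                        n_individuals=acc,
                        unit_kind="individuals",
                    )
                )
            else:
                discarded[stratum] = list(ids[start:])
    return CompositeSet(composites=composites, discarded=discarded)


def randomization_check(
    tiles: pd.DataFrame,
    observations: pd.DataFrame,
    composite_set: CompositeSet,
    stratum_col: str = "substratum_code",
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Check that the random pooling behaved as an unbiased randomization.

    For each stratum with >= 2 composites, verifies and reports:

    * **conservation** — summed composite area and individuals equal the
      retained-tile totals exactly;
    * **unbiasedness** — pooled density over composites equals the retained
      tiles' pooled density exactly (an identity under any partition);
    * **exchangeability** — the observed between-composite variance of
      density is ranked within the distribution obtained by ``n_perm``
      re-randomizations of tiles into the same group sizes. Under genuine
      random pooling the rank is uniform; a systematically extreme rank
      flags a non-random (e.g. sorted) grouping. ``p_variance`` is the
      two-sided permutation p-value of that rank.
    """
    counts = _tile_counts(tiles, observations)
    areas = pd.Series(
        tiles["area_m2"].to_numpy(dtype=float), index=tiles["tile_id"].astype(str)
    )
    rows = []
    by_stratum: dict[str, list[CompositeSample]] = {}
    for c in composite_set.composites:
        by_stratum.setdefault(c.stratum, []).append(c)
    for stratum, comps in sorted(by_stratum.items()):
        retained = [t for c in comps for t in c.tile_ids]
        tile_area = areas.loc[retained].to_numpy()
        tile_cnt = counts.loc[retained].to_numpy(dtype=float)
        total_area = float(tile_area.sum())
        total_ind = float(tile_cnt.sum())
        conserved = np.isclose(
            total_area, sum(c.area_m2 for c in comps)
        ) and total_ind == sum(c.n_individuals for c in comps)

        dens = np.array([c.n_individuals / c.area_m2 for c in comps])
        pooled_density = total_ind / total_area
        obs_var = float(np.var(dens, ddof=1)) if len(comps) > 1 else np.nan

        rank = np.nan
        p_var = np.nan
        if len(comps) > 1 and n_perm > 0:
            sizes = [len(c.tile_ids) for c in comps]
            edges = np.cumsum([0] + sizes)
            rng = child_rng(seed, "randomization_check", stratum)
            null = np.empty(n_perm)
            cnt_arr, area_arr = tile_cnt, tile_area
            for p in range(n_perm):
                perm = rng.permutation(len(retained))
                cp, ap = cnt_arr[perm], area_arr[perm]
                d = np.array(
                    [
                        cp[edges[i] : edges[i + 1]].sum()
                        / ap[edges[i] : edges[i + 1]].sum()
                        for i in range(len(sizes))
                    ]
                )
                null[p] = np.var(d, ddof=1)
            rank = float((null <= obs_var).mean())
            lower = (1 + np.sum(null <= obs_var)) / (1 + n_perm)
            upper = (1 + np.sum(null >= obs_var)) / (1 + n_perm)
            p_var = float(min(1.0, 2 * min(lower, upper)))

        rows.append(
            {
                "stratum": stratum,
                "n_composites": len(comps),
                "conserved": bool(conserved),
                "pooled_density": pooled_density,
                "mean_composite_density": float(dens.mean()),
                "var_composite_density": obs_var,
                "variance_rank": rank,
                "p_variance": p_var,
            }
        )
    return pd.DataFrame(rows)
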