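"""Full-assessment orchestration: classification → composites → stocks →
diversity → composition → indicators, from one config and one seed.

Every stage writes delimited-text outputs into the run directory and the
run log records every parameter and derived seed, so a run is reproducible
byte for byte and any stage can be re-run from the cached intermediates of
the stages before it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composites as comp
from . import composition as cmp
from . import diversity as dv
from . import indicators as ind
from . import stocks as st
from .core import LengthWeightTable, add_biomass, build_abundance_matrix, classify_tiles, read_coefficients, read_observations, read_tiles
from .synthetic import SurveyConfig, generate_survey

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_assessment"]

STAGES = ("data", "classify", "composites", "stocks", "diversity", "composition", "indicators")


def _habitat_of_code(code: str) -> str:
    if code.startswith("H"):
        return "hard"
    if code.endswith("h"):
        return "intermediate"
    return "coarse" if code.startswith("C") else "sand"


@dataclass
class RunConfig:
    """One assessment run: inputs, unit parameters, randomization counts."""

    out_dir: str = "biotope_run"
    seed: int = 0
    # inputs: either file paths or a synthetic survey
    tiles_path: str | None = None
    observations_path: str | None = None
    coefficients_path: str | None = None
    synthetic: dict = field(default_factory=dict)  # SurveyConfig overrides
    use_synthetic: bool = True
    # sampling-unit parameters
    tiles_per_composite: int = 20
    min_final_tiles: int = 15
    target_individuals: int = 150
    # randomization counts
    n_rand_diversity: int = 200
    n_perm: int = 499
    n_rep_accumulation: int = 100
    n_rand_autosimilarity: int = 200
    target_similarity: float = 0.75
    autosimilarity_sizes: list[int] = field(
        default_factory=lambda: [1, 2, 3, 5, 8, 12, 16, 20, 28, 40, 57, 80,
                                 113, 160, 226, 320]
    )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(**data)


class _Run:
    """Stage executor with file-backed intermediates."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._cache: dict[str, object] = {}

    # -- intermediates --------------------------------------------------

    def _csv(self, name: str) -> Path:
        return self.out / name

    def _load(self, name: str, **kw) -> pd.DataFrame:
        key = f"df:{name}"
        if key not in self._cache:
            path = self._csv(name)
            if not path.exists():
                raise FileNotFoundError(
                    f"{path} missing: run the earlier stage that produces it"
                )
            self._cache[key] = pd.read_csv(path, **kw)
        return self._cache[key]

    def _store(self, name: str, df: pd.DataFrame, **kw) -> None:
        df.to_csv(self._csv(name), index=kw.pop("index", False), **kw)
        self._cache.pop(f"df:{name}", None)  # later reads go through the file

    # -- stages ---------------------------------------------------------

    def data(self) -> None:
        cfg = self.cfg
        if cfg.tiles_path and cfg.observations_path:
            tiles = read_tiles(cfg.tiles_path)
            obs = read_observations(cfg.observations_path)
        elif cfg.use_synthetic:
            sc = SurveyConfig(**{**cfg.synthetic, "rng_seed": cfg.seed})
            tiles, obs, truth = generate_survey(sc)
            (self.out / "truth.json").write_text(json.dumps(truth, default=str))
        else:
            raise ValueError("no input paths and use_synthetic is False")
        lw = (
            read_coefficients(cfg.coefficients_path)
            if cfg.coefficients_path
            else LengthWeightTable()
        )
        obs = add_biomass(obs, lw)
        self._store("tiles.csv", tiles)
        self._store("observations.csv", obs)

    def classify(self) -> None:
        tiles = self._load("tiles.csv", dtype={"tile_id": str})
        self._store("tiles_classified.csv", classify_tiles(tiles))

    def composites(self) -> None:
        tiles = self._load("tiles_classified.csv", dtype={"tile_id": str})
        tiles = tiles[~tiles["unclassifiable"].astype(bool)]
        obs = self._load("observations.csv", dtype={"tile_id": str})
        cfg = self.cfg
        area_set = comp.make_composite_area(
            tiles,
            tiles_per_composite=cfg.tiles_per_composite,
            min_final=cfg.min_final_tiles,
            seed=cfg.seed,
            observations=obs,
        )
        ind_set = comp.make_composite_individuals(
            tiles, obs, target_individuals=cfg.target_individuals, seed=cfg.seed
        )
        self._store("composites_area.csv", area_set.membership())
        self._store("composites_area_summary.csv", area_set.summary())
        self._store("composites_individuals.csv", ind_set.membership())
        self._store("composites_individuals_summary.csv", ind_set.summary())

        # effort table (per-stratum bookkeeping across the three unit kinds)
        per_tile_counts = obs.groupby("tile_id").size()
        rows = []
        for code, grp in tiles.groupby("substratum_code", sort=True):
            a_sum = area_set.summary().query("stratum == @code")
            i_sum = ind_set.summary().query("stratum == @code")
            rows.append(
                {
                    "substratum_code": code,
                    "habitat": _habitat_of_code(str(code)),
                    "n_tiles": len(grp),
                    "area_m2": grp["area_m2"].sum(),
                    "n_individuals": int(
                        per_tile_counts.reindex(grp["tile_id"]).fillna(0).sum()
                    ),
                    "area_replicates": len(a_sum),
                    "area_mean_area": a_sum["area_m2"].mean(),
                    "area_mean_individuals": a_sum["n_individuals"].mean(),
                    "ind_replicates": len(i_sum),
                    "ind_mean_area": i_sum["area_m2"].mean(),
                    "ind_mean_individuals": i_sum["n_individuals"].mean(),
                }
            )
        effort = pd.DataFrame(rows)
        total_area = effort["area_m2"].sum()
        effort["area_pct"] = 100 * effort["area_m2"] / total_area
        self._store("effort_table.csv", effort)

        check = comp.randomization_check(
            tiles, obs, area_set, n_perm=min(200, self.cfg.n_perm), seed=cfg.seed
        )
        self._store("randomization_check.csv", check)

    def _tile_metrics(self) -> pd.DataFrame:
        tiles = self._load("tiles_classified.csv", dtype={"tile_id": str})
        tiles = tiles[~tiles["unclassifiable"].astype(bool)].copy()
        obs = self._load("observations.csv", dtype={"tile_id": str})
        counts = obs.groupby("tile_id").size()
        biomass = obs.groupby("tile_id")["biomass_gwwt"].sum()
        tiles["n_individuals"] = (
            counts.reindex(tiles["tile_id"]).to_numpy(dtype=float, na_value=0.0)
        )
        tiles["biomass_gwwt"] = (
            biomass.reindex(tiles["tile_id"]).to_numpy(dtype=float, na_value=0.0)
        )
        tiles["density"] = tiles["n_individuals"] / tiles["area_m2"]
        tiles["biomass_density"] = tiles["biomass_gwwt"] / tiles["area_m2"]
        return tiles

    def stocks(self) -> None:
        tiles = self._tile_metrics()
        cfg = self.cfg
        dens_offset = 1.0 / tiles["area_m2"].mean()  # one individual per tile
        pos_b = tiles.loc[tiles["biomass_density"] > 0, "biomass_density"]
        bio_offset = float(pos_b.min()) if len(pos_b) else dens_offset

        rows, tests = [], {}
        for metric, offset in (("density", dens_offset), ("biomass_density", bio_offset)):
            groups, labels = [], []
            for hab, grp in tiles.groupby("habitat", sort=True):
                est = st.geometric_mean_ci(grp[metric], offset=offset)
                rows.append(
                    {
                        "habitat": hab,
                        "metric": metric,
                        "geometric_mean": est.geometric_mean,
                        "ci95_low": est.ci95_low,
                        "ci95_high": est.ci95_high,
                        "n_units": est.n_units,
                        "offset": offset,
                    }
                )
                groups.append(np.log(grp[metric].to_numpy() + offset))
                labels.append(str(hab))
            F, df1, df2, p = st.welch_anova(groups)
            gh = st.games_howell(groups, labels=labels)
            tests[metric] = {
                "welch": {"F": F, "df1": df1, "df2": df2, "p": p},
                "games_howell": gh.to_dict(orient="records"),
            }
        self._store("stock_estimates.csv", pd.DataFrame(rows))
        (self.out / "stock_tests.json").write_text(json.dumps(tests, indent=1))

        curves = []
        for hab, grp in tiles.groupby("habitat", sort=True):
            n = len(grp)
            sizes = sorted(set(np.unique(np.geomspace(2, n, 25).astype(int))))
            for metric in ("n_individuals", "biomass_gwwt"):
                cur = st.accumulation_curve(
                    grp[metric],
                    grp["area_m2"],
                    sizes=sizes,
                    n_rep=cfg.n_rep_accumulation,
                    seed=cfg.seed,
                    stratum=str(hab),
                )
                cur["metric"] = "density" if metric == "n_individuals" else "biomass_density"
                curves.append(cur)
        self._store("accumulation_curves.csv", pd.concat(curves, ignore_index=True))

    def _composite_matrices(self):
        tiles = self._load("tiles_classified.csv", dtype={"tile_id": str})
        obs = self._load("observations.csv", dtype={"tile_id": str})
        members = self._load("composites_area.csv", dtype={"tile_id": str})
        grouping = pd.Series(members["sample_id"].values, index=members["tile_id"].values)
        counts, density = build_abundance_matrix(tiles, obs, grouping)
        stratum = members.drop_duplicates("sample_id").set_index("sample_id")["stratum"]
        stratum = stratum.reindex(counts.index)
        habitat = stratum.map(_habitat_of_code)
        areas = (
            tiles.set_index("tile_id")["area_m2"]
            .reindex(members["tile_id"])
            .groupby(members["sample_id"].values)
            .sum()
            .reindex(counts.index)
        )
        return counts, density, stratum, habitat, areas

    def _no_fauna(self, *names: str) -> None:
        """Explicit empty outputs for a survey without countable fauna."""
        logger.warning("no fauna in observations: writing empty outputs")
        for name in names:
            self._store(name, pd.DataFrame({"note": ["no fauna"]}))

    def diversity(self) -> None:
        counts, _, _, habitat, areas = self._composite_matrices()
        if counts.size == 0 or counts.to_numpy().sum() == 0:
            self._no_fauna("diversity_curves.csv", "diversity_at_effort.csv")
            return
        cfg = self.cfg
        curves = dv.rarefy_groups(
            counts, habitat, areas=areas, n_rand=cfg.n_rand_diversity, seed=cfg.seed
        )
        self._store("diversity_curves.csv", curves)
        # compare groups at the largest individual count every curve
        # reaches; groups whose smallest sample already exceeds it are
        # evaluated at their minimum (approximately equal effort)
        hi = float(curves.groupby(["group", "index"])["mean_individuals"].max().min())
        at = dv.diversity_at_effort(curves, hi, clamp=True)
        self._store("diversity_at_effort.csv", at)

    def composition(self) -> None:
        counts, density, stratum, habitat, _ = self._composite_matrices()
        if counts.size == 0 or counts.to_numpy().sum() == 0:
            self._no_fauna(
                "ordination.csv", "autosimilarity.csv", "required_unit_size.csv"
            )
            return
        cfg = self.cfg
        D = cmp.bray_curtis(density, transform="log1p")
        D.to_csv(self._csv("dissimilarity.csv"))
        ord_res = cmp.nmds(D, seed=cfg.seed)
        coords = ord_res.coordinates.copy()
        coords["stratum"] = stratum.reindex(coords.index)
        coords["habitat"] = habitat.reindex(coords.index)
        self._store("ordination.csv", coords, index=True)

        # strata with a single composite cannot enter the rank contrast
        sizes = stratum.value_counts()
        testable = stratum[stratum.map(sizes) >= 2]
        if sizes.min() < 2:
            logger.warning(
                "strata with one composite excluded from ANOSIM: %s",
                list(sizes[sizes < 2].index),
            )
        Dt = D.loc[testable.index, testable.index]
        an = cmp.anosim(Dt, testable, n_perm=cfg.n_perm, seed=cfg.seed)
        pw = cmp.pairwise_anosim(Dt, testable, n_perm=cfg.n_perm, seed=cfg.seed)
        (self.out / "anosim.json").write_text(
            json.dumps(
                {
                    "global": {"R": an.R, "p": an.p, "n_perm": an.n_perm},
                    "pairwise": pw.to_dict(orient="records"),
                    "nmds_stress": ord_res.stress,
                },
                indent=1,
            )
        )

        # autosimilarity per summary habitat, on tile-level compositions
        tiles = self._load("tiles_classified.csv", dtype={"tile_id": str})
        tiles = tiles[~tiles["unclassifiable"].astype(bool)]
        obs = self._load("observations.csv", dtype={"tile_id": str})
        tile_counts, _ = build_abundance_matrix(
            tiles, obs, pd.Series(tiles["tile_id"].values, index=tiles["tile_id"].values)
        )
        tile_areas = tiles.set_index("tile_id")["area_m2"]
        curves, units = [], []
        for hab, grp in tiles.groupby("habitat", sort=True):
            ids = grp["tile_id"]
            cur = cmp.autosimilarity(
                tile_counts.loc[ids],
                tile_areas,
                sizes=cfg.autosimilarity_sizes,
                n_rand=cfg.n_rand_autosimilarity,
                seed=cfg.seed,
                stratum=str(hab),
            )
            curves.append(cur)
            try:
                req = cmp.required_unit_size(cur, cfg.target_similarity)
                units.append({"habitat": hab, **req})
            except ValueError as e:
                logger.warning("habitat %s: %s", hab, e)
        self._store("autosimilarity.csv", pd.concat(curves, ignore_index=True))
        self._store("required_unit_size.csv", pd.DataFrame(units))

    def indicators(self) -> None:
        counts, _, stratum, habitat, _ = self._composite_matrices()
        if counts.size == 0 or counts.to_numpy().sum() == 0:
            self._no_fauna(
                "indval_substratum.csv", "indval_habitat.csv", "twinspan_leaves.csv"
            )
            return
        cfg = self.cfg
        iv_code = ind.indval(counts, stratum, n_perm=cfg.n_perm, seed=cfg.seed)
        iv_hab = ind.indval(counts, habitat, n_perm=cfg.n_perm, seed=cfg.seed)
        self._store("indval_substratum.csv", iv_code, index=True)
        self._store("indval_habitat.csv", iv_hab, index=True)

        tree = ind.twinspan_divide(counts, max_depth=2, seed=cfg.seed)
        rows = []
        for i, leaf in enumerate(tree.leaves()):
            for s in leaf.samples:
                rows.append(
                    {
                        "sample_id": s,
                        "leaf": i,
                        "habitat": habitat.get(s),
                        "stratum": stratum.get(s),
                    }
                )
        self._store("twinspan_leaves.csv", pd.DataFrame(rows))


def run_assessment(config: RunConfig, stages=None) -> Path:
    """Run the assessment pipeline; returns the output directory.

    ``stages`` selects a subset (in canonical order); earlier stages must
    have run before (their cached outputs are reused). Deterministic for a
    fixed config and seed. Any stage error aborts with the stage named.
    """
    run = _Run(config)
    selected = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    for stage in selected:
        try:
            getattr(run, stage)()
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    log = {"config": asdict(config), "stages": selected, "version": 1}
    (run.out / "run_log.json").write_text(json.dumps(log, indent=1))
    return run.out
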