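"""Assemblage composition: dissimilarity, ordination, group tests, and
autosimilarity-based sampling-unit sizing.

Composition is compared through Bray–Curtis dissimilarity of log-transformed
densities, visualised by 2-D non-metric multidimensional scaling (NMDS,
Kruskal stress-1), and tested with the rank-based ANOSIM permutation test.

The *autosimilarity curve* sizes the sampling unit: for increasing composite
sizes, pairs of disjoint random composites are drawn within a stratum and
their mean Bray–Curtis similarity (1 − dissimilarity) recorded. The effort
at which self-similarity reaches a target (conventionally 0.75, i.e. 0.25
within-habitat dissimilarity between replicates) is the smallest sampling
unit that describes the assemblage to that standard — expressible in tiles,
seabed area, or number of individuals. Because habitats differ mainly in
density, curves indexed by individuals collapse together far more tightly
than curves indexed by area.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.manifold import MDS

from ._rng import child_rng, child_seed

__all__ = [
    "OrdinationResult",
    "AnosimResult",
    "bray_curtis",
    "nmds",
    "anosim",
    "pairwise_anosim",
    "autosimilarity",
    "required_unit_size",
]


def _transform(X: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log1p":
        return np.log1p(X)
    if transform in (None, "none"):
        return X
    raise ValueError(f"unknown transform {transform!r}")


def bray_curtis(matrix: pd.DataFrame, transform: str = "log1p") -> pd.DataFrame:
    """Bray–Curtis dissimilarity matrix of (optionally log1p) abundances.

    All-zero samples make the dissimilarity undefined; they are excluded
    with a warning.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    nonzero = X.sum(axis=1) > 0
    if not nonzero.all():
        dropped = list(matrix.index[~nonzero])
        warnings.warn(
            f"excluding {len(dropped)} all-zero samples from dissimilarity: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
        matrix = matrix.loc[nonzero]
        X = X[nonzero]
    D = squareform(pdist(_transform(X, transform), metric="braycurtis"))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


@dataclass(frozen=True)
class OrdinationResult:
    """Best NMDS configuration over random restarts."""

    coordinates: pd.DataFrame
    stress: float
    restart_stresses: tuple[float, ...]
    converged: bool


def nmds(
    dissim: pd.DataFrame,
    dims: int = 2,
    n_restarts: int = 8,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1, best of random restarts.

    The returned configuration is centred and rotated to its principal axes
    (with a deterministic sign convention) so repeated runs are directly
    comparable.
    """
    D = dissim.to_numpy(dtype=float)
    n = D.shape[0]
    if n < dims + 2:
        raise ValueError("need at least dims + 2 samples")
    best = None
    stresses = []
    for r in range(n_restarts):
        model = MDS(
            n_components=dims,
            metric=False,
            dissimilarity="precomputed",
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
            random_state=child_seed(seed, "nmds", str(r)),
        )
        with warnings.catch_warnings():
            # sklearn renames these arguments across versions; the values
            # used here are equivalent under both spellings
            warnings.simplefilter("ignore", FutureWarning)
            coords = model.fit_transform(D)
        stresses.append(float(model.stress_))
        if best is None or model.stress_ < best[0]:
            best = (float(model.stress_), coords, model.n_iter_ < max_iter)
    stress, coords, converged = best
    if not converged:
        warnings.warn("NMDS best restart did not converge; best effort returned",
                      stacklevel=2)
    # principal-axis rotation with sign convention for reproducibility
    coords = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    signs = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    coords = coords @ (vt * signs[:, None]).T
    frame = pd.DataFrame(
        coords, index=dissim.index, columns=[f"axis{i + 1}" for i in range(dims)]
    )
    return OrdinationResult(
        coordinates=frame,
        stress=stress,
        restart_stresses=tuple(stresses),
        converged=bool(converged),
    )


@dataclass(frozen=True)
class AnosimResult:
    """Rank-based analysis of similarities."""

    R: float
    p: float
    n_perm: int


def _anosim_stat(ranks: np.ndarray, within_mask: np.ndarray, M: int) -> float:
    rw = ranks[within_mask].mean()
    rb = ranks[~within_mask].mean()
    return float((rb - rw) / (M / 2.0))


def anosim(
    dissim: pd.DataFrame, groups: pd.Series, n_perm: int = 999, seed: int = 0
) -> AnosimResult:
    """ANOSIM permutation test of compositional differences between groups.

    R contrasts mean between- and within-group ranks of the pairwise
    dissimilarities, scaled to [-1, 1]; being rank-based it is invariant to
    monotone transforms of the dissimilarities. The p-value is
    ``(1 + #{perm R >= observed}) / (1 + n_perm)`` under random relabelling,
    so it is never reported as exactly zero.
    """
    g = pd.Series(groups).reindex(dissim.index)
    if g.isna().any():
        raise ValueError("groups missing for some samples")
    labels, counts = np.unique(g.to_numpy(), return_counts=True)
    if len(labels) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    D = dissim.to_numpy(dtype=float)
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = rankdata(D[iu])
    M = n * (n - 1) // 2
    codes = pd.factorize(g.to_numpy())[0]
    within = codes[iu[0]] == codes[iu[1]]
    R_obs = _anosim_stat(ranks, within, M)

    rng = child_rng(seed, "anosim")
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        w = perm[iu[0]] == perm[iu[1]]
        if _anosim_stat(ranks, w, M) >= R_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return AnosimResult(R=R_obs, p=float(p), n_perm=n_perm)


def pairwise_anosim(
    dissim: pd.DataFrame, groups: pd.Series, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """ANOSIM for every pair of groups; singleton groups are skipped."""
    g = pd.Series(groups).reindex(dissim.index)
    rows = []
    for a, b in itertools.combinations(sorted(pd.unique(g.dropna())), 2):
        members = g.index[(g == a) | (g == b)]
        if (g == a).sum() < 2 or (g == b).sum() < 2:
            warnings.warn(f"skipping pair ({a}, {b}): singleton group", stacklevel=2)
            continue
        res = anosim(
            dissim.loc[members, members],
            g.loc[members],
            n_perm=n_perm,
            seed=child_seed(seed, "pairwise", str(a), str(b)),
        )
        rows.append({"group_a": a, "group_b": b, "R": res.R, "p": res.p,
                     "n_perm": res.n_perm})
    return pd.DataFrame(rows)


def autosimilarity(
    tile_counts: pd.DataFrame,
    tile_areas: pd.Series,
    sizes,
    n_rand: int = 1000,
    seed: int = 0,
    stratum: str = "",
    transform: str = "log1p",
) -> pd.DataFrame:
    """Mean similarity between disjoint random composites vs composite size.

    For each size ``s``: draw two disjoint s-tile composites without
    replacement, pool each into a density composition (counts / summed
    area, then transformed), and record 1 − Bray–Curtis between the pair;
    the mean over ``n_rand`` repeats is the autosimilarity at that size.
    Sizes needing more than the available tiles for a disjoint pair are
    dropped with a warning.

    Returns a frame: stratum, n_tiles, area_m2, mean_individuals,
    similarity, n_rand.
    """
    X = tile_counts.to_numpy(dtype=float)
    a = tile_areas.reindex(tile_counts.index).to_numpy(dtype=float)
    n = X.shape[0]
    rows = []
    for s in sizes:
        s = int(s)
        if 2 * s > n:
            warnings.warn(
                f"stratum {stratum!r}: size {s} needs {2 * s} tiles, have {n}; dropped",
                stacklevel=2,
            )
            continue
        rng = child_rng(seed, "autosimilarity", stratum, str(s))
        sims = np.empty(n_rand)
        inds = np.empty(n_rand)
        chunk = max(1, int(2**22 // max(1, 2 * s * X.shape[1])))
        for start in range(0, n_rand, chunk):
            m = min(chunk, n_rand - start)
            u = rng.random((m, n))
            pick = np.argpartition(u, 2 * s - 1, axis=1)[:, : 2 * s]
            ia, ib = pick[:, :s], pick[:, s:]
            ca = X[ia].sum(axis=1)
            cb = X[ib].sum(axis=1)
            da = _transform(ca / a[ia].sum(axis=1, keepdims=True), transform)
            db = _transform(cb / a[ib].sum(axis=1, keepdims=True), transform)
            num = np.abs(da - db).sum(axis=1)
            den = (da + db).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(den > 0, num / den, np.nan)
            sims[start : start + m] = 1.0 - d
            inds[start : start + m] = 0.5 * (ca.sum(axis=1) + cb.sum(axis=1))
        rows.append(
            {
                "stratum": stratum,
                "n_tiles": s,
                "area_m2": float(s * a.mean()),
                "mean_individuals": float(np.nanmean(inds)),
                "similarity": float(np.nanmean(sims)),
                "n_rand": n_rand,
            }
        )
    return pd.DataFrame(rows)


def required_unit_size(
    curve: pd.DataFrame, target_similarity: float = 0.75
) -> dict[str, float]:
    """Smallest effort at which mean autosimilarity reaches the target.

    Linear interpolation between evaluated sizes; reported on all three
    effort axes (tiles, seabed area, individuals). Raises if the curve
    never reaches the target, reporting the curve maximum.
    """
    cur = curve.sort_values("n_tiles").reset_index(drop=True)
    sim = cur["similarity"].to_numpy(dtype=float)
    hit = np.nonzero(sim >= target_similarity)[0]
    if len(hit) == 0:
        raise ValueError(
            f"autosimilarity never reaches {target_similarity}: max "
            f"{sim.max():.3f} at {int(cur['n_tiles'].iloc[sim.argmax()])} tiles"
        )
    j = int(hit[0])
    axes = ("n_tiles", "area_m2", "mean_individuals")
    if j == 0:
        return {ax: float(cur[ax].iloc[0]) for ax in axes} | {
            "similarity": float(sim[0])
        }
    frac = (target_similarity - sim[j - 1]) / (sim[j] - sim[j - 1])
    out = {
        ax: float(cur[ax].iloc[j - 1] + frac * (cur[ax].iloc[j] - cur[ax].iloc[j - 1]))
        for ax in axes
    }
    out["similarity"] = float(target_similarity)
    return out
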