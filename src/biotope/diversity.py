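"""Sample-based rarefaction of richness and Hill diversity.

Diversity is profiled against sampling effort by randomizing the order in
which replicate samples are pooled: estimated taxon richness ``Sest`` from
randomizations *without* replacement (so the curve ends exactly at the
observed pooled richness), and the Hill numbers of order 1 and 2 — the
exponential Shannon index ``expH'`` and the inverse Simpson index ``1/D``,
both "effective species" counts — from randomizations *with* replacement.
Curves carry percentile confidence bands and are re-indexed by mean
cumulative individuals and cumulative seabed area, so groups can be
compared at equal individuals rather than equal area.

A combinatorial closed form for the without-replacement richness expectation
is included; it serves as an analytic cross-check of the resampled ``Sest``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._rng import child_rng

__all__ = [
    "shannon_exp",
    "simpson_inv",
    "rarefy_samples",
    "rarefy_groups",
    "sest_closed_form",
    "diversity_at_effort",
]

INDICES = ("Sest", "expH", "invD")


def _checked_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if c.sum() <= 0:
        raise ValueError("counts are all zero")
    return c


def shannon_exp(counts) -> float:
    """Exponential Shannon index, exp(H') — Hill number of order 1."""
    c = _checked_counts(counts)
    p = c[c > 0] / c.sum()
    return float(np.exp(-(p * np.log(p)).sum()))


def simpson_inv(counts) -> float:
    """Inverse Simpson index, 1/D — Hill number of order 2."""
    c = _checked_counts(counts)
    p = c / c.sum()
    return float(1.0 / (p**2).sum())


def sest_closed_form(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Analytic sample-based rarefaction of richness.

    Expected pooled richness when t of the T samples are drawn without
    replacement: ``sum_i [1 - C(T - T_i, t) / C(T, t)]`` where ``T_i`` is
    the number of samples in which taxon i occurs. Returned for
    t = 1..T. Evaluated through log-gamma for stability.
    """
    X = np.asarray(matrix, dtype=float)
    T = X.shape[0]
    Ti = (X > 0).sum(axis=0)
    Ti = Ti[Ti > 0]
    t = np.arange(1, T + 1)

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = np.zeros(T)
    for j, tj in enumerate(t):
        valid = (T - Ti) >= tj
        frac = np.zeros(len(Ti))
        frac[valid] = np.exp(logC(T - Ti[valid], tj) - logC(T, tj))
        out[j] = (1.0 - frac).sum()
    return out


def _pool_with_replacement(
    X: np.ndarray, n_ind: np.ndarray, t: int, n_rand: int, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """expH' and 1/D of pooled counts over n_rand draws of t samples."""
    idx = rng.integers(0, X.shape[0], size=(n_rand, t))
    pooled = X[idx].sum(axis=1)  # (n_rand, S)
    tot = pooled.sum(axis=1, keepdims=True)
    p = np.divide(pooled, tot, out=np.zeros_like(pooled), where=tot > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    expH = np.exp(-plogp.sum(axis=1))
    invD = 1.0 / (p**2).sum(axis=1)
    individuals = n_ind[idx].sum(axis=1)
    return expH, invD, individuals


def rarefy_samples(
    matrix: pd.DataFrame,
    areas: pd.Series | None = None,
    group: str = "",
    n_rand: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Rarefaction curves of Sest, expH' and 1/D for one group of samples.

    Parameters
    ----------
    matrix:
        samples x morphotypes counts for one group of replicates.
    areas:
        Per-sample seabed area (m²), aligned with the matrix index; when
        given the curves also carry a cumulative-area axis.
    n_rand:
        Randomizations per effort level (without replacement for Sest,
        with replacement for the Hill indices).

    Returns a long-format frame: group, index, t (samples pooled),
    mean_individuals, area_m2, mean, ci_low, ci_high, n_randomizations.
    """
    X = matrix.to_numpy(dtype=float)
    T = X.shape[0]
    if T < 1 or X.sum() <= 0:
        raise ValueError("matrix must contain at least one individual")
    if T == 1:
        warnings.warn(f"group {group!r} has a single sample: point estimate only",
                      stacklevel=2)
    n_ind = X.sum(axis=1)
    area_arr = (
        areas.reindex(matrix.index).to_numpy(dtype=float) if areas is not None else None
    )
    lo_q, hi_q = 100 * (0.5 - ci / 2), 100 * (0.5 + ci / 2)
    rows = []

    # Sest: n_rand random orderings, cumulative presence
    rng = child_rng(seed, "rarefy_sest", group)
    pres = X > 0
    sest = np.empty((n_rand, T))
    ind_cum = np.empty((n_rand, T))
    for r in range(n_rand):
        order = rng.permutation(T)
        seen = np.cumsum(pres[order], axis=0) > 0  # (T, S) cumulative presence
        sest[r] = seen.sum(axis=1)
        ind_cum[r] = np.cumsum(n_ind[order])
    mean_area_per_sample = float(area_arr.mean()) if area_arr is not None else np.nan
    for j in range(T):
        rows.append(
            {
                "group": group,
                "index": "Sest",
                "t": j + 1,
                "mean_individuals": float(ind_cum[:, j].mean()),
                "area_m2": (j + 1) * mean_area_per_sample,
                "mean": float(sest[:, j].mean()),
                "ci_low": float(np.percentile(sest[:, j], lo_q)),
                "ci_high": float(np.percentile(sest[:, j], hi_q)),
                "n_randomizations": n_rand,
            }
        )

    # expH' and 1/D: with-replacement pooling
    for name in ("expH", "invD"):
        rng = child_rng(seed, f"rarefy_{name}", group)
        for t in range(1, T + 1):
            expH, invD, individuals = _pool_with_replacement(X, n_ind, t, n_rand, rng)
            vals = expH if name == "expH" else invD
            rows.append(
                {
                    "group": group,
                    "index": name,
                    "t": t,
                    "mean_individuals": float(individuals.mean()),
                    "area_m2": t * mean_area_per_sample,
                    "mean": float(vals.mean()),
                    "ci_low": float(np.percentile(vals, lo_q)),
                    "ci_high": float(np.percentile(vals, hi_q)),
                    "n_randomizations": n_rand,
                }
            )
    return pd.DataFrame(rows)


def rarefy_groups(
    matrix: pd.DataFrame,
    groups: pd.Series,
    areas: pd.Series | None = None,
    n_rand: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rarefaction curves for every group of samples (seeded per group)."""
    frames = []
    for g in sorted(pd.unique(groups)):
        sub = matrix.loc[groups[groups == g].index]
        frames.append(
            rarefy_samples(sub, areas=areas, group=str(g), n_rand=n_rand, seed=seed)
        )
    return pd.concat(frames, ignore_index=True)


def diversity_at_effort(
    curves: pd.DataFrame,
    effort_target: float,
    effort_axis: str = "mean_individuals",
    clamp: bool = False,
) -> pd.DataFrame:
    """Interpolate every (group, index) curve at a common effort.

    Groups are most meaningfully compared at an equal number of
    *individuals* (the default axis) rather than equal area, because
    densities differ strongly between habitats. Linear interpolation only —
    a target outside a curve's support raises rather than extrapolates,
    unless ``clamp`` is set, in which case the target is clipped into each
    curve's support (an *approximately* equal effort; the ``effort`` column
    reports the value actually used per group, e.g. a dense habitat whose
    single smallest sample already exceeds the target).
    """
    rows = []
    for (g, idx), cur in curves.groupby(["group", "index"]):
        cur = cur.sort_values(effort_axis)
        x = cur[effort_axis].to_numpy(dtype=float)
        target = effort_target
        if not (x.min() <= target <= x.max()):
            if not clamp:
                raise ValueError(
                    f"effort {effort_target} outside curve support "
                    f"[{x.min():g}, {x.max():g}] for group={g!r} index={idx!r}"
                )
            target = float(np.clip(target, x.min(), x.max()))
        rows.append(
            {
                "group": g,
                "index": idx,
                "effort": target,
                "mean": float(np.interp(target, x, cur["mean"])),
                "ci_low": float(np.interp(target, x, cur["ci_low"])),
                "ci_high": float(np.interp(target, x, cur["ci_high"])),
            }
        )
    return pd.DataFrame(rows)
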