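"""Indicator species analysis: IndVal scores and a divisive two-way
classification in the TWINSPAN tradition.

IndVal combines *specificity* A (a taxon's mean abundance in a group
relative to its summed mean abundance over all groups) and *fidelity* B
(the fraction of the group's samples in which it occurs); the indicator
value is sqrt(A*B) (or A*B), maximised over groups and tested by permuting
sample-group labels. A taxon exclusive to one group and present in every
one of its samples scores exactly 1.

The two-way classification is a *simplified* TWINSPAN: abundances are
expanded into pseudospecies at logarithmic cut levels, samples are
polarized by the sign of their first correspondence-analysis axis score,
and the split is refined by the pseudospecies with the largest frequency
contrast between the tentative sides. This captures the ordination-based
divisive behaviour used for depth-2 habitat classification; it is not
Hill's full algorithm (no preferential/borderline pseudospecies handling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng

__all__ = [
    "indval",
    "pseudospecies_transform",
    "DivisionNode",
    "twinspan_divide",
    "DEFAULT_CUT_LEVELS",
]

#: Five logarithmically arranged abundance thresholds for pseudospecies.
DEFAULT_CUT_LEVELS = (1, 2, 5, 20, 100)


def indval(
    matrix: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    mode: str = "sqrt",
) -> pd.DataFrame:
    """Indicator value of every morphotype for its best group.

    Parameters
    ----------
    matrix:
        samples x morphotypes abundances.
    groups:
        Sample-group labels aligned with the matrix index.
    mode:
        "sqrt" scores sqrt(A*B) (the indicspecies convention); "product"
        scores A*B.

    Returns a frame indexed by morphotype: best group, A, B, indval, p
    (permutation, never exactly 0), and per-group frequency-of-occurrence
    percentages (columns ``freq_<group>``). Morphotypes absent from every
    sample are skipped.
    """
    if mode not in ("sqrt", "product"):
        raise ValueError("mode must be 'sqrt' or 'product'")
    g = pd.Series(groups).reindex(matrix.index)
    if g.isna().any():
        raise ValueError("groups missing for some samples")
    X = matrix.to_numpy(dtype=float)
    present = X.sum(axis=0) > 0
    taxa = matrix.columns[present]
    X = X[:, present]
    codes, labels = pd.factorize(g.to_numpy(), sort=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    G = np.eye(k)[codes]  # (n, k) one-hot
    n_per = G.sum(axis=0)

    def scores(Xv: np.ndarray, onehot: np.ndarray) -> tuple[np.ndarray, ...]:
        means = (onehot.T @ Xv) / n_per[:, None]  # (k, S)
        denom = means.sum(axis=0)
        A = np.divide(means, denom, out=np.zeros_like(means), where=denom > 0)
        B = (onehot.T @ (Xv > 0)) / n_per[:, None]
        iv = A * B
        if mode == "sqrt":
            iv = np.sqrt(iv)
        return A, B, iv

    A, B, iv = scores(X, G)
    best = iv.argmax(axis=0)
    obs = iv.max(axis=0)

    rng = child_rng(seed, "indval")
    exceed = np.zeros(len(taxa))
    for _ in range(n_perm):
        perm = rng.permutation(len(codes))
        _, _, ivp = scores(X, G[perm])
        exceed += ivp.max(axis=0) >= obs
    p = (1 + exceed) / (1 + n_perm)

    freq = (G.T @ (X > 0)) / n_per[:, None] * 100.0  # (k, S) occurrence %
    out = pd.DataFrame(
        {
            "group": [labels[b] for b in best],
            "A": A[best, np.arange(len(taxa))],
            "B": B[best, np.arange(len(taxa))],
            "indval": obs,
            "p": p,
        },
        index=pd.Index(taxa, name="morphotype_id"),
    )
    for j, lab in enumerate(labels):
        out[f"freq_{lab}"] = freq[j]
    return out.sort_values("indval", ascending=False)


def pseudospecies_transform(
    matrix: pd.DataFrame, cut_levels=DEFAULT_CUT_LEVELS
) -> pd.DataFrame:
    """Expand abundances into binary pseudospecies columns.

    Column ``<taxon>|<j>`` is 1 iff the taxon's abundance in the sample is
    at least the j-th cut level. Cut levels must be strictly increasing.
    """
    cuts = list(cut_levels)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cut levels must be strictly increasing")
    X = matrix.to_numpy(dtype=float)
    blocks = [(X >= c).astype(np.int8) for c in cuts]
    cols = [f"{t}|{j + 1}" for j in range(len(cuts)) for t in matrix.columns]
    out = pd.DataFrame(
        np.concatenate(blocks, axis=1), index=matrix.index, columns=cols
    )
    # keep taxon-major ordering: sp1|1..sp1|k, sp2|1.. for readability
    ordered = [f"{t}|{j + 1}" for t in matrix.columns for j in range(len(cuts))]
    return out[ordered]


@dataclass
class DivisionNode:
    """One node of the divisive classification tree."""

    samples: tuple[str, ...]
    depth: int
    indicators: list[str] = field(default_factory=list)
    eigenvalue: float | None = None
    children: list["DivisionNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["DivisionNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]


def _ca_first_axis(Y: np.ndarray) -> tuple[np.ndarray, float]:
    """First correspondence-analysis axis row scores and its eigenvalue."""
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep_r, keep_c = r > 0, c > 0
    S = (P[np.ix_(keep_r, keep_c)] - np.outer(r[keep_r], c[keep_c])) / np.sqrt(
        np.outer(r[keep_r], c[keep_c])
    )
    u, sv, _ = np.linalg.svd(S, full_matrices=False)
    scores = np.zeros(Y.shape[0])
    scores[keep_r] = u[:, 0] / np.sqrt(r[keep_r]) * sv[0]
    return scores, float(sv[0] ** 2)


def _divide_once(
    pseudo: pd.DataFrame, n_indicators: int = 5
) -> tuple[np.ndarray, list[str], float] | None:
    """One binary division: CA polarization refined by indicator pseudospecies.

    Returns (side assignment in {0,1}, indicator pseudospecies, eigenvalue)
    or None when no valid division exists (degenerate matrix).
    """
    Y = pseudo.to_numpy(dtype=float)
    if Y.sum() == 0 or np.all(np.ptp(Y, axis=0) == 0):
        return None
    scores, eig = _ca_first_axis(Y)
    if np.allclose(scores, scores[0]):
        return None
    side = (scores > np.median(scores)).astype(int)
    if side.min() == side.max():
        side = (scores > scores.mean()).astype(int)
        if side.min() == side.max():
            return None

    # indicator refinement: pseudospecies with largest |frequency difference|
    f1 = Y[side == 1].mean(axis=0)
    f0 = Y[side == 0].mean(axis=0)
    diff = f1 - f0
    order = np.argsort(-np.abs(diff))[:n_indicators]
    indicators = [pseudo.columns[i] for i in order if abs(diff[i]) > 0]
    if indicators:
        idx = [pseudo.columns.get_loc(c) for c in indicators]
        sign = np.sign(diff[idx])
        ind_score = (Y[:, idx] * sign).sum(axis=1)
        thresh = np.median(ind_score)
        refined = (ind_score > thresh).astype(int)
        if 0 < refined.sum() < len(refined):
            side = refined
    return side, indicators, eig


def twinspan_divide(
    matrix: pd.DataFrame,
    max_depth: int = 2,
    min_size: int = 4,
    cut_levels=DEFAULT_CUT_LEVELS,
    seed: int = 0,
) -> DivisionNode:
    """Divisive two-way classification of samples by faunal composition.

    Recursively splits the sample set (to ``max_depth``) on the first
    correspondence-analysis axis of the pseudospecies matrix, refined by
    the highest-contrast indicator pseudospecies. Nodes smaller than
    ``min_size`` samples, or with no compositional structure left, become
    leaves. Deterministic: the same matrix always yields the same tree.

    Leaf membership (``root.leaves()``) supports confusion-matrix
    comparison against independently assigned habitat labels.
    """
    if len(matrix) < min_size:
        raise ValueError(f"need at least {min_size} samples")
    pseudo_full = pseudospecies_transform(matrix, cut_levels)

    def grow(samples: pd.Index, depth: int) -> DivisionNode:
        node = DivisionNode(samples=tuple(samples), depth=depth)
        if depth >= max_depth or len(samples) < min_size:
            return node
        division = _divide_once(pseudo_full.loc[samples])
        if division is None:
            return node
        side, indicators, eig = division
        node.indicators = indicators
        node.eigenvalue = eig
        for s in (0, 1):
            members = samples[side == s]
            node.children.append(grow(members, depth + 1))
        return node

    return grow(matrix.index, 0)
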