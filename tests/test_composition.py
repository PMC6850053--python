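import numpy as np
import pandas as pd
import pytest

from biotope import (
    anosim,
    autosimilarity,
    bray_curtis,
    nmds,
    pairwise_anosim,
    required_unit_size,
)


def _df(rows, prefix="s"):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        rows,
        index=[f"{prefix}{i}" for i in range(rows.shape[0])],
        columns=[f"sp{j}" for j in range(rows.shape[1])],
    )


def test_bray_curtis_hand_computed_values():
    m = _df([[1, 2, 0], [0, 2, 4]])
    D = bray_curtis(m, transform="none")
    assert D.iloc[0, 1] == pytest.approx(5 / 9)
    assert D.iloc[0, 0] == 0.0
    identical = bray_curtis(_df([[3, 1], [3, 1]]), transform="none")
    assert identical.iloc[0, 1] == pytest.approx(0.0)
    disjoint = bray_curtis(_df([[5, 0], [0, 7]]), transform="none")
    assert disjoint.iloc[0, 1] == pytest.approx(1.0)


def test_bray_curtis_symmetry_and_range(classified_small_survey):
    _, tiles, obs, _ = classified_small_survey
    sub = obs[obs["tile_id"].isin(tiles["tile_id"].head(200))]
    m = sub.groupby(["tile_id", "morphotype_id"]).size().unstack(fill_value=0)
    m = m[m.sum(axis=1) > 0].head(40)
    D = bray_curtis(m)
    X = D.to_numpy()
    assert np.allclose(X, X.T)
    assert np.allclose(np.diag(X), 0.0)
    assert (X >= 0).all() and (X <= 1).all()


def test_bray_curtis_excludes_all_zero_samples_with_warning():
    m = _df([[1, 2], [0, 0], [2, 1]])
    with pytest.warns(UserWarning, match="all-zero"):
        D = bray_curtis(m)
    assert list(D.index) == ["s0", "s2"]


def test_nmds_recovers_perfect_euclidean_embedding():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(12, 2))
    from scipy.spatial.distance import pdist, squareform

    D = pd.DataFrame(squareform(pdist(pts)))
    res = nmds(D, n_restarts=4, seed=1)
    assert res.stress < 0.01
    assert res.stress <= min(res.restart_stresses)
    assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-8)


def test_nmds_places_duplicated_samples_together():
    rng = np.random.default_rng(1)
    base = rng.random((6, 4)) * 10
    m = _df(np.vstack([base, base[:1]]))  # s6 duplicates s0
    D = bray_curtis(m, transform="none")
    res = nmds(D, n_restarts=6, seed=2)
    gap = np.linalg.norm(
        res.coordinates.loc["s0"].to_numpy() - res.coordinates.loc["s6"].to_numpy()
    )
    spread = np.linalg.norm(res.coordinates.to_numpy(), axis=1).max()
    assert gap < 0.05 * spread


def test_anosim_disjoint_groups_give_r_one():
    rng = np.random.default_rng(0)
    a = np.hstack([rng.poisson(6, size=(5, 3)) + 1, np.zeros((5, 3))])
    b = np.hstack([np.zeros((5, 3)), rng.poisson(6, size=(5, 3)) + 1])
    m = _df(np.vstack([a, b]))
    groups = pd.Series(["a"] * 5 + ["b"] * 5, index=m.index)
    res = anosim(bray_curtis(m), groups, n_perm=199, seed=0)
    assert res.R == pytest.approx(1.0)
    assert res.p <= 0.05


def test_anosim_matches_scikit_bio_reference():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(3)
    m = _df(rng.poisson(5, size=(12, 6)))
    groups = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4, index=m.index)
    D = bray_curtis(m)
    ours = anosim(D, groups, n_perm=499, seed=1)
    dm = skbio.DistanceMatrix(D.to_numpy(), ids=list(D.index))
    ref = skbio.stats.distance.anosim(dm, groups.to_numpy(), permutations=499)
    assert ours.R == pytest.approx(ref["test statistic"], abs=1e-12)
    # both p-values are permutation estimates of the same null probability
    assert ours.p == pytest.approx(ref["p-value"], abs=0.06)


def test_anosim_invariant_to_monotone_transform_of_dissimilarity():
    rng = np.random.default_rng(4)
    m = _df(rng.poisson(4, size=(10, 5)))
    groups = pd.Series(["a"] * 5 + ["b"] * 5, index=m.index)
    D = bray_curtis(m)
    r1 = anosim(D, groups, n_perm=99, seed=7)
    r2 = anosim(D**2, groups, n_perm=99, seed=7)  # monotone, rank-preserving
    assert r1.R == pytest.approx(r2.R, abs=1e-12)
    assert r1.p == r2.p


def test_anosim_null_centred_on_zero():
    rng = np.random.default_rng(5)
    rs = []
    for i in range(40):
        m = _df(rng.poisson(5, size=(12, 6)))
        groups = pd.Series(rng.permutation(["a"] * 6 + ["b"] * 6), index=m.index)
        rs.append(anosim(bray_curtis(m), groups, n_perm=49, seed=i).R)
    assert abs(np.mean(rs)) < 0.08


def test_pairwise_anosim_skips_singletons():
    m = _df(np.arange(28, dtype=float).reshape(7, 4) + 1)
    groups = pd.Series(["a", "a", "a", "b", "b", "b", "c"], index=m.index)
    with pytest.warns(UserWarning, match="singleton"):
        out = pairwise_anosim(bray_curtis(m), groups, n_perm=49, seed=0)
    assert set(zip(out["group_a"], out["group_b"])) == {("a", "b")}


def _poisson_tiles(rng, n, rates):
    counts = rng.poisson(rates, size=(n, len(rates)))
    m = pd.DataFrame(
        counts, index=[f"t{i}" for i in range(n)], columns=[f"sp{j}" for j in range(len(rates))]
    )
    areas = pd.Series(7.29, index=m.index)
    return m, areas


def test_autosimilarity_identical_composites_score_one():
    m = _df([[4, 2, 1]] * 30, prefix="t")
    areas = pd.Series(7.29, index=m.index)
    cur = autosimilarity(m, areas, sizes=[1, 5, 10], n_rand=50, seed=0, transform="none")
    assert cur["similarity"].to_numpy() == pytest.approx(1.0)


def test_autosimilarity_single_species_stratum_approaches_one():
    # a one-species stratum has a fixed composition; the only residual
    # dissimilarity is Poisson density noise, which shrinks with size
    rng = np.random.default_rng(6)
    m = pd.DataFrame(
        {"sp1": rng.poisson(5, 80) + 1}, index=[f"t{i}" for i in range(80)]
    )
    areas = pd.Series(7.29, index=m.index)
    cur = autosimilarity(m, areas, sizes=[2, 8, 32], n_rand=200, seed=1,
                         transform="none")
    sims = cur["similarity"].to_numpy()
    assert (np.diff(sims) > 0).all()
    assert sims[-1] > 0.95
    # with literally identical tiles the similarity is exactly 1
    const = pd.DataFrame({"sp1": [4] * 20}, index=[f"t{i}" for i in range(20)])
    cur_const = autosimilarity(const, pd.Series(7.29, index=const.index),
                               sizes=[2, 5], n_rand=20, seed=2, transform="none")
    assert cur_const["similarity"].to_numpy() == pytest.approx(1.0)


def test_autosimilarity_increases_with_composite_size():
    rng = np.random.default_rng(7)
    m, areas = _poisson_tiles(rng, 200, rates=[3, 2, 1, 0.5, 0.2, 0.1])
    cur = autosimilarity(m, areas, sizes=[1, 2, 4, 8, 16, 32], n_rand=300, seed=2)
    sims = cur["similarity"].to_numpy()
    assert (np.diff(sims) > 0).all()
    assert sims[-1] > 0.9


def test_autosimilarity_drops_oversized_requests():
    rng = np.random.default_rng(8)
    m, areas = _poisson_tiles(rng, 10, rates=[2, 1])
    with pytest.warns(UserWarning, match="dropped"):
        cur = autosimilarity(m, areas, sizes=[2, 8], n_rand=20, seed=0)
    assert cur["n_tiles"].tolist() == [2]


def test_required_unit_size_interpolates_crossing():
    curve = pd.DataFrame(
        {
            "n_tiles": [10, 20],
            "area_m2": [73.0, 146.0],
            "mean_individuals": [50.0, 100.0],
            "similarity": [0.70, 0.80],
        }
    )
    req = required_unit_size(curve, 0.75)
    assert req["n_tiles"] == pytest.approx(15.0)
    assert req["area_m2"] == pytest.approx(109.5)
    assert req["mean_individuals"] == pytest.approx(75.0)


def test_required_unit_size_boundary_and_failure_cases():
    above = pd.DataFrame(
        {"n_tiles": [5, 10], "area_m2": [36, 73], "mean_individuals": [20, 40],
         "similarity": [0.8, 0.9]}
    )
    assert required_unit_size(above, 0.75)["n_tiles"] == 5.0
    below = above.assign(similarity=[0.5, 0.6])
    with pytest.raises(ValueError, match="never reaches"):
        required_unit_size(below, 0.75)


def test_curves_collapse_when_indexed_by_individuals_not_area():
    """Two strata share one assemblage but differ 10-fold in density: the
    effort needed for 0.75 self-similarity differs ~10-fold in seabed area
    yet nearly coincides in number of individuals."""
    rng = np.random.default_rng(9)
    base_rates = np.array([3.0, 2.0, 1.0, 0.5, 0.2, 0.1])
    dense, areas_d = _poisson_tiles(rng, 400, rates=base_rates)
    sparse_counts = rng.poisson(base_rates * 0.1, size=(400, len(base_rates)))
    sparse = pd.DataFrame(sparse_counts, index=[f"t{i}" for i in range(400)],
                          columns=dense.columns)
    areas_s = pd.Series(7.29, index=sparse.index)

    sizes_dense = [1, 2, 4, 8, 16, 32]
    sizes_sparse = [4, 8, 16, 32, 64, 128]
    cur_d = autosimilarity(dense, areas_d, sizes=sizes_dense, n_rand=300, seed=3)
    cur_s = autosimilarity(sparse, areas_s, sizes=sizes_sparse, n_rand=300, seed=4)
    req_d = required_unit_size(cur_d, 0.75)
    req_s = required_unit_size(cur_s, 0.75)

    area_ratio = req_s["area_m2"] / req_d["area_m2"]
    ind_ratio = req_s["mean_individuals"] / req_d["mean_individuals"]
    assert area_ratio > 4  # area requirement scales with 1/density
    assert 0.5 < ind_ratio < 2  # individuals requirement nearly invariant
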