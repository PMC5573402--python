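import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim, mantel as skbio_mantel

from rarebio import multivariate as mv

from conftest import make_table, random_table


def euclid_dm(values, ids):
    return DistanceMatrix(squareform(pdist(np.asarray(values, float))), ids=ids)


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        t = make_table([[3, 3], [7, 7]])
        assert mv.bray_curtis(t)[0, 1] == 0.0

    def test_disjoint_support_one(self):
        t = make_table([[5, 0], [0, 9]])
        assert mv.bray_curtis(t)[0, 1] == 1.0

    def test_hand_computed_value(self):
        t = make_table([[6, 2], [2, 2]])
        assert mv.bray_curtis(t)[0, 1] == pytest.approx(1 / 3)

    def test_counts_vs_relative_identical_when_equal_depth(self, rng):
        t = random_table(rng, depth=1000)
        from rarebio.normalization import to_relative
        d1 = mv.bray_curtis(t)
        d2 = mv.bray_curtis(to_relative(t))
        assert np.allclose(d1.data, d2.data, atol=1e-12)

    def test_range_and_symmetry(self, rng):
        d = mv.bray_curtis(random_table(rng))
        data = np.asarray(d.data)
        assert (data >= 0).all() and (data <= 1).all()
        assert np.allclose(data, data.T)
        assert np.allclose(np.diag(data), 0.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            mv.bray_curtis(make_table([[1], [2]]))


class TestNmds:
    def test_three_equidistant_points_embed_perfectly(self):
        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                           ids=["a", "b", "c"])
        res = mv.nmds(d, k=2, restarts=8, max_iter=3000, tol=1e-12, seed=0)
        assert res.stress <= 1e-6

    def test_duplicated_samples_coincide(self):
        pts = np.array([[0, 0], [1, 0], [1, 0], [0, 2]], float)
        d = euclid_dm(pts, ["a", "b", "b2", "c"])
        res = mv.nmds(d, k=2, seed=1, max_iter=1000, tol=1e-10)
        coords = res.coordinates
        gap = np.linalg.norm(coords.loc["b"] - coords.loc["b2"])
        spread = np.linalg.norm(coords.loc["a"] - coords.loc["c"])
        assert gap < 0.05 * spread

    def test_recovers_planted_configuration(self):
        rng = np.random.default_rng(5)
        planted = rng.normal(size=(25, 2))
        d = euclid_dm(planted, [f"s{i}" for i in range(25)])
        res = mv.nmds(d, k=2, restarts=8, seed=2, max_iter=2000, tol=1e-10)
        assert res.stress <= 0.01
        from scipy.spatial import procrustes
        _, _, disparity = procrustes(planted, res.coordinates.to_numpy())
        assert 1 - disparity >= 0.99  # procrustes correlation-like score

    def test_k_must_be_below_n(self):
        d = euclid_dm(np.eye(3), ["a", "b", "c"])
        with pytest.raises(ValueError, match="k"):
            mv.nmds(d, k=3)

    def test_seed_determinism(self, rng):
        d = mv.bray_curtis(random_table(rng, n_samples=10))
        a = mv.nmds(d, seed=7)
        b = mv.nmds(d, seed=7)
        assert np.allclose(a.coordinates, b.coordinates)
        assert a.stress == b.stress


def separated_distance(n_per_group=3, gap=10.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(0, 0.5, size=(n_per_group, 2)),
                     rng.normal(gap, 0.5, size=(n_per_group, 2))])
    ids = [f"s{i}" for i in range(2 * n_per_group)]
    labels = ["g1"] * n_per_group + ["g2"] * n_per_group
    return euclid_dm(pts, ids), labels


def anosim_exact_p(d, labels):
    """Exact ANOSIM p by enumerating all distinct two-group labelings."""
    labels = np.asarray(labels)
    n = len(labels)
    ranks = squareform(stats.rankdata(squareform(np.asarray(d.data))))
    codes = (labels == labels[0]).astype(int)
    observed = mv._anosim_r(ranks, codes)
    k = codes.sum()
    hits = total = 0
    for combo in itertools.combinations(range(n), k):
        perm = np.zeros(n, dtype=int)
        perm[list(combo)] = 1
        total += 1
        if mv._anosim_r(ranks, perm) >= observed - 1e-12:
            hits += 1
    return hits / total


class TestAnosim:
    def test_perfect_separation_r_one(self):
        d, labels = separated_distance()
        res = mv.anosim(d, labels, n_permutations=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= 0.11  # only 10 distinct labelings at n=6

    def test_null_r_near_zero(self):
        rng = np.random.default_rng(1)
        rs = []
        for trial in range(20):
            pts = rng.normal(size=(12, 2))
            d = euclid_dm(pts, [f"s{i}" for i in range(12)])
            labels = ["a"] * 6 + ["b"] * 6
            rs.append(mv.anosim(d, labels, n_permutations=99, seed=trial).r)
        assert abs(np.mean(rs)) < 0.1

    def test_permutation_p_matches_exact_enumeration(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.0  # partial separation -> interesting p
        d = euclid_dm(pts, [f"s{i}" for i in range(6)])
        labels = ["a"] * 3 + ["b"] * 3
        exact = anosim_exact_p(d, labels)
        res = mv.anosim(d, labels, n_permutations=9999, seed=5)
        se = np.sqrt(exact * (1 - exact) / 9999)
        assert abs(res.p_value - exact) <= 3 * se + 2e-4

    def test_agrees_with_skbio(self, rng):
        t = random_table(rng, n_samples=12)
        d = mv.bray_curtis(t)
        labels = ["a"] * 6 + ["b"] * 6
        ours = mv.anosim(d, labels, n_permutations=999, seed=0)
        theirs = skbio_anosim(d, np.array(labels), permutations=999)
        assert ours.r == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_singleton_group_rejected(self):
        d, labels = separated_distance()
        labels = ["solo"] + labels[1:]
        with pytest.raises(ValueError, match="solo"):
            mv.anosim(d, labels)

    def test_invariant_under_reordering(self, rng):
        t = random_table(rng, n_samples=10)
        d = mv.bray_curtis(t)
        labels = pd.Series((["a"] * 5 + ["b"] * 5), index=d.ids)
        r1 = mv.anosim(d, labels, n_permutations=9, seed=0).r
        order = list(d.ids)[::-1]
        r2 = mv.anosim(d.filter(order), labels, n_permutations=9, seed=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestPairwiseAnosim:
    def test_three_groups_give_three_pairs(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(i * 5, 1, size=(4, 2)) for i in range(3)])
        d = euclid_dm(pts, [f"s{i}" for i in range(12)])
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        out = mv.pairwise_anosim(d, labels, n_permutations=99, seed=1)
        assert len(out) == 3

    def test_bonferroni_formula(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(i, 1, size=(4, 2)) for i in range(3)])
        d = euclid_dm(pts, [f"s{i}" for i in range(12)])
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        out = mv.pairwise_anosim(d, labels, n_permutations=99, seed=1,
                                 correction="bonferroni")
        assert np.allclose(out["p_adjusted"],
                           np.minimum(1.0, out["p_value"] * 3))

    def test_cloned_groups_r_near_zero(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 2))
        pts2 = np.vstack([pts, pts + rng.normal(0, 0.01, size=(6, 2))])
        d = euclid_dm(pts2, [f"s{i}" for i in range(12)])
        labels = ["a"] * 6 + ["b"] * 6
        res = mv.anosim(d, labels, n_permutations=99, seed=0)
        assert abs(res.r) < 0.3


def mantel_exact_p(a, b, method="spearman"):
    """Exhaustive Mantel p over all n! relabelings of matrix a."""
    amat = np.asarray(a.data, float)
    n = amat.shape[0]
    iu = np.triu_indices(n, k=1)
    bv = np.asarray(b.data, float)[iu]
    observed = mv._corr_vectors(amat[iu], bv, method)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        pv = amat[np.ix_(perm, perm)][iu]
        total += 1
        if mv._corr_vectors(pv, bv, method) >= observed - 1e-12:
            hits += 1
    return hits / total


class TestMantel:
    def test_identical_matrices_r_one(self, rng):
        d = mv.bray_curtis(random_table(rng, n_samples=8))
        res = mv.mantel(d, d, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_monotone_transform_spearman_r_one(self, rng):
        d = mv.bray_curtis(random_table(rng, n_samples=8))
        transformed = DistanceMatrix(np.asarray(d.data) ** 2, ids=list(d.ids))
        res = mv.mantel(d, transformed, method="spearman", n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_permutation_p_matches_exhaustive(self):
        rng = np.random.default_rng(9)
        a = euclid_dm(rng.normal(size=(5, 2)), list("abcde"))
        b = euclid_dm(rng.normal(size=(5, 2)) + 0.5 * np.asarray(
            [[r[0], r[1]] for r in rng.normal(size=(5, 2))]), list("abcde"))
        exact = mantel_exact_p(a, b)
        res = mv.mantel(a, b, n_permutations=9999, seed=1)
        se = np.sqrt(exact * (1 - exact) / 9999)
        assert abs(res.p_value - exact) <= 3 * se + 2e-3

    def test_agrees_with_skbio_statistic(self, rng):
        x = mv.bray_curtis(random_table(rng, n_samples=9))
        y = euclid_dm(np.random.default_rng(1).normal(size=(9, 3)), list(x.ids))
        for method in ("pearson", "spearman"):
            ours = mv.mantel(x, y, method=method, n_permutations=99, seed=0)
            theirs = skbio_mantel(x, y, method=method, permutations=99)
            assert ours.r == pytest.approx(theirs[0], abs=1e-12)

    def test_size_mismatch_rejected(self, rng):
        a = mv.bray_curtis(random_table(rng, n_samples=6))
        b = euclid_dm(np.eye(4), list("wxyz"))
        with pytest.raises(ValueError, match="different samples"):
            mv.mantel(a, b)

    def test_p_value_never_zero(self, rng):
        d = mv.bray_curtis(random_table(rng, n_samples=8))
        res = mv.mantel(d, d, n_permutations=99, seed=0)
        assert res.p_value > 0


class TestPartialMantel:
    def _triplet(self, seed, n=30, control_like_b=False):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        x = rng.normal(size=(n, 2))
        a = euclid_dm(x + rng.normal(0, 0.5, size=(n, 2)), ids)
        b = euclid_dm(rng.normal(size=(n, 2)), ids)
        control = b if control_like_b else euclid_dm(rng.normal(size=(n, 2)), ids)
        return a, b, control

    def test_control_equal_to_b_kills_correlation(self):
        rs = []
        for seed in range(10):
            a, b, _ = self._triplet(seed)
            res = mv.partial_mantel(a, b, b, n_permutations=9, seed=seed)
            rs.append(res.r)
        assert abs(np.mean(rs)) < 0.05

    def test_independent_control_preserves_simple_r(self):
        diffs = []
        for seed in range(8):
            rng = np.random.default_rng(seed + 100)
            ids = [f"s{i}" for i in range(30)]
            latent = rng.normal(size=(30, 2))
            a = euclid_dm(latent + rng.normal(0, 0.7, (30, 2)), ids)
            b = euclid_dm(latent + rng.normal(0, 0.7, (30, 2)), ids)
            control = euclid_dm(rng.normal(size=(30, 2)), ids)
            simple = mv.mantel(a, b, n_permutations=9, seed=seed).r
            partial = mv.partial_mantel(a, b, control, n_permutations=9, seed=seed).r
            diffs.append(partial - simple)
        assert abs(np.mean(diffs)) < 0.05

    def test_a_equals_b_with_independent_control(self):
        rng = np.random.default_rng(7)
        ids = [f"s{i}" for i in range(20)]
        a = euclid_dm(rng.normal(size=(20, 2)), ids)
        control = euclid_dm(rng.normal(size=(20, 2)), ids)
        res = mv.partial_mantel(a, a, control, n_permutations=9, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-9)


class TestEnvPrepare:
    def _env(self, rng, n=20):
        return pd.DataFrame({
            "salinity": rng.uniform(0, 35, n),
            "temperature": rng.uniform(10, 30, n),
            "noise": rng.normal(size=n),
        }, index=[f"s{i}" for i in range(n)])

    def test_perfectly_correlated_pair_pruned(self, rng):
        env = self._env(rng)
        env["salinity_twin"] = env["salinity"] * 2 + 1
        out, report = mv.env_prepare(env, transform="none")
        assert "salinity_twin" in report["dropped_variables"]
        assert "salinity" in out.columns

    def test_nothing_removed_below_threshold(self, rng):
        env = self._env(rng)
        out, report = mv.env_prepare(env, transform="none")
        assert report["dropped_variables"] == {}
        assert set(out.columns) == set(env.columns)

    def test_standardization(self, rng):
        out, _ = mv.env_prepare(self._env(rng), transform="none")
        assert np.allclose(out.mean(), 0.0, atol=1e-9)
        assert np.allclose(out.std(ddof=0), 1.0, atol=1e-9)

    def test_priority_decides_which_twin_survives(self, rng):
        env = self._env(rng)
        env["important"] = env["noise"] * 3
        out, report = mv.env_prepare(env, transform="none",
                                     priority=["important"])
        assert "noise" in report["dropped_variables"]
        assert "important" in out.columns

    def test_incomplete_samples_dropped_and_logged(self, rng):
        env = self._env(rng)
        env.iloc[0, 0] = np.nan
        out, report = mv.env_prepare(env, transform="none")
        assert report["dropped_samples"] == ["s0"]
        assert "s0" not in out.index

    def test_log_transform_reduces_skew(self, rng):
        env = pd.DataFrame({"skewed": np.exp(rng.normal(0, 1.5, 60)),
                            "flat": rng.uniform(size=60)},
                           index=[f"s{i}" for i in range(60)])
        _, report = mv.env_prepare(env, transform="auto")
        assert report["transforms"]["skewed"] in ("log", "sqrt")


def bioenv_bruteforce(d, env):
    """Independent exhaustive oracle: best subset by Spearman rho."""
    comm = np.asarray(d.data)[np.triu_indices(d.shape[0], k=1)]
    best = (None, -np.inf)
    for size in range(1, env.shape[1] + 1):
        for subset in itertools.combinations(env.columns, size):
            ed = pdist(env[list(subset)].to_numpy(float))
            rho = stats.spearmanr(ed, comm)[0]
            if rho > best[1]:
                best = (subset, rho)
    return best


class TestBioenv:
    def _planted(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        env = pd.DataFrame({
            "driver": rng.normal(size=n),
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
            "x3": rng.normal(size=n),
            "x4": rng.normal(size=n),
        }, index=ids)
        d = euclid_dm(env[["driver"]].to_numpy(), ids)
        return d, env

    def test_generative_identity_attains_rho_one(self):
        d, env = self._planted()
        res = mv.bioenv(d, env)
        assert res.by_size[1][0] == ("driver",)
        assert res.by_size[1][1] == pytest.approx(1.0)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(12)
        ids = [f"s{i}" for i in range(20)]
        env = pd.DataFrame(rng.normal(size=(20, 5)),
                           columns=list("abcde"), index=ids)
        latent = env[["a", "c"]].to_numpy() + rng.normal(0, 0.5, size=(20, 2))
        d = euclid_dm(latent, ids)
        res = mv.bioenv(d, env)
        oracle_subset, oracle_rho = bioenv_bruteforce(d, env)
        assert set(res.best_subset) == set(oracle_subset)
        assert res.best_rho == pytest.approx(oracle_rho, abs=1e-12)

    def test_noise_variable_does_not_beat_best_subset(self):
        d, env = self._planted(seed=3)
        res = mv.bioenv(d, env)
        singleton = res.by_size[1][1]
        assert res.best_rho <= singleton + 1e-9

    def test_guard_on_variable_count(self, rng):
        ids = [f"s{i}" for i in range(10)]
        env = pd.DataFrame(rng.normal(size=(10, 16)),
                           columns=[f"v{i}" for i in range(16)], index=ids)
        d = euclid_dm(rng.normal(size=(10, 2)), ids)
        with pytest.raises(ValueError, match="bvstep"):
            mv.bioenv(d, env)

    def test_incomplete_env_rejected(self, rng):
        d, env = self._planted()
        env.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="env_prepare"):
            mv.bioenv(d, env)


class TestBvstep:
    def test_single_variable_equals_bioenv(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(15)]
        env = pd.DataFrame({"only": rng.normal(size=15)}, index=ids)
        d = euclid_dm(rng.normal(size=(15, 2)), ids)
        be = mv.bioenv(d, env)
        bv = mv.bvstep(d, env, seed=0)
        assert bv.best_subset == be.best_subset
        assert bv.best_rho == pytest.approx(be.best_rho, abs=1e-12)

    def test_never_exceeds_exhaustive_maximum(self):
        for seed in range(5):
            rng = np.random.default_rng(seed + 40)
            ids = [f"s{i}" for i in range(18)]
            env = pd.DataFrame(rng.normal(size=(18, 5)),
                               columns=list("abcde"), index=ids)
            d = euclid_dm(env[["a", "b"]].to_numpy() + rng.normal(0, 1, (18, 2)), ids)
            be = mv.bioenv(d, env)
            for start in ("empty", "full", "random"):
                bv = mv.bvstep(d, env, start=start, seed=seed)
                assert bv.best_rho <= be.best_rho + 1e-9

    def test_recovers_planted_drivers(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed + 200)
            ids = [f"s{i}" for i in range(25)]
            env = pd.DataFrame(rng.normal(size=(25, 6)),
                               columns=[f"v{i}" for i in range(6)], index=ids)
            d = euclid_dm(env[["v0", "v1"]].to_numpy()
                          + rng.normal(0, 0.3, (25, 2)), ids)
            bv = mv.bvstep(d, env, seed=seed)
            hits += {"v0", "v1"} <= set(bv.best_subset)
        assert hits >= 9

    def test_search_path_recorded(self):
        d, env = TestBioenv()._planted(seed=5)
        bv = mv.bvstep(d, env, seed=0)
        assert bv.path and bv.path[0]["op"] == "add"


class TestAxisEnvCorrelation:
    def _ordination(self, values, ids):
        coords = pd.DataFrame({"dim1": values,
                               "dim2": np.zeros(len(values))}, index=ids)
        return mv.OrdinationResult(coords, stress=0.1, iterations=10,
                                   converged=True, n_restarts=1)

    def test_axis_equal_to_variable(self):
        ids = [f"s{i}" for i in range(10)]
        vals = np.arange(10.0)
        env = pd.DataFrame({"salinity": vals}, index=ids)
        res = mv.axis_env_correlation(self._ordination(vals, ids), env, "salinity")
        assert res["rho"] == pytest.approx(1.0)

    def test_monotone_transform_still_one(self):
        ids = [f"s{i}" for i in range(10)]
        vals = np.arange(10.0)
        env = pd.DataFrame({"salinity": np.exp(vals)}, index=ids)
        res = mv.axis_env_correlation(self._ordination(vals, ids), env, "salinity")
        assert res["rho"] == pytest.approx(1.0)

    def test_constant_variable_rejected(self):
        ids = [f"s{i}" for i in range(5)]
        env = pd.DataFrame({"flat": np.ones(5)}, index=ids)
        with pytest.raises(ValueError, match="constant"):
            mv.axis_env_correlation(self._ordination(np.arange(5.0), ids), env, "flat")

    def test_null_rho_small_at_n50(self):
        rng = np.random.default_rng(3)
        ids = [f"s{i}" for i in range(50)]
        rhos = []
        for _ in range(20):
            env = pd.DataFrame({"v": rng.normal(size=50)}, index=ids)
            ordn = self._ordination(rng.normal(size=50), ids)
            rhos.append(mv.axis_env_correlation(ordn, env, "v")["rho"])
        assert abs(np.mean(rhos)) < 0.1

    def test_permutation_p_flagged(self):
        ids = [f"s{i}" for i in range(12)]
        rng = np.random.default_rng(0)
        env = pd.DataFrame({"v": rng.normal(size=12)}, index=ids)
        res = mv.axis_env_correlation(self._ordination(rng.normal(size=12), ids),
                                      env, "v", p_method="permutation",
                                      n_permutations=99, seed=0)
        assert res["p_method"] == "permutation"
        assert 0 < res["p_value"] <= 1
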